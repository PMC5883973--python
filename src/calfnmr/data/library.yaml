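# calfnmr library configuration, v1.
# Pathway sets, name synonyms, reference-compound and background settings.

water_exclusion_ppm: [4.50, 5.00]

reference_compounds:
  TMSP:
    # chemical-shift reference; in-tube equivalent concentration (uM)
    concentration_uM: 500.0
  "1,4-dioxane":
    # internal standard for qNMR; concentration in the measured plasma+buffer
    # mixture (uM); only the ratio to metabolite signals matters
    concentration_uM: 100.0

# residual water: in-tube equivalent concentration (uM)
water_concentration_uM: 30000.0

# broad macromolecule (lipid/lipoprotein/glycoprotein) background:
# per-sample level multiplying the MM-* resonance weights (uM-equivalent),
# with a lognormal coefficient of variation across samples
macromolecule_level_uM: 150.0
macromolecule_cv: 0.2

dilution_factor: 2.0

synonyms:
  pyruvate: Pyruvic acid
  formate: Formic acid
  3-hydroxybutyrate: 3-Hydroxybutyric acid
  acetate: Acetic acid
  glucose: D-Glucose
  creatine: Creatine
  choline: Choline
  glycine: Glycine
  valine: Valine
  alanine: Alanine
  isoleucine: Isoleucine
  leucine: Leucine
  proline: Proline
  histidine: Histidine
  phenylalanine: Phenylalanine
  acetone: Acetone

pathways:
  aminoacyl-tRNA biosynthesis:
    - histidine
    - phenylalanine
    - glycine
    - valine
    - alanine
    - isoleucine
    - leucine
    - proline
  valine, leucine and isoleucine biosynthesis:
    - pyruvate
    - leucine
    - valine
    - isoleucine
  nitrogen metabolism:
    - phenylalanine
    - histidine
    - glycine
    - formate
  glycine, serine and threonine metabolism:
    - choline
    - glycine
    - creatine
    - pyruvate
  synthesis and degradation of ketone bodies:
    - 3-hydroxybutyrate
    - acetone
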