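# calfnmr resonance library, v1.
# One row per resonance. Positions/multiplicities are approximate literature
# (HMDB-style) values at pH 7.4, adjusted so that every quantification window
# (center +/- 0.04 ppm) contains no other library line.
# component_class: metabolite | macromolecule | reference | water
# quantify: 1 marks the resonance integrated for qNMR (exactly one per metabolite).
name	center_ppm	multiplicity	j_hz	n_protons	component_class	r2_hz	diffusion_coeff	quantify
Isoleucine	0.93	triplet	7.4	3	metabolite	3.0	0.05	1
Isoleucine	1.26	multiplet	7.3	1	metabolite	3.0	0.05	0
Valine	0.98	doublet	7.0	3	metabolite	3.0	0.05	1
Leucine	1.72	multiplet	7.0	3	metabolite	3.0	0.05	1
Alanine	1.48	doublet	7.2	3	metabolite	3.0	0.05	1
3-Hydroxybutyric acid	1.19	doublet	6.3	3	metabolite	3.0	0.05	1
Isobutyric acid	1.06	doublet	7.0	6	metabolite	3.0	0.05	1
Acetic acid	1.91	singlet	0	3	metabolite	3.0	0.05	1
Acetone	2.22	singlet	0	6	metabolite	3.0	0.05	1
Pyruvic acid	2.36	singlet	0	3	metabolite	3.0	0.05	1
Creatine	3.03	singlet	0	3	metabolite	3.0	0.05	1
Creatine	3.92	singlet	0	2	metabolite	3.0	0.05	0
Phosphocreatine + creatinine	4.06	singlet	0	2	metabolite	3.0	0.05	1
Choline	3.20	singlet	0	9	metabolite	3.0	0.05	1
Dimethyl sulfone	3.14	singlet	0	6	metabolite	3.0	0.05	1
Glycine	3.56	singlet	0	2	metabolite	3.0	0.05	1
GPC	3.61	multiplet	5.0	2	metabolite	3.0	0.05	1
GPC	4.33	multiplet	5.0	1	metabolite	3.0	0.05	0
Proline	4.13	multiplet	6.5	1	metabolite	3.0	0.05	0
Proline	1.99	multiplet	6.5	3	metabolite	3.0	0.05	1
D-Glucose	5.24	doublet	3.8	1	metabolite	3.0	0.05	1
D-Glucose	3.46	multiplet	7.0	5	metabolite	3.0	0.05	0
D-Glucose	3.84	multiplet	7.0	2	metabolite	3.0	0.05	0
Allantoin	5.39	singlet	0	1	metabolite	3.0	0.05	1
Phenylalanine	7.37	multiplet	7.0	5	metabolite	3.0	0.05	1
Tyrosine	6.90	doublet	8.6	2	metabolite	3.0	0.05	1
Tyrosine	7.19	doublet	8.6	2	metabolite	3.0	0.05	0
Histidine	7.80	singlet	0	1	metabolite	3.0	0.05	1
Histidine	7.09	singlet	0	1	metabolite	3.0	0.05	0
Formic acid	8.46	singlet	0	1	metabolite	3.0	0.05	1
TMSP	0.00	singlet	0	9	reference	3.0	0.05	1
1,4-dioxane	3.70	singlet	0	8	reference	3.0	0.05	1
MM-CH3	0.87	singlet	0	9	macromolecule	60.0	0.90	0
MM-CH2	1.28	singlet	0	20	macromolecule	60.0	0.90	0
MM-CH2CO	1.58	singlet	0	4	macromolecule	60.0	0.90	0
MM-NAc	2.03	singlet	0	6	macromolecule	60.0	0.90	0
MM-allylic	2.76	singlet	0	2	macromolecule	60.0	0.90	0
MM-cholineHead	3.25	singlet	0	3	macromolecule	60.0	0.90	0
MM-olefinic	5.32	singlet	0	3	macromolecule	60.0	0.90	0
Water	4.70	singlet	0	2	water	300.0	0.01	0
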