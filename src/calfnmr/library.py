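"""Packaged reference data for the 22-metabolite plasma NMR library.

The library bundles, for each metabolite quantified in the calf-sepsis study:
resonance assignments (position, multiplicity, J, proton count), one designated
quantification signal, and the per-group concentration distributions
(mean, SD, n in μM) that parameterize the synthetic-data generator. It also
carries the reference compounds (TMSP at 0.00 ppm and the 1,4-dioxane internal
standard), a residual-water definition, a broad macromolecule background, and
the five metabolic pathway sets used for over-representation analysis.

Resonance positions are approximate literature (HMDB-style) values; the study
itself did not publish its assignment table, so these are best-practice
choices, documented in the versioned data files under ``calfnmr/data``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "Resonance",
    "MetaboliteDef",
    "PathwaySet",
    "MetaboliteLibrary",
    "load_library",
    "MULTIPLICITIES",
    "PPM_RANGE",
]

#: binning / analysis window (ppm)
PPM_RANGE = (0.2, 10.0)

#: default transverse relaxation rate for small metabolites (s^-1);
#: macromolecules must be at least 10x this
METABOLITE_R2_DEFAULT = 3.0

#: minimum separation between quantification signals (ppm)
QUANT_SEPARATION_PPM = 0.04

# line offsets (in units of J) and relative intensities per multiplicity;
# "multiplet" is an idealized 4-line symmetric cluster
MULTIPLICITIES: dict[str, list[tuple[float, float]]] = {
    "singlet": [(0.0, 1.0)],
    "doublet": [(-0.5, 0.5), (0.5, 0.5)],
    "triplet": [(-1.0, 0.25), (0.0, 0.5), (1.0, 0.25)],
    "quartet": [(-1.5, 0.125), (-0.5, 0.375), (0.5, 0.375), (1.5, 0.125)],
    "multiplet": [(-1.5, 0.25), (-0.5, 0.25), (0.5, 0.25), (1.5, 0.25)],
}


class LibraryValidationError(ValueError):
    """Raised when library data violate a structural invariant."""


@dataclass(frozen=True)
class Resonance:
    """A single NMR resonance (possibly J-split into several lines)."""

    center_ppm: float
    multiplicity: str
    j_hz: float
    n_protons: float
    component_class: str = "metabolite"
    r2_hz: float = METABOLITE_R2_DEFAULT
    diffusion_coeff: float = 0.05

    def __post_init__(self) -> None:
        if not (-0.5 <= self.center_ppm <= 12.0):
            raise LibraryValidationError(
                f"resonance at {self.center_ppm} ppm outside [-0.5, 12]"
            )
        if self.multiplicity not in MULTIPLICITIES:
            raise LibraryValidationError(f"unknown multiplicity {self.multiplicity!r}")
        if self.n_protons < 1:
            raise LibraryValidationError("n_protons must be >= 1")
        if self.r2_hz <= 0:
            raise LibraryValidationError("r2_hz must be positive")
        if not (0.0 <= self.diffusion_coeff <= 1.0):
            raise LibraryValidationError("diffusion_coeff must lie in [0, 1]")

    def lines(self, larmor_mhz: float) -> list[tuple[float, float]]:
        """J-split line positions (ppm) and fractional intensities.

        Returns ``[(ppm, fraction), ...]`` with fractions summing to 1.
        """
        j_ppm = self.j_hz / larmor_mhz
        return [
            (self.center_ppm + off * j_ppm, w)
            for off, w in MULTIPLICITIES[self.multiplicity]
        ]


@dataclass(frozen=True)
class MetaboliteDef:
    """One library metabolite: resonances, quantification signal, Table-style
    per-group concentration distributions (mean μM, SD μM, n)."""

    name: str
    resonances: tuple[Resonance, ...]
    quantification_signal: int
    group_distributions: Mapping[str, tuple[float, float, int]]

    def __post_init__(self) -> None:
        if not (0 <= self.quantification_signal < len(self.resonances)):
            raise LibraryValidationError(
                f"{self.name}: quantification_signal index out of range"
            )
        for group, (mean, sd, n) in self.group_distributions.items():
            if mean <= 0 or sd < 0 or n < 1:
                raise LibraryValidationError(
                    f"{self.name}/{group}: need mean > 0, sd >= 0, n >= 1"
                )

    @property
    def quant_resonance(self) -> Resonance:
        return self.resonances[self.quantification_signal]


@dataclass(frozen=True)
class PathwaySet:
    """A named metabolic pathway with its member metabolites (canonical names)."""

    name: str
    members: frozenset[str]


@dataclass(frozen=True)
class MetaboliteLibrary:
    metabolites: tuple[MetaboliteDef, ...]
    references: Mapping[str, tuple[Resonance, float]]  # name -> (resonance, in-tube μM)
    water: Resonance
    water_concentration_uM: float
    water_exclusion_ppm: tuple[float, float]
    macromolecules: tuple[tuple[str, Resonance], ...]
    macromolecule_level_uM: float
    macromolecule_cv: float
    dilution_factor: float
    synonyms: Mapping[str, str]
    pathways: tuple[PathwaySet, ...]

    @property
    def metabolite_names(self) -> list[str]:
        return [m.name for m in self.metabolites]

    def get(self, name: str) -> MetaboliteDef:
        for m in self.metabolites:
            if m.name == name:
                return m
        raise KeyError(f"metabolite {name!r} not in library")

    @property
    def groups(self) -> list[str]:
        return list(self.metabolites[0].group_distributions.keys())

    def resolve_name(self, name: str) -> str:
        """Map a synonym (e.g. 'pyruvate') to its canonical library name."""
        if name in self.metabolite_names:
            return name
        if name in self.synonyms:
            return self.synonyms[name]
        raise KeyError(f"cannot resolve metabolite name {name!r}")

    @property
    def dioxane(self) -> tuple[Resonance, float]:
        return self.references["1,4-dioxane"]

    @property
    def tmsp(self) -> tuple[Resonance, float]:
        return self.references["TMSP"]

    def save(self, directory: str | Path) -> None:
        """Serialize back to the on-disk schema (resonances/concentrations TSV
        plus a YAML config); ``load_library`` on the result round-trips."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for met in self.metabolites:
            for i, r in enumerate(met.resonances):
                rows.append(_resonance_row(met.name, r, i == met.quantification_signal))
        for name, (r, _) in self.references.items():
            rows.append(_resonance_row(name, r, True))
        for name, r in self.macromolecules:
            rows.append(_resonance_row(name, r, False))
        rows.append(_resonance_row("Water", self.water, False))
        pd.DataFrame(rows).to_csv(directory / "resonances.tsv", sep="\t", index=False)

        conc_rows = [
            {"metabolite": met.name, "group": g, "mean_uM": mu, "sd_uM": sd, "n": n}
            for met in self.metabolites
            for g, (mu, sd, n) in met.group_distributions.items()
        ]
        pd.DataFrame(conc_rows).to_csv(
            directory / "concentrations.tsv", sep="\t", index=False
        )

        cfg = {
            "water_exclusion_ppm": list(self.water_exclusion_ppm),
            "reference_compounds": {
                name: {"concentration_uM": conc}
                for name, (_, conc) in self.references.items()
            },
            "water_concentration_uM": self.water_concentration_uM,
            "macromolecule_level_uM": self.macromolecule_level_uM,
            "macromolecule_cv": self.macromolecule_cv,
            "dilution_factor": self.dilution_factor,
            "synonyms": dict(self.synonyms),
            "pathways": {p.name: sorted(p.members) for p in self.pathways},
        }
        (directory / "library.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))


def _resonance_row(name: str, r: Resonance, quantify: bool) -> dict:
    return {
        "name": name,
        "center_ppm": r.center_ppm,
        "multiplicity": r.multiplicity,
        "j_hz": r.j_hz,
        "n_protons": r.n_protons,
        "component_class": r.component_class,
        "r2_hz": r.r2_hz,
        "diffusion_coeff": r.diffusion_coeff,
        "quantify": int(quantify),
    }


_DATA = files("calfnmr.data")


def _read_resonance_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {
        "name", "center_ppm", "multiplicity", "j_hz", "n_protons",
        "component_class", "r2_hz", "diffusion_coeff", "quantify",
    }
    missing = required - set(df.columns)
    if missing:
        raise LibraryValidationError(f"resonance table missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["name", "center_ppm"])
    if dup.any():
        row = df[dup].iloc[0]
        raise LibraryValidationError(
            f"duplicate resonance row: {row['name']} @ {row['center_ppm']} ppm"
        )
    return df


def load_library(
    overrides: str | Path | None = None,
    concentrations: str | Path | None = None,
    config: str | Path | None = None,
) -> MetaboliteLibrary:
    """Load the packaged 22-metabolite library (or user replacements).

    Parameters
    ----------
    overrides
        Optional path to a resonance table (tab-delimited, same schema as the
        packaged ``resonances.tsv``) replacing the packaged assignments.
    concentrations, config
        Optional replacements for the concentration table and the YAML
        pathway/reference config (used mainly by :meth:`MetaboliteLibrary.save`
        round-trips).

    Returns
    -------
    MetaboliteLibrary
        Validated library with 22 metabolites, reference compounds, water
        definition, macromolecule background and 5 pathway sets.
    """
    res_src = Path(overrides) if overrides is not None else _DATA / "resonances.tsv"
    conc_src = (
        Path(concentrations) if concentrations is not None else _DATA / "concentrations.tsv"
    )
    cfg_src = Path(config) if config is not None else _DATA / "library.yaml"

    try:
        rdf = _read_resonance_table(res_src)
    except LibraryValidationError:
        raise
    except Exception as exc:  # malformed file: name the source
        raise LibraryValidationError(f"cannot parse resonance table {res_src}: {exc}") from exc
    cdf = pd.read_csv(conc_src, sep="\t", comment="#")
    cfg = yaml.safe_load(cfg_src.read_text())

    dists: dict[str, dict[str, tuple[float, float, int]]] = {}
    for _, row in cdf.iterrows():
        dists.setdefault(row["metabolite"], {})[row["group"]] = (
            float(row["mean_uM"]), float(row["sd_uM"]), int(row["n"]),
        )

    metabolites: list[MetaboliteDef] = []
    references: dict[str, tuple[Resonance, float]] = {}
    macromolecules: list[tuple[str, Resonance]] = []
    water: Resonance | None = None
    ref_cfg = cfg["reference_compounds"]

    for name, sub in rdf.groupby("name", sort=False):
        try:
            resonances = tuple(
                Resonance(
                    center_ppm=float(r.center_ppm),
                    multiplicity=str(r.multiplicity),
                    j_hz=float(r.j_hz),
                    n_protons=float(r.n_protons),
                    component_class=str(r.component_class),
                    r2_hz=float(r.r2_hz),
                    diffusion_coeff=float(r.diffusion_coeff),
                )
                for r in sub.itertuples()
            )
        except LibraryValidationError as exc:
            raise LibraryValidationError(f"row for {name!r}: {exc}") from exc
        cls = resonances[0].component_class
        if cls == "metabolite":
            quant_idx = [i for i, q in enumerate(sub["quantify"]) if int(q) == 1]
            if len(quant_idx) != 1:
                raise LibraryValidationError(
                    f"{name}: exactly one quantification signal required"
                )
            if name not in dists:
                raise LibraryValidationError(f"{name}: no concentration distributions")
            metabolites.append(
                MetaboliteDef(
                    name=str(name),
                    resonances=resonances,
                    quantification_signal=quant_idx[0],
                    group_distributions=dists[str(name)],
                )
            )
        elif cls == "reference":
            references[str(name)] = (
                resonances[0],
                float(ref_cfg[str(name)]["concentration_uM"]),
            )
        elif cls == "macromolecule":
            macromolecules.extend((str(name), r) for r in resonances)
        elif cls == "water":
            water = resonances[0]
        else:
            raise LibraryValidationError(f"{name}: unknown component_class {cls!r}")

    if water is None:
        raise LibraryValidationError("library must define a water resonance")

    synonyms = dict(cfg.get("synonyms", {}))
    names = {m.name for m in metabolites}
    pathways = []
    for pname, members in cfg["pathways"].items():
        canon = set()
        for member in members:
            target = synonyms.get(member, member)
            if target not in names:
                raise LibraryValidationError(
                    f"pathway {pname!r}: member {member!r} unresolvable"
                )
            canon.add(target)
        pathways.append(PathwaySet(name=pname, members=frozenset(canon)))

    lib = MetaboliteLibrary(
        metabolites=tuple(metabolites),
        references=references,
        water=water,
        water_concentration_uM=float(cfg["water_concentration_uM"]),
        water_exclusion_ppm=tuple(cfg["water_exclusion_ppm"]),
        macromolecules=tuple(macromolecules),
        macromolecule_level_uM=float(cfg["macromolecule_level_uM"]),
        macromolecule_cv=float(cfg["macromolecule_cv"]),
        dilution_factor=float(cfg["dilution_factor"]),
        synonyms=synonyms,
        pathways=tuple(pathways),
    )
    _validate_library(lib)
    return lib


def _validate_library(lib: MetaboliteLibrary) -> None:
    if len(lib.metabolites) != 22:
        raise LibraryValidationError(
            f"library must contain exactly 22 metabolites, got {len(lib.metabolites)}"
        )
    names = lib.metabolite_names
    if len(set(names)) != len(names):
        raise LibraryValidationError("duplicate metabolite names")

    lo, hi = PPM_RANGE
    wlo, whi = lib.water_exclusion_ppm
    quants = [(m.name, m.quant_resonance.center_ppm) for m in lib.metabolites]
    for name, ppm in quants:
        if not (lo <= ppm <= hi):
            raise LibraryValidationError(
                f"{name}: quantification signal {ppm} ppm outside [{lo}, {hi}]"
            )
        if wlo - QUANT_SEPARATION_PPM <= ppm <= whi + QUANT_SEPARATION_PPM:
            raise LibraryValidationError(
                f"{name}: quantification signal {ppm} ppm overlaps water exclusion"
            )
    for (n1, p1) in quants:
        for (n2, p2) in quants:
            if n1 < n2 and abs(p1 - p2) <= QUANT_SEPARATION_PPM:
                raise LibraryValidationError(
                    f"quantification signals of {n1} and {n2} overlap "
                    f"({p1} vs {p2} ppm)"
                )

    for _, r in lib.macromolecules:
        if r.r2_hz < 10 * METABOLITE_R2_DEFAULT:
            raise LibraryValidationError(
                "macromolecule r2_hz must be >= 10x the metabolite default"
            )
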