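"""Synthetic study design: sample manifest, concentration draws, sepsis rules.

The emulated study follows 20 diseased newborn calves sampled at six
post-admission time points (0, 3, 6, 24, 48 and 72 h) plus 10 healthy
controls (Ha). Deaths over time are encoded purely through the shrinking
per-time-point sample sizes; one acquired 0 h spectrum is flagged as removed
for bad quality, so analyses see n = 19 at 0 h out of 113 acquired spectra.

Per-sample metabolite concentrations are drawn from lognormal distributions
moment-matched to the published per-group mean/SD — lognormals guarantee
positivity and the right skew typical of plasma metabolites, and mean/SD are
the only published moments.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library import MetaboliteLibrary

__all__ = [
    "GROUPS",
    "DEFAULT_GROUP_SIZES",
    "SampleRecord",
    "VitalsRecord",
    "SepsisClass",
    "generate_manifest",
    "manifest_frame",
    "sample_concentrations",
    "lognormal_params",
    "classify_sepsis",
    "count_sirs_criteria",
    "simulate_vitals",
]

GROUPS = ("Ha", "0h", "3h", "6h", "24h", "48h", "72h")

#: acquired spectra per group; the 0h group loses one sample to QC (n=19 analyzed)
DEFAULT_GROUP_SIZES = {"Ha": 10, "0h": 20, "3h": 20, "6h": 20, "24h": 17, "48h": 14, "72h": 12}

#: index (1-based within the 0h group) of the acquired-but-removed sample
QC_REMOVED = ("0h", 15)


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    subject_id: str
    group: str
    qc_flag: str = "pass"  # "pass" | "removed"


class SepsisClass(enum.IntEnum):
    """Ordered severity classes from the SIRS/sepsis rule set."""

    none = 0
    SIRS = 1
    sepsis = 2
    severe_sepsis = 3


@dataclass(frozen=True)
class VitalsRecord:
    body_temp_c: float
    heart_rate_bpm: float
    resp_rate_per_min: float
    pco2_mmhg: float
    wbc_per_mm3: float
    band_neutrophil_pct: float
    infection_present: bool = False
    organ_failures: int = 0

    def __post_init__(self) -> None:
        for name in ("body_temp_c", "heart_rate_bpm", "resp_rate_per_min",
                     "pco2_mmhg", "wbc_per_mm3", "band_neutrophil_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.organ_failures < 0:
            raise ValueError("organ_failures must be nonnegative")


def generate_manifest(
    group_sizes: dict[str, int] | None = None, seed: int = 0
) -> list[SampleRecord]:
    """Build the sample manifest, one record per (subject, time point).

    Healthy subjects appear only in Ha; diseased subjects share subject ids
    across time points (subjects drop out as the per-group n shrinks). With
    the default sizes the manifest has 113 records, of which one 0 h sample
    carries ``qc_flag="removed"``.
    """
    sizes = dict(DEFAULT_GROUP_SIZES if group_sizes is None else group_sizes)
    for g, n in sizes.items():
        if g not in GROUPS:
            raise ValueError(f"unknown group {g!r}")
        if n < 0:
            raise ValueError(f"group {g!r}: negative count")
    records: list[SampleRecord] = []
    for group in GROUPS:
        n = sizes.get(group, 0)
        prefix = "H" if group == "Ha" else "D"
        for i in range(1, n + 1):
            qc = "removed" if (group, i) == QC_REMOVED and sizes == DEFAULT_GROUP_SIZES else "pass"
            records.append(
                SampleRecord(
                    sample_id=f"{group}-{i:02d}",
                    subject_id=f"{prefix}{i:02d}",
                    group=group,
                    qc_flag=qc,
                )
            )
    return records


def manifest_frame(manifest: list[SampleRecord]) -> pd.DataFrame:
    """Manifest as a DataFrame (serialization schema)."""
    return pd.DataFrame(
        [
            {"sample_id": r.sample_id, "subject_id": r.subject_id,
             "group": r.group, "qc_flag": r.qc_flag}
            for r in manifest
        ]
    )


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Lognormal (μ, σ) whose first two moments equal ``(mean, sd**2)``.

    Closed-form moment match: σ² = ln(1 + sd²/mean²), μ = ln(mean) − σ²/2.
    ``sd = 0`` degenerates to a point mass at ``mean`` (σ = 0).
    """
    if mean <= 0:
        raise ValueError("lognormal moment match requires mean > 0")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample_concentrations(
    manifest: list[SampleRecord],
    library: MetaboliteLibrary,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-sample metabolite concentrations (μM, plasma scale).

    Returns a DataFrame indexed by sample_id with one column per library
    metabolite. Values are independent lognormal draws moment-matched to the
    sampled group's published (mean, SD).
    """
    rng = np.random.default_rng(seed)
    names = library.metabolite_names
    for rec in manifest:
        for met in library.metabolites:
            if rec.group not in met.group_distributions:
                raise ValueError(
                    f"group {rec.group!r} has no distribution for {met.name!r}"
                )
    values = np.empty((len(manifest), len(names)))
    for j, met in enumerate(library.metabolites):
        for i, rec in enumerate(manifest):
            mean, sd, _ = met.group_distributions[rec.group]
            mu, sigma = lognormal_params(mean, sd)
            values[i, j] = rng.lognormal(mu, sigma) if sigma > 0 else mean
    df = pd.DataFrame(values, columns=names, index=[r.sample_id for r in manifest])
    df.index.name = "sample_id"
    return df


def count_sirs_criteria(v: VitalsRecord) -> int:
    """Number of SIRS criteria met (0-4): temperature, heart rate,
    respiration/pCO₂, leukogram."""
    n = 0
    if v.body_temp_c > 39.0 or v.body_temp_c < 36.0:
        n += 1
    if v.heart_rate_bpm < 100.0 or v.heart_rate_bpm > 160.0:
        n += 1
    if v.resp_rate_per_min > 65.0 or v.pco2_mmhg > 50.0:
        n += 1
    if v.wbc_per_mm3 > 12000.0 or v.wbc_per_mm3 < 4000.0 or v.band_neutrophil_pct > 10.0:
        n += 1
    return n


def classify_sepsis(vitals: VitalsRecord) -> SepsisClass:
    """Rule classifier: SIRS (≥1 criterion), sepsis (≥2 criteria + infection),
    severe sepsis (all 4 criteria + infection + ≥1 organ failure)."""
    n = count_sirs_criteria(vitals)
    if n >= 4 and vitals.infection_present and vitals.organ_failures >= 1:
        return SepsisClass.severe_sepsis
    if n >= 2 and vitals.infection_present:
        return SepsisClass.sepsis
    if n >= 1:
        return SepsisClass.SIRS
    return SepsisClass.none


def simulate_vitals(group: str, rng: np.random.Generator) -> VitalsRecord:
    """Draw plausible vitals for a healthy or severely septic calf.

    Healthy draws sit mid-normal on every criterion; diseased draws reproduce
    the admission picture of severe sepsis (hypothermia-side temperature,
    tachypnea, leukocytosis, left shift, confirmed infection, organ failure).
    """
    if group == "Ha":
        return VitalsRecord(
            body_temp_c=rng.normal(38.6, 0.2),
            heart_rate_bpm=rng.normal(120, 8),
            resp_rate_per_min=rng.normal(40, 5),
            pco2_mmhg=rng.normal(42, 3),
            wbc_per_mm3=rng.normal(8000, 1000),
            band_neutrophil_pct=abs(rng.normal(2, 1)),
            infection_present=False,
            organ_failures=0,
        )
    return VitalsRecord(
        body_temp_c=rng.normal(35.5, 0.4),
        heart_rate_bpm=rng.normal(92, 6),
        resp_rate_per_min=rng.normal(72, 6),
        pco2_mmhg=rng.normal(54, 4),
        wbc_per_mm3=rng.normal(16000, 2500),
        band_neutrophil_pct=abs(rng.normal(14, 3)),
        infection_present=True,
        organ_failures=1 + int(rng.integers(0, 2)),
    )
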