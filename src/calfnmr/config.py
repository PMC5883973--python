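"""Single configuration schema for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .synthesis import DEFAULT_GROUP_SIZES

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    seed: int = 101
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    experiments: list = field(default_factory=lambda: ["noesy", "cpmg", "diffedit"])

    # acquisition
    larmor_mhz: float = 600.13
    n_points: int = 2**15
    spectral_width_ppm: float = 14.0
    noise_sd: float | None = None          # None -> simulator default
    shift_jitter_sd_ppm: float = 0.005
    peak_jitter_sd_ppm: float = 0.001
    t_cpmg_s: float = 0.1

    # processing
    lb_hz: float = 0.3
    bin_width: float = 0.02
    ppm_range: tuple = (0.2, 10.0)
    exclusions: list = field(default_factory=lambda: [[4.50, 5.00]])
    baseline_lam: float = 1e7
    baseline_p: float = 0.001

    # chemometrics: n_pred + n_orth = 10 total components retained;
    # feature_transform "glog" stabilizes the lognormal bin intensities
    n_pred: int = 6
    n_orth: int = 4
    cv_iterations: int = 100
    train_fraction: float = 0.9
    feature_transform: str = "glog"        # "glog" | "none"
    glog_lambda: float = 1e-6

    # quantification
    dioxane_uM: float = 100.0
    dilution_factor: float = 2.0

    # statistics
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.ppm_range = tuple(self.ppm_range)
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.bin_width <= 0 or self.lb_hz < 0 or self.alpha <= 0:
            raise ValueError("invalid processing/statistics parameters")
        if self.feature_transform not in ("glog", "none") or self.glog_lambda <= 0:
            raise ValueError("feature_transform must be 'glog' or 'none' with glog_lambda > 0")
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"group {g!r}: negative size")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    def as_dict(self) -> dict:
        d = asdict(self)
        d["ppm_range"] = list(d["ppm_range"])
        return d

    @property
    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.as_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream seed derived from the global seed.

        The derivation hashes the stage name so stages can be re-run in
        isolation; values stay below 2^31.
        """
        stage_id = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
        state = np.random.SeedSequence([self.seed, stage_id]).generate_state(1)[0]
        return int(state) & 0x7FFFFFFF
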