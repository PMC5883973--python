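"""Nonparametric group statistics: Kruskal–Wallis, Dunn post hoc, BH FDR.

Metabolite concentrations are compared across the seven study groups with the
rank-based Kruskal–Wallis test (tie-corrected H, χ² reference with k−1 df),
followed by Dunn's pairwise z tests on the pooled mean ranks with the
tie-corrected variance, and Benjamini–Hochberg step-up adjustment of the 21
pairwise p-values within each metabolite. Time points are treated as
independent groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .library import MetaboliteLibrary

__all__ = ["kruskal_wallis", "dunn_posthoc", "bh_adjust", "build_stat_table",
           "StatTable"]


def _group_arrays(values, group_labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = list(dict.fromkeys(labels.tolist()))  # preserve first-appearance order
    arrays = [values[labels == g] for g in groups]
    for g, a in zip(groups, arrays):
        if len(a) == 0:
            raise ValueError(f"group {g!r} has no observations")
    return groups, arrays


def kruskal_wallis(values, group_labels) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its χ²(k−1) p-value.

    Degenerate input (all values identical) returns (0.0, 1.0).
    """
    groups, arrays = _group_arrays(values, group_labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*arrays)
    return float(h), float(p)


def dunn_posthoc(values, group_labels) -> pd.DataFrame:
    """Dunn's pairwise post hoc z tests on pooled mean ranks.

    For groups i, j:

        z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T) · (1/n_i + 1/n_j)),
        T = Σ(t³ − t) / (12(N − 1))   over tie groups of size t,

    with two-sided p from the standard normal. Returns one row per unordered
    pair (all C(k,2) combinations) with columns group1, group2, z, p.
    """
    groups, arrays = _group_arrays(values, group_labels)
    flat = np.concatenate(arrays)
    n = len(flat)
    ranks = scipy.stats.rankdata(flat)
    offsets = np.cumsum([0] + [len(a) for a in arrays])
    mean_ranks = {
        g: ranks[offsets[i]:offsets[i + 1]].mean() for i, g in enumerate(groups)
    }
    _, counts = np.unique(flat, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term

    rows = []
    sizes = {g: len(a) for g, a in zip(groups, arrays)}
    for g1, g2 in itertools.combinations(groups, 2):
        denom = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        if denom == 0:
            z = 0.0
        else:
            z = (mean_ranks[g1] - mean_ranks[g2]) / denom
        p = 2.0 * scipy.stats.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": float(z), "p": min(1.0, float(p))})
    return pd.DataFrame(rows)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


@dataclass
class StatTable:
    """Per-metabolite group summary and pairwise test results."""

    summary: pd.DataFrame    # metabolite × group "mean ± sd" plus KW stat/p
    pairwise: pd.DataFrame   # long format: metabolite, group1, group2, z, p, p_adj, significant
    alpha: float

    def significant_metabolites(self) -> list[str]:
        sig = self.pairwise[self.pairwise["significant"]]
        return sorted(sig["metabolite"].unique())


def build_stat_table(
    concentrations: pd.DataFrame,
    manifest,
    alpha: float = 0.05,
    family: str = "per_metabolite",
) -> StatTable:
    """Kruskal–Wallis + Dunn + BH over a samples × metabolites table.

    ``manifest`` supplies group labels and the QC flag (removed samples are
    excluded). The BH family is the 21 pairwise comparisons within one
    metabolite by default; ``family="global"`` pools all metabolites' pairs
    into one family instead.
    """
    if family not in ("per_metabolite", "global"):
        raise ValueError("family must be 'per_metabolite' or 'global'")
    by_id = {r.sample_id: r for r in manifest}
    keep = [sid for sid in concentrations.index
            if by_id[sid].qc_flag == "pass"]
    data = concentrations.loc[keep]
    labels = np.array([by_id[sid].group for sid in keep])
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 groups")

    summary_rows = []
    pair_frames = []
    for met in data.columns:
        vals = data[met].to_numpy(dtype=float)
        h, p = kruskal_wallis(vals, labels)
        row = {"metabolite": met, "kw_statistic": h, "kw_p": p}
        for g in dict.fromkeys(labels.tolist()):
            gv = vals[labels == g]
            row[g] = f"{gv.mean():.1f} ± {gv.std(ddof=1):.1f}"
        summary_rows.append(row)

        pw = dunn_posthoc(vals, labels)
        pw.insert(0, "metabolite", met)
        pair_frames.append(pw)

    pairwise = pd.concat(pair_frames, ignore_index=True)
    if family == "per_metabolite":
        pairwise["p_adj"] = np.concatenate(
            [bh_adjust(f["p"].to_numpy()) for f in pair_frames]
        )
    else:
        pairwise["p_adj"] = bh_adjust(pairwise["p"].to_numpy())
    pairwise["significant"] = pairwise["p_adj"] < alpha
    return StatTable(
        summary=pd.DataFrame(summary_rows),
        pairwise=pairwise,
        alpha=alpha,
    )
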