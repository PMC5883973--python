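"""Minimal hypergeometric over-representation analysis of metabolite sets.

For each packaged pathway the enrichment p-value is the hypergeometric upper
tail P(X ≥ hits) for drawing ``significant_size`` metabolites from a
background of quantified metabolites containing ``pathway_size`` pathway
members. This is a deliberately minimal stand-in for topology-aware pathway
analysis: only enrichment is computed, and the default background is the 22
quantified metabolites rather than a full compound database.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from scipy.stats import hypergeom

from .library import MetaboliteLibrary, PathwaySet

__all__ = ["PathwayResult", "ora"]


@dataclass(frozen=True)
class PathwayResult:
    pathway: str
    hits: int
    pathway_size: int
    background_size: int
    significant_size: int
    p: float


def ora(
    significant_metabolites: Iterable[str],
    pathways: Iterable[PathwaySet],
    background: Iterable[str],
    library: MetaboliteLibrary | None = None,
) -> list[PathwayResult]:
    """Hypergeometric enrichment of significant metabolites in each pathway.

    Names are resolved through the library synonym map when a library is
    given. Results are sorted by p-value with a deterministic name tie-break.
    """
    resolve = library.resolve_name if library is not None else (lambda x: x)
    bg = {resolve(m) for m in background}
    if not bg:
        raise ValueError("background set must not be empty")
    sig = {resolve(m) for m in significant_metabolites}
    if not sig <= bg:
        raise ValueError("significant set must be a subset of the background")

    results = []
    for pw in pathways:
        members = {resolve(m) for m in pw.members} & bg
        hits = len(members & sig)
        # P(X >= hits), X ~ Hypergeom(M=|bg|, K=|members|, N=|sig|)
        p = float(hypergeom.sf(hits - 1, len(bg), len(members), len(sig)))
        results.append(
            PathwayResult(
                pathway=pw.name,
                hits=hits,
                pathway_size=len(members),
                background_size=len(bg),
                significant_size=len(sig),
                p=min(1.0, p),
            )
        )
    return sorted(results, key=lambda r: (r.p, r.pathway))
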