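"""Over-representation of a reference gene set among screen hits.

An exact hypergeometric tail test: given a universe of N genes of which K
belong to the reference set (e.g. known parkin interactors), the p value of
observing k or more reference genes in a hit list of size n is
``P(X >= k)`` for X ~ Hypergeometric(N, K, n).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable

from scipy import stats

from .errors import EmptyInputError


@dataclasses.dataclass(frozen=True)
class EnrichmentResult:
    universe_size: int  # N
    reference_size: int  # K (after intersecting with the universe)
    hit_size: int  # n
    overlap: int  # k
    p_value: float
    fold_enrichment: float
    reference_dropped: int  # reference genes absent from the universe


def hypergeom_enrichment(
    hits: Iterable[str], reference: Iterable[str], universe: Iterable[str]
) -> EnrichmentResult:
    """One-sided over-representation test of ``reference`` within ``hits``.

    ``hits`` must be a subset of ``universe``; reference genes outside the
    universe are dropped (and counted) before testing.
    """
    universe = set(universe)
    hits = set(hits)
    reference_all = set(reference)
    if not universe:
        raise EmptyInputError("empty universe")
    if not hits:
        raise EmptyInputError("empty hit list")
    stray = hits - universe
    if stray:
        raise ValueError(f"hits outside the universe: {sorted(stray)[:5]} ...")
    reference_in = reference_all & universe
    N, K, n = len(universe), len(reference_in), len(hits)
    k = len(hits & reference_in)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    fold = (k / n) / (K / N) if K > 0 else float("nan")
    return EnrichmentResult(
        universe_size=N,
        reference_size=K,
        hit_size=n,
        overlap=k,
        p_value=p,
        fold_enrichment=fold,
        reference_dropped=len(reference_all - reference_in),
    )
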