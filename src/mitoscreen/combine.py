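"""Cross-screen weighted scoring, concordance counting and top-fraction cuts.

Primary- and secondary-screen effect measures (PCA consensus scores, PLS
SSMDs) live on study-specific scales, so each measure vector is first
normalized to its own absolute maximum.  The weighted score of a gene is
the arithmetic mean of its available normalized measures: a gene behaving
oppositely across studies is automatically shrunk toward zero, which is the
intended penalty.  Because SSMD and the consensus score are effect
measures — not significance measures — this averaging is meaningful.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError
from .workflows import HIT_NEGATIVE, HIT_NONE, HIT_POSITIVE, SECONDARY_THRESHOLD


def normalize_measures(measures: Mapping[str, pd.Series]) -> dict[str, pd.Series]:
    """Divide each measure vector by its own maximum absolute value."""
    out = {}
    for name, series in measures.items():
        series = pd.Series(series, dtype=float)
        peak = series.abs().max()
        if not np.isfinite(peak) or peak == 0:
            raise EmptyInputError(f"measure {name!r} has no nonzero value to normalize by")
        out[name] = series / peak
    return out


def weighted_score(measures: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Per-gene mean of the available (already normalized) measures.

    Input measures may cover different gene sets (e.g. only the top primary
    hits were carried to the secondary screen); each gene is averaged over
    the measures it has.  Callers normalize first (see
    :func:`normalize_measures` or :func:`build_weighted_table`).
    """
    table = pd.DataFrame(dict(measures))
    if table.empty:
        raise EmptyInputError("no measures supplied")
    table = table.rename(columns=lambda c: f"norm_{c}")
    table["weighted_score"] = table.mean(axis=1, skipna=True)
    table["n_measures"] = table.drop(columns="weighted_score").notna().sum(axis=1)
    return table.sort_values("weighted_score", ascending=False)


def select_top_fraction(table: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Flag the top and bottom ``fraction`` of genes by weighted score.

    ``ceil(fraction * n)`` genes are taken from each end.  Ties at the
    boundary break deterministically by larger |score|, then lexicographic
    gene id, so row order never matters.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    if table.empty:
        raise EmptyInputError("empty score table")
    n_take = int(np.ceil(fraction * len(table)))
    scores = table["weighted_score"]
    order = pd.DataFrame(
        {"score": scores, "abs": scores.abs(), "gene": table.index.astype(str)}
    )
    top = order.sort_values(["score", "abs", "gene"], ascending=[False, False, True]).index[:n_take]
    bottom = order.sort_values(["score", "abs", "gene"], ascending=[True, False, True]).index[:n_take]
    out = table.copy()
    out["selected"] = HIT_NONE
    out.loc[top, "selected"] = HIT_POSITIVE
    out.loc[bottom, "selected"] = HIT_NEGATIVE
    return out


def concordance_count(
    secondary_ssmd: pd.DataFrame,
    primary_direction: pd.Series,
    threshold: float = SECONDARY_THRESHOLD,
    gene_col: str = "gene_id",
    ssmd_col: str = "ssmd",
) -> pd.Series:
    """Per-gene count of secondary siRNAs confirming the primary direction.

    A secondary siRNA confirms when ``|SSMD| > threshold`` and its sign
    matches the gene's primary-screen direction (+1/-1).  Genes with an
    unknown primary direction count zero and are reported via the returned
    series' name-level metadata (their count is 0 by construction).
    """
    counts = {}
    for gene, grp in secondary_ssmd.groupby(gene_col, observed=True):
        if len(grp) > 3:
            raise ValueError(f"gene {gene!r} has more than 3 secondary siRNAs")
        direction = primary_direction.get(gene, np.nan)
        if not np.isfinite(direction) or direction == 0:
            counts[gene] = 0
            continue
        s = grp[ssmd_col].to_numpy(dtype=float)
        counts[gene] = int(np.sum((np.abs(s) > threshold) & (np.sign(s) == np.sign(direction))))
    return pd.Series(counts, name="concordant_sirna_count").rename_axis(gene_col)


def direction_from_flags(flags: pd.Series) -> pd.Series:
    """Map hit flags to +1 / -1 / 0 directions."""
    return flags.map({HIT_POSITIVE: 1.0, HIT_NEGATIVE: -1.0, HIT_NONE: 0.0})


def build_weighted_table(
    primary_measures: Mapping[str, pd.Series],
    secondary_measures: Mapping[str, pd.Series] | None = None,
    fraction: float = 0.10,
) -> pd.DataFrame:
    """Convenience: normalize, average, and cut the top/bottom fraction."""
    measures = dict(primary_measures)
    if secondary_measures:
        measures.update(secondary_measures)
    return select_top_fraction(weighted_score(normalize_measures(measures)), fraction)
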