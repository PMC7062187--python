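"""Univariate and PCA hit-selection workflows.

Both workflows score each silenced gene by SSMD against the negative
controls of its own plate.  The univariate workflow reports a hit list per
lead readout; the PCA workflow condenses the three per-parameter SSMD
vectors into one consensus score via a one-component (uncentred) singular
value decomposition and thresholds that.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateModelError, FitError, PlateLookupError
from .robust import series_s0_squared, ssmd_gene, ssmd_qc
from .screen import NAMED_READOUTS, ROLE_NEGATIVE, ROLE_POSITIVE, ROLE_SAMPLE, ScreenDataset

HIT_POSITIVE = "positive_hit"
HIT_NEGATIVE = "negative_hit"
HIT_NONE = "none"

PRIMARY_THRESHOLD = 3.0
SECONDARY_THRESHOLD = 1.3

#: Candidate readouts considered when choosing the control-separating trio:
#: the three recruitment readouts plus three morphology-style fillers that
#: do not separate the controls.
DEFAULT_CANDIDATES = (
    "pct_cells_gt3_puncta",
    "puncta_area_per_cell",
    "puncta_intensity_per_cell",
    "param_70",
    "param_75",
    "param_80",
)


def _gene_ssmd_series(meta: pd.DataFrame, values: pd.Series, key: str) -> pd.Series:
    """Per-gene (or per-siRNA) SSMD of one value column.

    For each key, the well values across plate replicates form the "well"
    vector; the negative controls of the same plates (all surviving
    replicates pooled) form the reference; ``s0^2`` is the pooled replicate
    variance of the value column over all wells.
    """
    s0sq = series_s0_squared(meta, values)
    is_neg = meta["role"] == ROLE_NEGATIVE
    neg_by_plate = {
        plate: values[is_neg & (meta["plate_id"] == plate)].to_numpy(dtype=float)
        for plate in meta.loc[is_neg, "plate_id"].unique()
    }
    is_sample = meta["role"] == ROLE_SAMPLE
    out: dict[str, float] = {}
    grouped = meta[is_sample].groupby(key, observed=True, sort=True)
    for gene, idx in grouped.groups.items():
        well_vals = values.loc[idx].to_numpy(dtype=float)
        plates = meta.loc[idx, "plate_id"].unique()
        neg = np.concatenate([neg_by_plate.get(p, np.empty(0)) for p in plates]) if len(plates) else np.empty(0)
        out[gene] = ssmd_gene(well_vals, neg, s0sq).value
    return pd.Series(out, name="ssmd").rename_axis(key)


def gene_ssmd_table(
    dataset: ScreenDataset, parameters: Sequence[str], key: str = "gene_id"
) -> pd.DataFrame:
    """Genes x parameters table of per-gene SSMD values."""
    unknown = [p for p in parameters if p not in dataset.parameter_names]
    if unknown:
        raise PlateLookupError(f"parameters not in registry: {unknown}")
    meta = dataset.wells[["plate_id", "replicate", "well", "role", key]]
    cols = {p: _gene_ssmd_series(meta, dataset.wells[p], key) for p in parameters}
    return pd.DataFrame(cols)


def flag_hits(scores: pd.Series, threshold: float) -> pd.Series:
    """Strict-threshold hit flags: ``score > t`` positive, ``score < -t`` negative."""
    flags = pd.Series(HIT_NONE, index=scores.index, dtype=object)
    flags[scores > threshold] = HIT_POSITIVE
    flags[scores < -threshold] = HIT_NEGATIVE
    return flags


# backwards-friendly aliases used throughout tests and the CLI
pca_hits = flag_hits


def univariate_hits(
    dataset: ScreenDataset,
    parameters: Sequence[str] = NAMED_READOUTS,
    threshold: float = PRIMARY_THRESHOLD,
    key: str = "gene_id",
) -> pd.DataFrame:
    """Per-parameter SSMD hit lists on the named lead readouts.

    Returns one row per gene with ``ssmd_<param>`` and ``hit_<param>``
    columns plus a combined ``univariate_hit`` flag: a gene is a hit if any
    of the lead readouts crosses the threshold (ties of direction resolved
    by the largest |SSMD|).
    """
    table = gene_ssmd_table(dataset, parameters, key=key)
    out = table.add_prefix("ssmd_")
    for p in parameters:
        out[f"hit_{p}"] = flag_hits(table[p], threshold)
    extreme = table.to_numpy()[np.arange(len(table)), np.abs(table.to_numpy()).argmax(axis=1)]
    combined = pd.Series(extreme, index=table.index)
    combined[np.abs(table).max(axis=1) <= threshold] = 0.0
    out["univariate_hit"] = flag_hits(combined, 0.0).where(combined != 0.0, HIT_NONE)
    return out


def select_parameters(
    dataset: ScreenDataset,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    n_select: int = 3,
    override: Sequence[str] | None = None,
) -> list[str]:
    """Choose the readouts that best separate positive from negative controls.

    Candidates are ranked by the median absolute plate-wise control SSMD;
    the top ``n_select`` are returned.  ``override`` short-circuits the
    ranking and is returned verbatim (after registry validation).
    """
    if override is not None:
        unknown = [p for p in override if p not in dataset.parameter_names]
        if unknown:
            raise PlateLookupError(f"override parameters not in registry: {unknown}")
        return list(override)
    usable = [p for p in candidates if p in dataset.parameter_names]
    if len(usable) < n_select:
        raise FitError(f"need >= {n_select} usable candidates, got {len(usable)}")
    wells = dataset.wells
    scores = {}
    for p in usable:
        per_plate = []
        for plate_id, replicate in dataset.plate_replicates():
            sel = (wells["plate_id"] == plate_id) & (wells["replicate"] == replicate)
            pos = wells.loc[sel & (wells["role"] == ROLE_POSITIVE), p]
            neg = wells.loc[sel & (wells["role"] == ROLE_NEGATIVE), p]
            if pos.notna().sum() >= 2 and neg.notna().sum() >= 2:
                per_plate.append(abs(ssmd_qc(pos, neg).value))
        if not per_plate:
            raise FitError(f"no plate has both control classes for {p!r}")
        scores[p] = float(np.median(per_plate))
    ranked = sorted(usable, key=lambda p: (-scores[p], p))
    return ranked[:n_select]


@dataclasses.dataclass(frozen=True)
class PCAModel:
    """One-component uncentred SVD of the genes x parameters SSMD matrix."""

    loadings: pd.Series  # unit-norm loading vector W
    singular_values: np.ndarray
    explained_variance: float
    sign_anchor: str


def pca_score(
    ssmd_matrix: pd.DataFrame, sign_anchor: str = "pct_cells_gt3_puncta"
) -> tuple[pd.Series, PCAModel]:
    """Consensus SSMD via the first component of an uncentred SVD.

    With ``X = U D V^T``, the score vector is ``H = u1 * d1`` and the loading
    ``W = v1``; ``X ~= H W^T``.  The matrix is neither centred nor scaled:
    SSMDs share a dimensionless scale and a zero score must mean "no
    effect".  The SVD sign ambiguity is resolved by making the loading on
    ``sign_anchor`` (the lead recruitment readout) positive, so positive
    scores mean more recruitment.  Genes with missing SSMDs are dropped.
    """
    clean = ssmd_matrix.dropna()
    if len(clean) < 2:
        raise DegenerateModelError("need >= 2 complete gene rows for the consensus score")
    X = clean.to_numpy(dtype=float)
    if not np.any(X):
        raise DegenerateModelError("all-zero SSMD matrix has no principal direction")
    U, D, Vt = np.linalg.svd(X, full_matrices=False)
    w = Vt[0]
    h = U[:, 0] * D[0]
    anchor_idx = list(clean.columns).index(sign_anchor) if sign_anchor in clean.columns else 0
    if w[anchor_idx] < 0:
        w, h = -w, -h
    explained = float(D[0] ** 2 / np.sum(D**2))
    model = PCAModel(
        loadings=pd.Series(w, index=clean.columns, name="loading"),
        singular_values=D.copy(),
        explained_variance=explained,
        sign_anchor=clean.columns[anchor_idx],
    )
    return pd.Series(h, index=clean.index, name="pca_score"), model


def pca_workflow(
    dataset: ScreenDataset,
    parameters: Sequence[str] | None = None,
    threshold: float = PRIMARY_THRESHOLD,
    key: str = "gene_id",
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
) -> tuple[pd.DataFrame, PCAModel]:
    """Full PCA workflow on a corrected, QC-passed dataset.

    Selects the control-separating trio (unless given), computes per-gene
    SSMDs, condenses them to the consensus score and flags hits at
    ``+-threshold``.
    """
    if parameters is None:
        parameters = select_parameters(dataset, candidates)
    table = gene_ssmd_table(dataset, parameters, key=key)
    scores, model = pca_score(table)
    out = table.add_prefix("ssmd_").loc[scores.index]
    out["pca_score"] = scores
    out["pca_hit"] = flag_hits(scores, threshold)
    return out, model
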