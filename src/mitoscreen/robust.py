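"""Robust effect-size primitives: MAD, plate-QC SSMD and per-gene SSMD.

The strictly standardized mean difference (SSMD) is the screen field's
effect-size statistic: a difference of locations over the square root of the
summed squared scale estimates.  Two variants are used here:

* a robust plate-quality score comparing positive- against negative-control
  wells with medians and MADs, and
* a per-gene score comparing a gene's replicate well values against the
  negative controls, with a pooled replicate-variance floor ``s0^2``.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .errors import EmptyInputError, InsufficientReplicationError

#: Reciprocal of the standard-normal third quartile; makes the MAD a
#: consistent estimate of the standard deviation under normality.
MAD_CONSTANT = 1.4826


def _finite(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    return arr[np.isfinite(arr)]


def mad(values) -> float:
    """Scaled median absolute deviation, ``1.4826 * median(|x - median(x)|)``.

    Missing (NaN/inf) values are dropped first.  Raises
    :class:`EmptyInputError` when no finite value remains.
    """
    arr = _finite(values)
    if arr.size == 0:
        raise EmptyInputError("mad() of an all-missing vector")
    med = np.median(arr)
    return float(MAD_CONSTANT * np.median(np.abs(arr - med)))


@dataclasses.dataclass(frozen=True)
class SSMDValue:
    """A dimensionless SSMD with provenance of its operands."""

    value: float
    kind: str  # "qc" or "gene"
    operands: dict

    def __float__(self) -> float:
        return self.value


def ssmd_qc(positive, negative) -> SSMDValue:
    """Plate-quality SSMD: ``(med(pos) - med(neg)) / sqrt(MAD(pos)^2 + MAD(neg)^2)``.

    A very strong positive control (recruitment abolished) drives this far
    negative; plates above the -2 cut-off are considered unreliable.
    """
    pos = _finite(positive)
    neg = _finite(negative)
    if pos.size < 2 or neg.size < 2:
        raise EmptyInputError("ssmd_qc needs >= 2 finite values per control class")
    num = float(np.median(pos) - np.median(neg))
    denom = float(np.hypot(mad(pos), mad(neg)))
    if denom == 0.0:
        if num == 0.0:
            value = 0.0
            warnings.warn("ssmd_qc: zero spread and zero difference; defining SSMD = 0")
        else:
            value = float(np.sign(num)) * np.inf
            warnings.warn("ssmd_qc: zero spread with nonzero difference; returning signed infinity")
    else:
        value = num / denom
    return SSMDValue(value, "qc", {"n_pos": int(pos.size), "n_neg": int(neg.size)})


def ssmd_gene(well_values, negative_values, s0_squared: float) -> SSMDValue:
    """Per-gene SSMD against the negative controls of the same plates.

    ``(med(well) - med(neg)) / sqrt(s_well^2 / 2 + s0^2 / 2)`` where
    ``s_well^2`` is the across-replicate variance (n-1 denominator) of the
    gene's well and ``s0^2`` is the pooled replicate variance supplied by
    the caller (see :func:`pooled_s0_squared`).
    """
    well = _finite(well_values)
    neg = _finite(negative_values)
    if well.size < 2:
        raise InsufficientReplicationError("ssmd_gene needs >= 2 finite replicate values")
    if neg.size == 0:
        raise EmptyInputError("ssmd_gene: no finite negative-control values")
    if s0_squared < 0:
        raise ValueError("s0_squared must be >= 0")
    num = float(np.median(well) - np.median(neg))
    s2_well = float(np.var(well, ddof=1))
    denom = float(np.sqrt(0.5 * s2_well + 0.5 * s0_squared))
    if denom == 0.0:
        if num == 0.0:
            value = 0.0
            warnings.warn("ssmd_gene: zero spread and zero difference; defining SSMD = 0")
        else:
            value = float(np.sign(num)) * np.inf
            warnings.warn("ssmd_gene: zero spread with nonzero difference; returning signed infinity")
    else:
        value = num / denom
    return SSMDValue(
        value, "gene", {"n_well": int(well.size), "n_neg": int(neg.size), "s0_squared": float(s0_squared)}
    )


def pooled_s0_squared(dataset, parameter: str) -> float:
    """Median over wells of the squared across-replicate S.D. of ``parameter``.

    This pools the replicate variability of every well of the screen into a
    single robust variance floor for the per-gene SSMD denominator.
    """
    from .screen import ScreenDataset  # local import to avoid cycle

    assert isinstance(dataset, ScreenDataset)
    if parameter not in dataset.parameter_names:
        raise KeyError(f"unknown parameter {parameter!r}")
    wells = dataset.wells
    grouped = wells.groupby(["plate_id", "well"], observed=True)[parameter]
    counts = grouped.count()
    if (counts < 2).all():
        raise InsufficientReplicationError("pooled_s0_squared needs >= 2 replicates per plate")
    variances = grouped.var(ddof=1).dropna()  # NaN where < 2 finite replicates
    if variances.empty:
        raise InsufficientReplicationError("no well has >= 2 finite replicate values")
    return float(np.median(variances.to_numpy()))


def series_s0_squared(meta, values) -> float:
    """Pooled ``s0^2`` for an arbitrary per-well score series.

    ``meta`` must supply ``plate_id`` and ``well`` columns aligned with
    ``values``; the replicate structure is recovered from repeated
    (plate, well) pairs.
    """
    import pandas as pd

    df = pd.DataFrame({"plate_id": meta["plate_id"], "well": meta["well"], "v": np.asarray(values, float)})
    variances = df.groupby(["plate_id", "well"], observed=True)["v"].var(ddof=1).dropna()
    if variances.empty:
        raise InsufficientReplicationError("score series has no replicated wells")
    return float(np.median(variances.to_numpy()))
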