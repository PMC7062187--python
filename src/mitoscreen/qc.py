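"""Plate-quality gating by control-separation SSMD.

A plate replicate passes only if its positive controls (recruitment
abolished) separate from the negative controls strongly enough:
``SSMD_QC <= -2``, the conventional cut-off for very strong positive
controls.  The gate can run on a raw readout column or on any per-well
score series (the supervised workflow gates on model scores).
"""

from __future__ import annotations

import pandas as pd

from .errors import EmptyInputError
from .robust import ssmd_qc
from .screen import ROLE_NEGATIVE, ROLE_POSITIVE, ScreenDataset

QC_CUTOFF = -2.0


def qc_screen(
    dataset: ScreenDataset,
    readout,
    cutoff: float = QC_CUTOFF,
) -> tuple[pd.DataFrame, ScreenDataset]:
    """Gate plate replicates on control separation.

    Parameters
    ----------
    dataset
        The (artifact-corrected) screen.
    readout
        Either a parameter name, or a :class:`pandas.Series` of per-well
        scores aligned with ``dataset.wells.index``.
    cutoff
        Pass iff ``SSMD_QC <= cutoff`` (default -2).

    Returns
    -------
    report : DataFrame
        One row per plate replicate: ``plate_id, replicate, score_name,
        ssmd_qc, n_pos, n_neg, passed``.  Plate replicates missing a control
        role are reported with NaN and removed.
    filtered : ScreenDataset
        The dataset restricted to passing plate replicates.
    """
    wells = dataset.wells
    if isinstance(readout, str):
        if readout not in dataset.parameter_names:
            raise KeyError(f"unknown readout {readout!r}")
        values = wells[readout]
        score_name = readout
    else:
        values = pd.Series(readout, index=wells.index, dtype=float)
        score_name = getattr(readout, "name", None) or "score"

    rows = []
    keep = pd.Series(False, index=wells.index)
    for plate_id, replicate in dataset.plate_replicates():
        sel = (wells["plate_id"] == plate_id) & (wells["replicate"] == replicate)
        pos = values[sel & (wells["role"] == ROLE_POSITIVE)]
        neg = values[sel & (wells["role"] == ROLE_NEGATIVE)]
        try:
            score = ssmd_qc(pos, neg)
            value = score.value
            n_pos, n_neg = score.operands["n_pos"], score.operands["n_neg"]
            passed = bool(value <= cutoff)
        except EmptyInputError:
            value, n_pos, n_neg, passed = float("nan"), int(pos.notna().sum()), int(neg.notna().sum()), False
        rows.append(
            {
                "plate_id": plate_id,
                "replicate": replicate,
                "score_name": score_name,
                "ssmd_qc": value,
                "n_pos": n_pos,
                "n_neg": n_neg,
                "passed": passed,
            }
        )
        if passed:
            keep |= sel
    report = pd.DataFrame(
        rows, columns=["plate_id", "replicate", "score_name", "ssmd_qc", "n_pos", "n_neg", "passed"]
    )
    return report, dataset.subset(keep)
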