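"""Per-plate row/column systematic-artifact correction.

Dispense order, evaporation and edge effects leave near-linear intensity
gradients across microtiter plates.  Following the screen-statistics
literature, each plate replicate is fitted with a robust linear model of the
readout against row and column numbers, and the slope components are
subtracted.  Row/column covariates are centred on the plate middle so the
correction leaves the plate median essentially unchanged; the intercept is
retained.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import statsmodels.api as sm

from .errors import FitError, PlateLookupError
from .screen import ScreenDataset, well_to_rc

ROW_CENTER = 4.5  # mean of rows 1..8
COL_CENTER = 6.5  # mean of columns 1..12


@dataclasses.dataclass(frozen=True)
class ArtifactFit:
    """Robust linear gradient fitted to one (plate, replicate, parameter)."""

    plate_id: str
    replicate: int
    parameter: str
    row_slope: float
    col_slope: float
    intercept: float
    converged: bool

    def trend(self, rows, cols) -> np.ndarray:
        """The positional term removed by the correction (centred covariates)."""
        rows = np.asarray(rows, dtype=float)
        cols = np.asarray(cols, dtype=float)
        return self.row_slope * (rows - ROW_CENTER) + self.col_slope * (cols - COL_CENTER)


def fit_plate_artifact(
    rows,
    cols,
    values,
    plate_id: str = "",
    replicate: int = 0,
    parameter: str = "",
) -> ArtifactFit:
    """Huber M-estimation fit of ``value ~ 1 + row + col`` on one plate.

    Uses iteratively reweighted least squares with the conventional
    95%-efficiency Huber tuning, so a handful of gross outlier wells cannot
    drag the slope estimates the way ordinary least squares would.
    """
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    rows, cols, values = rows[ok], cols[ok], values[ok]
    if values.size < 6:
        raise FitError("need >= 6 finite wells to fit a row/column gradient")
    X = np.column_stack([np.ones_like(rows), rows - ROW_CENTER, cols - COL_CENTER])
    if np.linalg.matrix_rank(X) < 3:
        raise FitError("rank-deficient design: wells span a single row or column")
    model = sm.RLM(values, X, M=sm.robust.norms.HuberT())
    res = model.fit()
    converged = bool(np.all(np.isfinite(res.params)))
    return ArtifactFit(
        plate_id=plate_id,
        replicate=replicate,
        parameter=parameter,
        intercept=float(res.params[0]),
        row_slope=float(res.params[1]),
        col_slope=float(res.params[2]),
        converged=converged,
    )


def correct_dataset(
    dataset: ScreenDataset, parameters: Sequence[str] | None = None
) -> tuple[ScreenDataset, list[ArtifactFit]]:
    """Remove fitted row/column gradients from every plate replicate.

    All wells (controls included) are corrected: the artifact is positional,
    not biological.  Defaults to correcting every registered parameter.
    Returns the corrected dataset and the list of per-plate fits.
    """
    if parameters is None:
        parameters = dataset.parameter_names
    unknown = [p for p in parameters if p not in dataset.parameter_names]
    if unknown:
        raise PlateLookupError(f"parameters not in registry: {unknown}")

    out = dataset.copy()
    wells = out.wells
    rc = np.array([well_to_rc(w) for w in wells["well"]], dtype=float).reshape(-1, 2)
    rows_all, cols_all = rc[:, 0], rc[:, 1]
    fits: list[ArtifactFit] = []
    for plate_id, replicate in out.plate_replicates():
        sel = ((wells["plate_id"] == plate_id) & (wells["replicate"] == replicate)).to_numpy()
        r, c = rows_all[sel], cols_all[sel]
        for param in parameters:
            v = wells.loc[sel, param].to_numpy(dtype=float)
            fit = fit_plate_artifact(r, c, v, plate_id, replicate, param)
            fits.append(fit)
            wells.loc[sel, param] = v - fit.trend(r, c)
    return out, fits
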