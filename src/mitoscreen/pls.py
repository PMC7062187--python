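"""Parameter-agnostic hit selection via partial least squares.

The supervised workflow needs no manual choice of readouts: it learns a
control-separating axis from all parameters.  Stages, in order:

1. feature selection — Welch t tests per parameter between positive and
   negative controls, Benjamini-Hochberg adjusted, keep FDR <= 0.05;
2. control outlier removal — Hotelling's T^2 in a principal-component
   subspace capturing >= 90% of the control variance, 99% F limit;
3. a cross-validated PLS regression of the control label (-1 = negative
   control, +1 = positive control) on the selected readouts;
4. per-well score prediction for every well, plate QC on those scores;
5. a second PLS model on the surviving plates whose scores feed the
   per-gene SSMD and the usual strict thresholds.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .errors import FitError
from .qc import QC_CUTOFF, qc_screen
from .robust import series_s0_squared, ssmd_gene
from .screen import ROLE_NEGATIVE, ROLE_POSITIVE, ROLE_SAMPLE, ScreenDataset
from .workflows import PRIMARY_THRESHOLD, flag_hits

LABEL_CODING = {ROLE_NEGATIVE: -1.0, ROLE_POSITIVE: 1.0}


def select_features(
    controls: pd.DataFrame, labels: Sequence, fdr: float = 0.05
) -> pd.DataFrame:
    """Welch t test per parameter between control classes, BH-adjusted.

    Returns a DataFrame indexed by parameter with columns ``t, p, p_adj,
    selected``.  A parameter constant in both classes gets p = 1 and is
    never selected.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise FitError(f"need exactly 2 control classes, got {classes.tolist()}")
    a = controls[labels == classes[0]].to_numpy(dtype=float)
    b = controls[labels == classes[1]].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise FitError("need >= 2 wells per control class")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    if fdr > 0:
        selected, p_adj, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    else:
        p_adj = np.minimum(1.0, p * len(p))
        selected = np.zeros(len(p), dtype=bool)
    return pd.DataFrame(
        {"t": t, "p": p, "p_adj": p_adj, "selected": selected}, index=controls.columns
    )


def remove_outlier_controls(
    controls: pd.DataFrame, confidence: float = 0.99, var_explained: float = 0.90
) -> pd.DataFrame:
    """Hotelling's T^2 outlier flags for control wells.

    The raw covariance of 84 readouts over a few dozen control wells is
    singular, so T^2 is computed in the principal-component subspace
    capturing at least ``var_explained`` of the control variance (capped so
    the F limit keeps positive denominator degrees of freedom).  Flagged
    wells are excluded from model training.
    """
    X = controls.to_numpy(dtype=float)
    n = len(X)
    if n < 3:
        raise FitError("need >= 3 control wells for outlier detection")
    Xc = X - X.mean(axis=0)
    U, D, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = D**2 / (n - 1)
    positive = lam > max(lam[0], 1.0) * 1e-12
    if not positive.any():
        raise FitError("zero-variance controls: no subspace for outlier detection")
    frac = np.cumsum(lam) / lam.sum()
    a = int(np.searchsorted(frac, var_explained) + 1)
    a = min(a, int(positive.sum()), n - 2)
    a = max(a, 1)
    scores = U[:, :a] * D[:a]
    t2 = np.sum(scores**2 / lam[:a], axis=1)
    limit = a * (n - 1) / (n - a) * stats.f.ppf(confidence, a, n - a)
    return pd.DataFrame(
        {"t2": t2, "limit": limit, "excluded": t2 > limit}, index=controls.index
    )


@dataclasses.dataclass
class PLSModel:
    """A fitted control-label PLS model and its provenance."""

    estimator: PLSRegression
    selected_parameters: list[str]
    n_components: int
    cv_error: float
    cv_curve: list[float]
    training_index: pd.Index

    # Bilinear decomposition views (X = T P^T + E, Y = U Q^T + F)
    @property
    def x_scores(self) -> np.ndarray:  # T
        return self.estimator.x_scores_

    @property
    def x_loadings(self) -> np.ndarray:  # P
        return self.estimator.x_loadings_

    @property
    def y_scores(self) -> np.ndarray:  # U
        return self.estimator.y_scores_

    @property
    def y_loadings(self) -> np.ndarray:  # Q
        return self.estimator.y_loadings_

    @property
    def x_residuals(self) -> np.ndarray:  # E
        Xc = self.estimator._x_mean  # noqa: SLF001 - documented sklearn attribute
        X = self.estimator.x_scores_ @ self.estimator.x_loadings_.T
        return self._training_X - (X + Xc)

    _training_X: np.ndarray = dataclasses.field(default=None, repr=False)


def fit_pls(
    controls: pd.DataFrame,
    labels: Sequence,
    max_components: int = 10,
    folds: int = 10,
    seed: int = 0,
) -> PLSModel:
    """Cross-validated PLS regression of the control label on the readouts.

    The number of components minimising the stratified ``folds``-fold
    cross-validated squared prediction error of the label is chosen (ties
    to the smaller model), then the final model is refitted on all wells.
    Deterministic given ``seed``.
    """
    y = pd.Series(labels, index=controls.index).map(
        lambda v: LABEL_CODING.get(v, v)
    ).to_numpy(dtype=float)
    classes = np.unique(y)
    if classes.size != 2:
        raise FitError(f"need exactly 2 label values, got {classes.tolist()}")
    X = controls.to_numpy(dtype=float)
    n, m = X.shape
    folds = min(folds, int(min(np.bincount((y == classes[1]).astype(int)))))
    if folds < 2:
        raise FitError("too few wells in a class for cross-validation")
    k_max = int(min(max_components, m, n - int(np.ceil(n / folds)) - 1))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    curve = []
    for k in range(1, k_max + 1):
        sse = 0.0
        for train, test in cv.split(X, y):
            est = PLSRegression(n_components=k, scale=False)
            est.fit(X[train], y[train])
            pred = est.predict(X[test]).ravel()
            sse += float(np.sum((pred - y[test]) ** 2))
        curve.append(sse / n)
    best_k = int(np.argmin(curve)) + 1
    est = PLSRegression(n_components=best_k, scale=False)
    est.fit(X, y)
    model = PLSModel(
        estimator=est,
        selected_parameters=list(controls.columns),
        n_components=best_k,
        cv_error=float(curve[best_k - 1]),
        cv_curve=curve,
        training_index=controls.index,
    )
    model._training_X = X
    return model


def predict_scores(model: PLSModel, wells: pd.DataFrame) -> pd.Series:
    """Component-1 X-score of each well under the fitted model.

    This scalar is the well's coordinate along the learned
    control-separating axis; it is what the QC stage and the per-gene SSMD
    consume.  Wells must supply every selected parameter.
    """
    missing = [p for p in model.selected_parameters if p not in wells.columns]
    if missing:
        raise KeyError(f"wells are missing selected parameters: {missing}")
    X = wells[model.selected_parameters].to_numpy(dtype=float)
    scores = model.estimator.transform(X)[:, 0]
    return pd.Series(scores, index=wells.index, name="pls_score")


def pls_pipeline(
    dataset: ScreenDataset,
    threshold: float = PRIMARY_THRESHOLD,
    key: str = "gene_id",
    fdr: float = 0.05,
    qc_cutoff: float = QC_CUTOFF,
    confidence: float = 0.99,
    max_components: int = 10,
    folds: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """End-to-end supervised workflow on an artifact-corrected dataset.

    Returns the per-gene score table (``pls_ssmd``, ``pls_hit``) and a
    details dict with the feature selection, outlier reports, both models,
    the QC report and the per-well scores.
    """
    wells = dataset.wells
    is_control = wells["role"].isin([ROLE_NEGATIVE, ROLE_POSITIVE])
    params = dataset.parameter_names

    def _train(sub_wells: pd.DataFrame) -> tuple[PLSModel, pd.DataFrame, pd.DataFrame]:
        ctrl = sub_wells[sub_wells["role"].isin([ROLE_NEGATIVE, ROLE_POSITIVE])]
        features = select_features(ctrl[params], ctrl["role"], fdr=fdr)
        chosen = list(features.index[features["selected"]])
        if not chosen:
            raise FitError("no parameter separates the control classes at the FDR cut")
        outliers = remove_outlier_controls(ctrl[chosen], confidence=confidence)
        kept = ctrl.loc[~outliers["excluded"]]
        model = fit_pls(
            kept[chosen], kept["role"], max_components=max_components, folds=folds, seed=seed
        )
        return model, features, outliers

    model1, features1, outliers1 = _train(wells)
    scores1 = predict_scores(model1, wells)
    # sign convention: negative controls (full recruitment) at the positive
    # pole so that the score behaves like the recruitment readouts
    if scores1[is_control & (wells["role"] == ROLE_NEGATIVE)].mean() < 0:
        scores1 = -scores1
    qc_report, surviving = qc_screen(dataset, scores1, cutoff=qc_cutoff)

    model2, features2, outliers2 = _train(surviving.wells)
    scores2 = predict_scores(model2, surviving.wells)
    if scores2[surviving.wells["role"] == ROLE_NEGATIVE].mean() < 0:
        scores2 = -scores2

    meta = surviving.wells[["plate_id", "replicate", "well", "role", key]]
    from .workflows import _gene_ssmd_series

    ssmd = _gene_ssmd_series(meta, scores2, key)
    table = pd.DataFrame({"pls_ssmd": ssmd})
    table["pls_hit"] = flag_hits(table["pls_ssmd"], threshold)
    details = {
        "feature_selection": features1,
        "outliers": outliers1,
        "model": model1,
        "qc_report": qc_report,
        "well_scores": scores1,
        "feature_selection_refit": features2,
        "outliers_refit": outliers2,
        "model_refit": model2,
        "well_scores_refit": scores2,
        "s0_squared": series_s0_squared(meta, scores2),
    }
    return table, details
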