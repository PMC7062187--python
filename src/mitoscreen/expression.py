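"""Expressed / non-expressed gene calls from a normalized intensity matrix.

The density of per-gene log intensities on a microarray is bimodal: a
low-intensity mode of probes whose genes the cell line does not express and
a high-intensity mode of expressed genes.  A two-component Gaussian mixture
fitted by EM separates the modes; the lower-mean component is the
non-expressed distribution.  Each gene is then tested against a large
sample drawn from that null component (one-sided Welch t test, the gene
greater), p values are corrected across genes, and genes at adjusted
p <= 0.05 are called expressed.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateModelError, EmptyInputError


@dataclasses.dataclass(frozen=True)
class MixtureFit:
    """Two-component Gaussian mixture, components ordered mean1 < mean2."""

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    log_likelihood: float
    converged: bool
    degenerate: bool

    @property
    def off_mean(self) -> float:
        return self.means[0]

    @property
    def off_sd(self) -> float:
        return self.sds[0]


def fit_mixture(
    intensities,
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureFit:
    """EM fit of a two-Gaussian mixture to per-gene mean intensities.

    Runs ``n_init`` k-means-style initializations and keeps the best
    likelihood; deterministic given ``seed``.  A collapse onto one mode
    (means closer than half the wider S.D., or a vanishing weight) is
    reported via the ``degenerate`` flag rather than an exception, so the
    caller can refuse to gate on it.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise EmptyInputError("need >= 10 finite intensities to fit a mixture")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        tol=tol,
        max_iter=max_iter,
        n_init=n_init,
        init_params="kmeans",
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    degenerate = bool(
        abs(means[1] - means[0]) < 0.5 * max(sds) or min(weights) < 0.05
    )
    if not gm.converged_:
        warnings.warn("mixture EM did not converge; returning the best fit found")
    return MixtureFit(
        means=(float(means[0]), float(means[1])),
        sds=(float(sds[0]), float(sds[1])),
        weights=(float(weights[0]), float(weights[1])),
        log_likelihood=float(gm.score(x.reshape(-1, 1)) * x.size),
        converged=bool(gm.converged_),
        degenerate=degenerate,
    )


def _welch_greater(values: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Row-wise one-sided Welch t test p values (row mean greater than null)."""
    n1 = values.shape[1]
    n2 = null.size
    m1 = values.mean(axis=1)
    v1 = values.var(axis=1, ddof=1)
    m2 = null.mean()
    v2 = null.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    t = np.where(np.isfinite(t), t, 0.0)
    df = np.where(np.isfinite(df), df, 1.0)
    return stats.t.sf(t, df)


def call_expressed(
    matrix: pd.DataFrame,
    fit: MixtureFit,
    n_null: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-gene expressed calls against the non-expressed mixture component.

    Draws ``n_null`` points from the lower-mean component, runs a one-sided
    Welch t test per gene (gene samples greater than the null draws),
    corrects across genes (Benjamini-Hochberg by default; ``method``
    accepts any statsmodels multipletests method, e.g. ``"bonferroni"``)
    and calls a gene expressed iff adjusted p <= ``alpha``.
    """
    if fit.degenerate:
        raise DegenerateModelError(
            "mixture fit is degenerate (unimodal data?); refusing to gate expression"
        )
    values = matrix.to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise EmptyInputError("expression matrix needs >= 2 samples per gene")
    rng = np.random.default_rng(seed)
    null = rng.normal(fit.off_mean, fit.off_sd, size=n_null)
    p = _welch_greater(values, null)
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method=method)
    return pd.DataFrame(
        {
            "mean_intensity": values.mean(axis=1),
            "p": p,
            "p_adj": p_adj,
            "expressed": p_adj <= alpha,
        },
        index=matrix.index,
    )
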