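"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's numerical code paths: the posterior
oracle integrates with a midpoint Riemann sum on a finer grid using scipy's
multivariate-normal density directly, recomputing the broken-stick means
itself; the ROC oracle enumerates thresholds exhaustively.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal, norm

from pescreen.params import MARKERS, RiskModelParameters


def midpoint_posterior_risk(
    mu: float,
    sigma: float,
    log10_moms: dict[str, float],
    params: RiskModelParameters,
    refine: int = 10,
) -> float:
    """Posterior preterm risk by midpoint Riemann sum on a ``refine``-times
    finer grid, with the same analytic tail convention as the model."""
    step = params.g_grid_step / refine
    n = int(round((params.g_grid_max - params.g_grid_min) / step))
    mids = params.g_grid_min + step * (np.arange(n) + 0.5)
    names = [m for m in MARKERS if m in log10_moms]
    x = np.array([log10_moms[m] for m in names])

    def likelihood(g: np.ndarray) -> np.ndarray:
        if not names:
            return np.ones(np.shape(g))
        means = np.column_stack(
            [
                params.markers[m].intercept
                + params.markers[m].slope
                * np.maximum(0.0, params.markers[m].knot - np.asarray(g))
                for m in names
            ]
        )
        mvn = multivariate_normal(mean=np.zeros(len(names)), cov=params.covariance(names))
        return np.atleast_1d(mvn.pdf(x[None, :] - means))

    dens = norm.pdf(mids, mu, sigma) * likelihood(mids)
    num = dens[mids < params.preterm_cutoff].sum() * step
    den = dens.sum() * step
    like_lo = float(likelihood(np.array([params.g_grid_min]))[0])
    like_hi = float(likelihood(np.array([params.g_grid_max]))[0])
    num += like_lo * norm.cdf((params.g_grid_min - mu) / sigma)
    den += like_lo * norm.cdf((params.g_grid_min - mu) / sigma)
    den += like_hi * norm.sf((params.g_grid_max - mu) / sigma)
    return num / den


def conjugate_posterior_risk(
    mu0: float, sigma0: float, a: float, b: float, tau: float, x: float, cutoff: float
) -> float:
    """Closed-form Gaussian posterior mass below ``cutoff`` for a single
    marker with mean a + b·g and SD tau observed at value x."""
    precision = 1.0 / sigma0**2 + b * b / tau**2
    mean = (mu0 / sigma0**2 + b * (x - a) / tau**2) / precision
    return float(norm.cdf((cutoff - mean) * np.sqrt(precision)))


def brute_force_roc_points(
    scores: np.ndarray, labels: np.ndarray, weights: np.ndarray
) -> set[tuple[float, float]]:
    """All (FPR, TPR) operating points of the rule score >= t, t over the
    observed scores, by exhaustive enumeration."""
    labels = labels.astype(bool)
    pos = weights[labels].sum()
    neg = weights[~labels].sum()
    points = {(0.0, 0.0)}
    for t in np.unique(scores):
        pred = scores >= t
        points.add(
            (
                round(float(weights[~labels & pred].sum() / neg), 12),
                round(float(weights[labels & pred].sum() / pos), 12),
            )
        )
    return points


def brute_force_dr_at_fpr(
    scores: np.ndarray, labels: np.ndarray, weights: np.ndarray, target_fpr: float
) -> float:
    """Best TPR over all thresholds with FPR <= target, exhaustive scan."""
    labels = labels.astype(bool)
    pos = weights[labels].sum()
    neg = weights[~labels].sum()
    best = 0.0
    for t in np.unique(scores):
        pred = scores >= t
        fpr = weights[~labels & pred].sum() / neg
        if fpr <= target_fpr + 1e-12:
            best = max(best, weights[labels & pred].sum() / pos)
    return float(best)
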