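"""Competing-risks Bayes engine for preterm-preeclampsia risk.

The model treats the gestational age ``g`` at which delivery with
preeclampsia (PE) would occur as a latent variable with a Gaussian prior
whose mean depends on maternal history. Pregnancies with ``g`` beyond the
no-PE boundary deliver without PE, so "no PE" is the competing outcome and
its prior mass stays in the normalization. Biomarker log10 MoMs update the
prior through a multivariate Gaussian likelihood whose mean follows a
broken-stick in ``g`` (deflected below a per-marker knot, centered on 1 MoM
at or beyond it). The preterm-PE risk is the posterior mass below the
37-week cutoff.

Numerically the posterior is integrated by Simpson's rule on the
``g`` grid, with analytic Gaussian tail terms outside the grid: above
``g_grid_max`` the marker means are constant (the grid is required to cover
every knot) so the upper tail term is exact; below ``g_grid_min`` the
likelihood is frozen at its ``g_grid_min`` value, an approximation only
relevant for priors with substantial mass before the grid starts. With the
tails included, an empty marker set reproduces the untruncated prior risk
exactly (up to quadrature error in the numerator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy.integrate import simpson
from scipy.stats import norm

from .errors import ConfigurationError, DomainError, PosteriorNumericalError
from .params import MARKERS, RiskModelParameters
from .profiles import MaternalProfile

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class MoMSet:
    """Observed log10 MoMs for the markers measured on one woman."""

    log10_mom: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, value in self.log10_mom.items():
            if name not in MARKERS:
                raise ConfigurationError(f"unknown marker: {name!r}")
            if not np.isfinite(value):
                raise DomainError(f"log10 MoM for {name} is not finite: {value!r}")

    @property
    def available_markers(self) -> tuple[str, ...]:
        return tuple(m for m in MARKERS if m in self.log10_mom)

    def vector(self, markers: Sequence[str] | None = None) -> np.ndarray:
        names = self.available_markers if markers is None else tuple(markers)
        return np.array([self.log10_mom[m] for m in names], dtype=float)

    @classmethod
    def from_moms(cls, moms: Mapping[str, float]) -> "MoMSet":
        """Build from MoMs on the natural scale (values must be > 0)."""
        out = {}
        for name, value in moms.items():
            if not value > 0:
                raise DomainError(f"MoM for {name} must be > 0, got {value!r}")
            out[name] = float(np.log10(value))
        return cls(out)


class GaussianPrior(NamedTuple):
    """Gaussian prior over the gestational age at delivery with PE (weeks)."""

    mean: float
    sd: float


@dataclass(frozen=True)
class RiskResult:
    """Posterior preterm-PE risk for one woman."""

    preterm_pe_probability: float
    one_in_n: str
    markers_used: tuple[str, ...]
    prior_probability: float


def prior_distribution(profile: MaternalProfile, params: RiskModelParameters) -> GaussianPrior:
    """Maternal-history prior over g: baseline mean plus additive effects, fixed SD."""
    return GaussianPrior(mean=params.prior_mean(profile), sd=params.prior_sd)


def prior_preterm_risk(profile: MaternalProfile, params: RiskModelParameters) -> float:
    """Prior Gaussian mass below the preterm cutoff, Φ((cutoff − mean)/sd)."""
    prior = prior_distribution(profile, params)
    return float(norm.cdf((params.preterm_cutoff - prior.mean) / prior.sd))


def _likelihood_terms(
    X: np.ndarray, markers: Sequence[str], g: np.ndarray, params: RiskModelParameters
) -> np.ndarray:
    """Log-likelihood matrix (n women × m grid points) of log10 MoM rows ``X``."""
    n = X.shape[0]
    m = g.shape[0]
    if len(markers) == 0:
        return np.zeros((n, m))
    cov = params.covariance(markers)
    prec = np.linalg.inv(cov)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ConfigurationError("marker covariance is not positive definite")
    const = -0.5 * (len(markers) * _LOG_2PI + logdet)
    M = np.column_stack([params.markers[name].mean_log10_mom(g) for name in markers])
    XP = X @ prec                     # (n, k)
    xPx = np.einsum("ij,ij->i", XP, X)            # (n,)
    cross = XP @ M.T                  # (n, m)
    mPm = np.einsum("ij,jk,ik->i", M, prec, M)    # (m,)
    return const - 0.5 * (xPx[:, None] - 2.0 * cross + mPm[None, :])


def marker_log_likelihood(moms: MoMSet, g, params: RiskModelParameters):
    """Multivariate Gaussian log-density of the available log10 MoMs at ``g``.

    Missing markers are marginalized out (covariance sub-matrix). ``g`` may be
    a scalar or an array; the result has the same shape.
    """
    markers = moms.available_markers
    if not markers:
        raise DomainError("MoMSet has no available markers")
    g_arr = np.atleast_1d(np.asarray(g, dtype=float))
    out = _likelihood_terms(moms.vector(markers)[None, :], markers, g_arr, params)[0]
    return float(out[0]) if np.isscalar(g) or np.ndim(g) == 0 else out


def posterior_preterm_risk_batch(
    prior_means: np.ndarray,
    X: np.ndarray,
    markers: Sequence[str],
    params: RiskModelParameters,
    chunk: int = 2000,
) -> np.ndarray:
    """Vectorized posterior preterm-PE risk for many women at once.

    Parameters
    ----------
    prior_means : array (n,)
        Prior mean of g per woman (weeks); the SD is ``params.prior_sd``.
    X : array (n, k)
        log10 MoM values, columns ordered as ``markers``. With ``k == 0`` the
        result equals the prior risk.
    markers : sequence of str
        Marker names for the columns of ``X``.
    """
    mus = np.asarray(prior_means, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != mus.shape[0] or X.shape[1] != len(markers):
        raise DomainError(
            f"X must have shape (n, {len(markers)}), got {X.shape} for n={mus.shape[0]}"
        )
    g = params.grid()
    sd = params.prior_sd
    below = g <= params.preterm_cutoff + 1e-12
    out = np.empty(mus.shape[0])
    for start in range(0, mus.shape[0], chunk):
        sl = slice(start, start + chunk)
        out[sl] = _posterior_chunk(mus[sl], X[sl], markers, params, g, sd, below)
    return out


def _posterior_chunk(mus, X, markers, params, g, sd, below) -> np.ndarray:
    loglik = _likelihood_terms(X, markers, g, params)        # (n, m)
    z = (g[None, :] - mus[:, None]) / sd
    logprior = -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI
    logpost = logprior + loglik
    shift = np.max(logpost, axis=1, keepdims=True)
    y = np.exp(logpost - shift)
    num = simpson(y[:, below], x=g[below], axis=1)
    den = simpson(y, x=g, axis=1)
    # analytic Gaussian tails outside the grid; likelihood constant above the
    # grid (all knots covered), frozen at g_grid_min below it
    mass_low = norm.cdf((params.g_grid_min - mus) / sd)
    mass_high = norm.sf((params.g_grid_max - mus) / sd)
    with np.errstate(over="ignore"):
        tail_low = np.exp(loglik[:, 0] - shift[:, 0]) * mass_low
        tail_high = np.exp(loglik[:, -1] - shift[:, 0]) * mass_high
    numerator = num + tail_low
    denominator = den + tail_low + tail_high
    if np.any(~np.isfinite(denominator)) or np.any(denominator <= 0.0):
        raise PosteriorNumericalError(
            "posterior normalizer underflowed: grid too narrow or MoMs too extreme"
        )
    return np.clip(numerator / denominator, 0.0, 1.0)


def posterior_preterm_risk(
    profile: MaternalProfile, moms: MoMSet, params: RiskModelParameters
) -> RiskResult:
    """Posterior probability of PE with delivery before the preterm cutoff.

    The posterior over g multiplies the maternal-history prior by the marker
    likelihood and normalizes over the whole competing-risks range, so prior
    mass at or beyond the no-PE boundary (the "never develops PE" outcome)
    deflates the risk as it should. An empty marker set returns the prior
    risk.
    """
    markers = moms.available_markers
    prior = prior_distribution(profile, params)
    X = moms.vector(markers)[None, :] if markers else np.empty((1, 0))
    p = float(
        posterior_preterm_risk_batch(np.array([prior.mean]), X, markers, params)[0]
    )
    return RiskResult(
        preterm_pe_probability=p,
        one_in_n=risk_to_one_in_n(p) if p > 0.0 else "1:inf",
        markers_used=markers,
        prior_probability=prior_preterm_risk(profile, params),
    )


def risk_to_one_in_n(p: float) -> str:
    """Display a probability as the conventional "1:N" risk string.

    N is 1/p rounded half away from zero (minimum 1). Classification must use
    the raw probability, never this rounded display form.
    """
    if not 0.0 < p <= 1.0:
        raise DomainError(f"risk must be in (0, 1], got {p!r}")
    n = max(1, int(np.floor(1.0 / p + 0.5)))
    return f"1:{n}"
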