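"""Multiple-of-the-median (MoM) computation, distribution QC and re-centering.

Raw biomarker measurements are divided by the expected median for the same
gestational age and maternal characteristics, so that 1 MoM means
"population-typical". In a correctly specified population the log10 MoMs of
unaffected pregnancies are Gaussian with mean zero. This module tests that
assumption (one-sample t-test of the log10 MoMs against zero), and
re-centers a miscentered marker by dividing every MoM by the empirical
median of the unaffected distribution — the convention used when a screening
algorithm developed elsewhere is deployed in a new population.

Two deliberate asymmetries of that procedure are preserved and reported
side by side: the *test* is on the mean of the log10 MoMs while the
*correction* divides by the median of the MoMs, and a statistically
significant shift may still be left uncorrected when the median is within a
clinically negligible band around 1 (default [0.98, 1.02]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DegenerateInputError, DomainError, RangeError
from .profiles import Conception, MaternalProfile

#: Median within this band around 1 MoM is treated as clinically negligible.
DEFAULT_CLINICAL_BAND = (0.98, 1.02)


@dataclass(frozen=True)
class ExpectedMedianModel:
    """Regression of the log10 expected median of a marker on gestational age.

    ``ga_coefficients`` are polynomial coefficients in ascending powers of
    gestational age (weeks), degree at most 3, giving log10 of the expected
    median in the marker's units. ``covariate_adjustments`` maps maternal
    factors to additive log10 shifts: boolean factors (``smoker``,
    ``diabetes``, ``conception_assisted``, ``south_asian``) map to a number;
    continuous factors (``weight_kg``, ``age_years``, ``height_cm``) map to
    ``{"slope": s, "center": c}`` contributing ``s * (value - c)``.
    """

    marker: str
    ga_coefficients: tuple[float, ...]
    covariate_adjustments: Mapping[str, object] = field(default_factory=dict)
    valid_ga_range: tuple[float, float] = (9.0, 14.5)

    def __post_init__(self) -> None:
        if len(self.ga_coefficients) > 4:
            raise ConfigurationError("ga_coefficients: polynomial degree must be <= 3")

    def log10_expected_median(self, ga: float, profile: MaternalProfile) -> float:
        lo, hi = self.valid_ga_range
        if not lo <= ga <= hi:
            raise RangeError(
                f"gestational age {ga} weeks outside valid range [{lo}, {hi}] for {self.marker}"
            )
        value = float(np.polyval(self.ga_coefficients[::-1], ga))
        flags = {
            "smoker": profile.smoker,
            "diabetes": profile.diabetes,
            "chronic_hypertension": profile.chronic_hypertension,
            "conception_assisted": profile.conception is Conception.ASSISTED,
            "south_asian": profile.ethnicity == "south_asian",
        }
        continuous = {
            "weight_kg": profile.weight,
            "age_years": profile.age,
            "height_cm": profile.height,
        }
        for key, adj in self.covariate_adjustments.items():
            if key in continuous:
                value += float(adj["slope"]) * (continuous[key] - float(adj["center"]))
            elif key in flags:
                if flags[key]:
                    value += float(adj)
            else:
                raise ConfigurationError(f"unknown covariate adjustment key: {key!r}")
        return value


def compute_mom(
    raw_value: float, ga: float, profile: MaternalProfile, model: ExpectedMedianModel
) -> float:
    """Raw measurement divided by the expected median at (ga, profile)."""
    if not raw_value > 0:
        raise DomainError(f"raw {model.marker} value must be > 0, got {raw_value!r}")
    return raw_value / 10.0 ** model.log10_expected_median(ga, profile)


def one_sample_log_mom_test(log10_moms: Sequence[float]) -> tuple[float, float]:
    """Two-sided one-sample t-test of the log10 MoMs against mean zero."""
    x = np.asarray(log10_moms, dtype=float)
    if x.size < 2:
        raise DomainError(f"need at least 2 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise DomainError("log10 MoMs must be finite")
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("log10 MoMs have zero variance")
    t, p = stats.ttest_1samp(x, 0.0)
    return float(t), float(p)


def one_sample_log_mom_test_summary(mean: float, sd: float, n: int) -> tuple[float, float]:
    """Same test from summary statistics (mean, SD, n) of the log10 MoMs."""
    if n < 2:
        raise DomainError(f"need n >= 2, got {n}")
    if not sd > 0:
        raise DegenerateInputError(f"sd must be > 0, got {sd}")
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


@dataclass(frozen=True)
class RecenteringReport:
    """Outcome of the QC test and (possible) re-centering for one marker."""

    marker: str
    n: int
    mean_log10_mom: float
    sd_log10_mom: float
    t_statistic: float
    p_value: float
    median_mom: float
    recentering_factor: float
    applied: bool

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_text(self) -> str:
        flag = "re-centered" if self.applied else "left as reported"
        return (
            f"{self.marker:6s} n={self.n:6d}  mean log10 MoM {self.mean_log10_mom:+.4f} "
            f"(sd {self.sd_log10_mom:.4f})  t={self.t_statistic:+.2f} p={self.p_value:.3g}  "
            f"median {self.median_mom:.2f} MoM  factor {self.recentering_factor:.4f}  [{flag}]"
        )


def recenter(
    moms: Sequence[float],
    p_value: float,
    alpha: float = 0.05,
    marker: str = "",
    clinical_band: tuple[float, float] | None = DEFAULT_CLINICAL_BAND,
) -> tuple[np.ndarray, RecenteringReport]:
    """Divide MoMs by their empirical median when the QC test flags a shift.

    The correction is applied only when ``p_value < alpha`` *and* the median
    lies outside ``clinical_band`` (pass ``clinical_band=None`` to re-center
    on statistical significance alone). The returned report carries both the
    mean-based test and the median-based factor so the mean/median
    discrepancy of the procedure stays visible.
    """
    x = np.asarray(moms, dtype=float)
    if x.size == 0:
        raise DomainError("cannot re-center an empty MoM vector")
    if np.any(x <= 0):
        raise DomainError("MoMs must be strictly positive")
    log10 = np.log10(x)
    median = float(np.median(x))
    significant = p_value < alpha
    negligible = clinical_band is not None and clinical_band[0] <= median <= clinical_band[1]
    applied = significant and not negligible
    factor = median if applied else 1.0
    out = x / factor
    if x.size >= 2 and np.ptp(log10) > 0:
        t_stat = float(np.mean(log10) / (np.std(log10, ddof=1) / np.sqrt(x.size)))
        sd = float(np.std(log10, ddof=1))
    else:
        t_stat, sd = float("nan"), float("nan")
    report = RecenteringReport(
        marker=marker,
        n=int(x.size),
        mean_log10_mom=float(np.mean(log10)),
        sd_log10_mom=sd,
        t_statistic=t_stat,
        p_value=float(p_value),
        median_mom=median,
        recentering_factor=factor,
        applied=applied,
    )
    return out, report


def qc_recenter(
    moms: Sequence[float],
    alpha: float = 0.05,
    marker: str = "",
    clinical_band: tuple[float, float] | None = DEFAULT_CLINICAL_BAND,
) -> tuple[np.ndarray, RecenteringReport]:
    """Run the one-sample t-test on log10 MoMs, then :func:`recenter`."""
    x = np.asarray(moms, dtype=float)
    if np.any(x <= 0):
        raise DomainError("MoMs must be strictly positive")
    _, p = one_sample_log_mom_test(np.log10(x))
    return recenter(x, p, alpha=alpha, marker=marker, clinical_band=clinical_band)
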