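"""Synthetic screening cohorts with the statistical structure the model assumes.

The study population this generator emulates is a South Asian first-trimester
screening cohort: maternal characteristics are drawn from the published
marginal distributions, the latent gestational age at delivery with
preeclampsia is drawn from the maternal-history prior, outcome labels follow
from the preterm cutoff and the no-PE boundary, and log10 MoMs are drawn
from the marker likelihood at that latent age (zero-mean for unaffected
pregnancies). A configurable per-marker multiplicative shift emulates
population-level MoM miscentering, and an aspirin policy assigns prophylaxis
among screened-high-risk women with a configurable preventive effect,
keeping the counterfactual outcome as generator bookkeeping.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import truncnorm

from .errors import ConfigurationError, DomainError
from .model import posterior_preterm_risk_batch
from .params import MARKERS, RiskModelParameters, default_parameters
from .profiles import Conception, MaternalProfile, ParityClass


class Outcome(str, Enum):
    NO_PE = "no_pe"
    TERM_PE = "term_pe"
    PRETERM_PE = "preterm_pe"


@dataclass(frozen=True)
class ProfileDistributions:
    """Marginal distributions of maternal characteristics (study-cohort defaults).

    Continuous covariates are independent Gaussians truncated to plausible
    ranges; the generator reproduces marginals only — any dependence between
    characteristics and outcome arises through the prior, not by
    construction.
    """

    age_mean: float = 30.91
    age_sd: float = 4.03
    age_range: tuple[float, float] = (18.0, 45.0)
    weight_mean: float = 63.10
    weight_sd: float = 10.90
    weight_range: tuple[float, float] = (35.0, 120.0)
    height_mean: float = 159.51
    height_sd: float = 5.53
    height_range: tuple[float, float] = (140.0, 185.0)
    p_chronic_hypertension: float = 30.0 / 1863.0
    p_diabetes: float = 53.0 / 1863.0
    p_sle_aps: float = 6.0 / 1863.0
    p_assisted_conception: float = 97.0 / 1863.0
    p_smoker: float = 0.0
    #: nulliparous, parous without previous PE, parous with previous PE
    parity_proportions: tuple[float, float, float] = (
        1122.0 / 1863.0,
        710.0 / 1863.0,
        31.0 / 1863.0,
    )

    def validate(self) -> None:
        for name in (
            "p_chronic_hypertension",
            "p_diabetes",
            "p_sle_aps",
            "p_assisted_conception",
            "p_smoker",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if not np.isclose(sum(self.parity_proportions), 1.0):
            raise ConfigurationError("parity_proportions must sum to 1")
        for name in ("age_sd", "weight_sd", "height_sd"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")


@dataclass(frozen=True)
class AspirinPolicy:
    """Prophylactic-aspirin assignment among screened-high-risk women.

    ``uptake`` is the probability that a high-risk woman takes aspirin
    (study default 75/431 ≈ 17.4%); ``effect`` is the probability that
    aspirin prevents (or delays past the preterm cutoff) a would-be preterm-PE
    case, independent of dose and compliance. ``relabel_to`` controls what a
    prevented case becomes in the observed data: ``"term_pe"`` (delivery
    redrawn between the cutoff and the no-PE boundary) or ``"no_pe"``.
    """

    uptake: float = 75.0 / 431.0
    effect: float = 0.6
    threshold_n: int = 100
    dose_tags_mg: tuple[int, ...] = (75, 150)
    dose_proportions: tuple[float, ...] = (20.0 / 75.0, 55.0 / 75.0)
    relabel_to: str = "term_pe"

    def validate(self) -> None:
        if not 0.0 <= self.uptake <= 1.0:
            raise ConfigurationError(f"uptake must be in [0, 1], got {self.uptake}")
        if not 0.0 <= self.effect < 1.0:
            raise ConfigurationError(f"effect must be in [0, 1), got {self.effect}")
        if self.relabel_to not in ("term_pe", "no_pe"):
            raise ConfigurationError(f"relabel_to must be 'term_pe' or 'no_pe'")
        if len(self.dose_tags_mg) != len(self.dose_proportions) or not np.isclose(
            sum(self.dose_proportions), 1.0
        ):
            raise ConfigurationError("dose proportions must match tags and sum to 1")


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one reproducible synthetic cohort."""

    n: int
    seed: int
    profile_distributions: ProfileDistributions = field(default_factory=ProfileDistributions)
    mom_shift: Mapping[str, float] = field(default_factory=dict)
    aspirin_policy: AspirinPolicy = field(default_factory=AspirinPolicy)
    risk_params: RiskModelParameters | None = None
    #: gestational age at delivery of unaffected pregnancies, days (mean, sd)
    no_pe_delivery_days: tuple[float, float] = (272.0, 12.0)
    ga_screen_days: tuple[float, float] = (77.0, 98.0)

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigurationError(f"n must be >= 0, got {self.n}")
        self.profile_distributions.validate()
        self.aspirin_policy.validate()
        for name, shift in self.mom_shift.items():
            if name not in MARKERS:
                raise ConfigurationError(f"mom_shift names unknown marker {name!r}")
            if not shift > 0:
                raise ConfigurationError(f"mom_shift for {name} must be > 0")

    def params(self) -> RiskModelParameters:
        return self.risk_params if self.risk_params is not None else default_parameters()


@dataclass
class CohortRecord:
    """One screened pregnancy: profile, markers, outcome, treatment."""

    id: int
    profile: MaternalProfile
    ga_at_screening: float  # weeks
    log10_moms: dict[str, float]  # observed (post-shift)
    log10_moms_unshifted: dict[str, float]  # generator bookkeeping
    outcome: Outcome
    ga_at_delivery: float  # weeks
    aspirin: bool = False
    counterfactual_outcome: Outcome | None = None
    aspirin_dose_mg: int | None = None
    risk: float | None = None
    high_risk: bool | None = None

    def __post_init__(self) -> None:
        if self.counterfactual_outcome is None:
            self.counterfactual_outcome = self.outcome


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def prior_mean_arrays(
    params: RiskModelParameters,
    *,
    age: np.ndarray,
    weight: np.ndarray,
    height: np.ndarray,
    chronic_hypertension: np.ndarray,
    diabetes: np.ndarray,
    sle_aps: np.ndarray,
    smoker: np.ndarray,
    assisted: np.ndarray,
    parity: np.ndarray,
) -> np.ndarray:
    """Vectorized prior mean of g; `parity` holds ParityClass string values."""
    mean = np.full(age.shape, params.prior_baseline_mean, dtype=float)
    flags = {
        "chronic_hypertension": chronic_hypertension,
        "diabetes": diabetes,
        "sle_aps": sle_aps,
        "smoker": smoker,
        "conception_assisted": assisted,
        "parity_parous_no_pe": parity == ParityClass.PAROUS_NO_PE.value,
        "parity_parous_previous_pe": parity == ParityClass.PAROUS_PREVIOUS_PE.value,
    }
    for key, effect in params.prior_effects.items():
        mean += effect * flags[key].astype(float)
    values = {"age_years": age, "weight_kg": weight, "height_cm": height}
    for key, eff in params.prior_slopes.items():
        mean += eff.slope * (values[key] - eff.center)
    return mean


def simulate_cohort(spec: CohortSpec) -> list[CohortRecord]:
    """Generate ``spec.n`` pregnancies; bit-identical for identical spec+seed."""
    spec.validate()
    params = spec.params()
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    if n == 0:
        return []
    d = spec.profile_distributions

    age = _truncated_normal(rng, d.age_mean, d.age_sd, *d.age_range, size=n)
    weight = _truncated_normal(rng, d.weight_mean, d.weight_sd, *d.weight_range, size=n)
    height = _truncated_normal(rng, d.height_mean, d.height_sd, *d.height_range, size=n)
    chronic = rng.random(n) < d.p_chronic_hypertension
    diabetes = rng.random(n) < d.p_diabetes
    sle = rng.random(n) < d.p_sle_aps
    assisted = rng.random(n) < d.p_assisted_conception
    smoker = rng.random(n) < d.p_smoker
    parity = rng.choice(
        [c.value for c in ParityClass], size=n, p=list(d.parity_proportions)
    )
    ga_screen = rng.uniform(*spec.ga_screen_days, size=n) / 7.0

    mu = prior_mean_arrays(
        params,
        age=age,
        weight=weight,
        height=height,
        chronic_hypertension=chronic,
        diabetes=diabetes,
        sle_aps=sle,
        smoker=smoker,
        assisted=assisted,
        parity=parity,
    )
    g = rng.normal(mu, params.prior_sd)
    preterm = g < params.preterm_cutoff
    term = (g >= params.preterm_cutoff) & (g < params.no_pe_boundary)
    outcome = np.where(preterm, Outcome.PRETERM_PE.value,
                       np.where(term, Outcome.TERM_PE.value, Outcome.NO_PE.value))

    no_pe_mean, no_pe_sd = spec.no_pe_delivery_days
    ga_delivery = np.where(
        outcome == Outcome.NO_PE.value,
        _truncated_normal(rng, no_pe_mean, no_pe_sd, 196.0, 294.0, size=n) / 7.0,
        g,
    )

    names = params.marker_names
    k = len(names)
    M = np.zeros((n, k))
    pe = outcome != Outcome.NO_PE.value
    for j, name in enumerate(names):
        # unaffected pregnancies draw from the zero-deflection distribution
        M[pe, j] = params.markers[name].mean_log10_mom(g[pe])
        M[~pe, j] = params.markers[name].intercept
    L = np.linalg.cholesky(params.covariance(names))
    X = M + rng.standard_normal((n, k)) @ L.T
    shift_log10 = np.array([np.log10(spec.mom_shift.get(name, 1.0)) for name in names])
    X_obs = X + shift_log10[None, :]

    records = []
    for i in range(n):
        profile = MaternalProfile(
            age=float(age[i]),
            weight=float(weight[i]),
            height=float(height[i]),
            parity_class=ParityClass(parity[i]),
            chronic_hypertension=bool(chronic[i]),
            diabetes=bool(diabetes[i]),
            sle_aps=bool(sle[i]),
            conception=Conception.ASSISTED if assisted[i] else Conception.SPONTANEOUS,
            smoker=bool(smoker[i]),
        )
        records.append(
            CohortRecord(
                id=i,
                profile=profile,
                ga_at_screening=float(ga_screen[i]),
                log10_moms={name: float(X_obs[i, j]) for j, name in enumerate(names)},
                log10_moms_unshifted={name: float(X[i, j]) for j, name in enumerate(names)},
                outcome=Outcome(outcome[i]),
                ga_at_delivery=float(ga_delivery[i]),
            )
        )
    return records


def compute_cohort_risks(
    records: Sequence[CohortRecord],
    params: RiskModelParameters,
    markers: Sequence[str] | None = None,
    log10_moms_override: Mapping[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Posterior preterm-PE risk for every record, using ``markers`` (default all)."""
    names = tuple(markers) if markers is not None else params.marker_names
    mus = np.array([params.prior_mean(r.profile) for r in records])
    if names:
        if log10_moms_override is not None:
            X = np.column_stack([np.asarray(log10_moms_override[m], dtype=float) for m in names])
        else:
            X = np.array([[r.log10_moms[m] for m in names] for r in records])
    else:
        X = np.empty((len(records), 0))
    return posterior_preterm_risk_batch(mus, X, names, params)


def apply_aspirin(
    records: Sequence[CohortRecord],
    policy: AspirinPolicy,
    seed: int | np.random.Generator,
    params: RiskModelParameters | None = None,
) -> list[CohortRecord]:
    """Assign aspirin among high-risk women and realize its preventive effect.

    Requires ``high_risk`` flags to be set (this step runs after screening
    classification). Each aspirin taker who would have developed preterm PE
    is relabeled with probability ``policy.effect``; the counterfactual
    outcome is preserved.
    """
    policy.validate()
    if params is None:
        params = default_parameters()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for r in records:
        if r.high_risk is None:
            raise DomainError(
                "apply_aspirin requires screening classification first (high_risk is unset)"
            )
        r = copy.copy(r)
        r.counterfactual_outcome = r.outcome
        if r.high_risk and rng.random() < policy.uptake:
            r.aspirin = True
            r.aspirin_dose_mg = int(
                rng.choice(policy.dose_tags_mg, p=list(policy.dose_proportions))
            )
            if r.outcome is Outcome.PRETERM_PE and rng.random() < policy.effect:
                if policy.relabel_to == "term_pe":
                    r.outcome = Outcome.TERM_PE
                    r.ga_at_delivery = float(
                        rng.uniform(params.preterm_cutoff, params.no_pe_boundary)
                    )
                else:
                    r.outcome = Outcome.NO_PE
                    r.ga_at_delivery = float(
                        rng.uniform(params.preterm_cutoff, 42.0)
                    )
        out.append(r)
    return out


def simulate_screened_cohort(
    spec: CohortSpec, markers: Sequence[str] | None = None
) -> list[CohortRecord]:
    """Simulate, compute screening risks, classify at the policy threshold,
    and apply the aspirin policy — the full as-screened study flow.

    Risks are computed on the *observed* (possibly miscentered) MoMs, as in a
    deployment where the screening software is unaware of the population
    shift; QC and re-centering happen downstream in the analysis pipeline.
    """
    params = spec.params()
    records = simulate_cohort(spec)
    if not records:
        return []
    risks = compute_cohort_risks(records, params, markers)
    threshold = 1.0 / spec.aspirin_policy.threshold_n
    for r, risk in zip(records, risks):
        r.risk = float(risk)
        r.high_risk = bool(risk >= threshold)
    return apply_aspirin(
        records, spec.aspirin_policy, np.random.default_rng((spec.seed, 1)), params
    )
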