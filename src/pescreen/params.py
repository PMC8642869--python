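"""Coefficients of the competing-risks screening model.

:class:`RiskModelParameters` is the single home for every symbol of the risk
model: the Gaussian prior over the gestational age at delivery with
preeclampsia (baseline mean, additive history effects, SD), the integration
grid, the preterm cutoff and the no-PE boundary, and the per-marker
likelihood (broken-stick mean of the log10 MoM versus gestational age, and
the covariance of the log10 MoM vector).

The published first-trimester algorithms keep their fitted coefficients
inside proprietary software, so the engine here is fully parameterized and
the packaged defaults (``data/default_params.yaml``) are a documented
synthetic stand-in calibrated to the incidence structure of a South Asian
screening cohort — not the proprietary values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError
from .profiles import Conception, MaternalProfile, ParityClass

#: Canonical marker order used everywhere a MoM vector appears.
MARKERS: tuple[str, ...] = ("MAP", "UtAPI", "PAPPA", "PlGF")

#: Boolean / categorical factors that may carry an additive prior-mean shift.
PRIOR_EFFECT_KEYS = frozenset(
    {
        "chronic_hypertension",
        "diabetes",
        "sle_aps",
        "smoker",
        "conception_assisted",
        "parity_parous_no_pe",
        "parity_parous_previous_pe",
    }
)

#: Continuous covariates that may carry a (slope, center) prior-mean term.
PRIOR_SLOPE_KEYS = frozenset({"age_years", "weight_kg", "height_cm"})


@dataclass(frozen=True)
class ContinuousEffect:
    """Additive prior-mean term ``slope * (value - center)`` in weeks."""

    slope: float
    center: float


@dataclass(frozen=True)
class MarkerModel:
    """Broken-stick likelihood for one marker's log10 MoM.

    E[log10 MoM | g] = intercept + slope * max(0, knot - g); pregnancies with
    g at or beyond the knot (in particular unaffected pregnancies) therefore
    center on ``intercept``, which is 0 (1 MoM) in the default configuration.
    """

    intercept: float
    slope: float
    knot: float
    sd: float

    def mean_log10_mom(self, g: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.maximum(0.0, self.knot - np.asarray(g, dtype=float))


@dataclass
class RiskModelParameters:
    """All coefficients of the competing-risks model."""

    prior_baseline_mean: float
    prior_sd: float
    prior_effects: dict[str, float] = field(default_factory=dict)
    prior_slopes: dict[str, ContinuousEffect] = field(default_factory=dict)
    g_grid_min: float = 24.0
    g_grid_max: float = 60.0
    g_grid_step: float = 0.02
    preterm_cutoff: float = 37.0
    no_pe_boundary: float = 41.0
    markers: dict[str, MarkerModel] = field(default_factory=dict)
    correlations: dict[str, float] = field(default_factory=dict)
    schema_version: int = 1

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if not self.prior_sd > 0:
            raise ConfigurationError(f"prior_sd must be > 0, got {self.prior_sd}")
        if not (self.g_grid_min < self.preterm_cutoff < self.no_pe_boundary <= self.g_grid_max):
            raise ConfigurationError(
                "need g_grid_min < preterm_cutoff < no_pe_boundary <= g_grid_max, got "
                f"{self.g_grid_min}, {self.preterm_cutoff}, {self.no_pe_boundary}, {self.g_grid_max}"
            )
        if not self.g_grid_step > 0:
            raise ConfigurationError("g_grid_step must be > 0")
        for key in self.prior_effects:
            if key not in PRIOR_EFFECT_KEYS:
                raise ConfigurationError(f"unknown prior effect key: {key!r}")
        for key in self.prior_slopes:
            if key not in PRIOR_SLOPE_KEYS:
                raise ConfigurationError(f"unknown prior slope key: {key!r}")
        for name, marker in self.markers.items():
            if name not in MARKERS:
                raise ConfigurationError(f"unknown marker: {name!r}")
            if not marker.sd > 0:
                raise ConfigurationError(f"marker {name}: sd must be > 0")
            if marker.knot > self.g_grid_max:
                raise ConfigurationError(
                    f"marker {name}: knot {marker.knot} exceeds g_grid_max {self.g_grid_max}"
                )
        for key, rho in self.correlations.items():
            a, _, b = key.partition(":")
            if a not in self.markers or b not in self.markers:
                raise ConfigurationError(f"correlation {key!r} names an unknown marker")
            if not -1.0 < rho < 1.0:
                raise ConfigurationError(f"correlation {key!r} must lie in (-1, 1)")
        if self.markers:
            self.covariance(tuple(self.markers))  # raises if not positive definite

    # -- derived quantities -------------------------------------------------

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(m for m in MARKERS if m in self.markers)

    def grid(self) -> np.ndarray:
        """Integration grid over g including both endpoints and the cutoff."""
        n = int(round((self.g_grid_max - self.g_grid_min) / self.g_grid_step))
        g = self.g_grid_min + self.g_grid_step * np.arange(n + 1)
        g[-1] = self.g_grid_max
        if not np.any(np.isclose(g, self.preterm_cutoff, atol=1e-9)):
            g = np.sort(np.append(g, self.preterm_cutoff))
        return g

    def correlation(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.correlations.get(f"{a}:{b}", self.correlations.get(f"{b}:{a}", 0.0))

    def covariance(self, markers: Sequence[str] | None = None) -> np.ndarray:
        """Covariance of the log10 MoM vector restricted to ``markers``.

        Missing markers are handled by marginalization (sub-matrix), not
        imputation.
        """
        names = list(markers) if markers is not None else list(self.marker_names)
        for m in names:
            if m not in self.markers:
                raise ConfigurationError(f"no likelihood configured for marker {m!r}")
        k = len(names)
        cov = np.empty((k, k))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                cov[i, j] = self.correlation(a, b) * self.markers[a].sd * self.markers[b].sd
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError(
                f"marker covariance over {names} is not positive definite"
            ) from exc
        return cov

    def prior_mean(self, profile: MaternalProfile) -> float:
        """Prior mean gestational age (weeks) at delivery with PE for ``profile``."""
        mean = self.prior_baseline_mean
        flags = {
            "chronic_hypertension": profile.chronic_hypertension,
            "diabetes": profile.diabetes,
            "sle_aps": profile.sle_aps,
            "smoker": profile.smoker,
            "conception_assisted": profile.conception is Conception.ASSISTED,
            "parity_parous_no_pe": profile.parity_class is ParityClass.PAROUS_NO_PE,
            "parity_parous_previous_pe": profile.parity_class is ParityClass.PAROUS_PREVIOUS_PE,
        }
        for key, effect in self.prior_effects.items():
            if flags[key]:
                mean += effect
        values = {"age_years": profile.age, "weight_kg": profile.weight, "height_cm": profile.height}
        for key, eff in self.prior_slopes.items():
            mean += eff.slope * (values[key] - eff.center)
        return mean

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "schema_version": self.schema_version,
            "prior": {
                "baseline_mean_weeks": self.prior_baseline_mean,
                "sd_weeks": self.prior_sd,
                "effects": dict(self.prior_effects),
                "slopes": {k: {"slope": v.slope, "center": v.center} for k, v in self.prior_slopes.items()},
            },
            "grid": {"min": self.g_grid_min, "max": self.g_grid_max, "step": self.g_grid_step},
            "preterm_cutoff_weeks": self.preterm_cutoff,
            "no_pe_boundary_weeks": self.no_pe_boundary,
            "markers": {k: asdict(v) for k, v in self.markers.items()},
            "correlations": dict(self.correlations),
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RiskModelParameters":
        try:
            prior = d["prior"]
            grid = d.get("grid", {})
            markers = {
                name: MarkerModel(**spec) for name, spec in d.get("markers", {}).items()
            }
            slopes = {
                k: ContinuousEffect(**v) for k, v in prior.get("slopes", {}).items()
            }
            return cls(
                prior_baseline_mean=float(prior["baseline_mean_weeks"]),
                prior_sd=float(prior["sd_weeks"]),
                prior_effects={k: float(v) for k, v in prior.get("effects", {}).items()},
                prior_slopes=slopes,
                g_grid_min=float(grid.get("min", 24.0)),
                g_grid_max=float(grid.get("max", 60.0)),
                g_grid_step=float(grid.get("step", 0.02)),
                preterm_cutoff=float(d.get("preterm_cutoff_weeks", 37.0)),
                no_pe_boundary=float(d["no_pe_boundary_weeks"]),
                markers=markers,
                correlations={k: float(v) for k, v in d.get("correlations", {}).items()},
                schema_version=int(d.get("schema_version", 1)),
            )
        except KeyError as exc:
            raise ConfigurationError(f"missing key in parameter file: {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RiskModelParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_parameters() -> RiskModelParameters:
    """The packaged synthetic default parameter set (see module docstring)."""
    text = resources.files("pescreen.data").joinpath("default_params.yaml").read_text()
    return RiskModelParameters.from_dict(yaml.safe_load(text))
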