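"""Maternal characteristics driving the prior risk and expected-median adjustments.

A :class:`MaternalProfile` carries the history and physical-size variables used
both by the competing-risks prior (through additive shifts of the prior mean
gestational age at delivery with preeclampsia) and by the expected-median
models that turn raw biomarker measurements into multiples of the median.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import DomainError


class ParityClass(str, Enum):
    NULLIPAROUS = "nulliparous"
    PAROUS_NO_PE = "parous_no_pe"
    PAROUS_PREVIOUS_PE = "parous_previous_pe"


class Conception(str, Enum):
    SPONTANEOUS = "spontaneous"
    ASSISTED = "assisted"


@dataclass(frozen=True)
class MaternalProfile:
    """One woman's characteristics at the time of first-trimester screening.

    Parameters
    ----------
    age : float
        Maternal age in years.
    weight : float
        Weight in kg.
    height : float
        Height in cm.
    parity_class : ParityClass
        Nulliparous, parous without previous preeclampsia, or parous with
        previous preeclampsia.
    chronic_hypertension, diabetes, sle_aps, smoker : bool
        History flags (systemic lupus erythematosus / antiphospholipid
        syndrome combined, as usual in first-trimester screening).
    conception : Conception
        Spontaneous or assisted (in-vitro fertilisation / ovulation drugs).
    ethnicity : str
        Ethnicity tag; the cohort this package emulates is entirely
        ``"south_asian"``.
    """

    age: float
    weight: float
    height: float
    parity_class: ParityClass = ParityClass.NULLIPAROUS
    chronic_hypertension: bool = False
    diabetes: bool = False
    sle_aps: bool = False
    conception: Conception = Conception.SPONTANEOUS
    smoker: bool = False
    ethnicity: str = "south_asian"

    def __post_init__(self) -> None:
        object.__setattr__(self, "parity_class", ParityClass(self.parity_class))
        object.__setattr__(self, "conception", Conception(self.conception))
        for name in ("age", "weight", "height"):
            value = getattr(self, name)
            if not value > 0:
                raise DomainError(f"{name} must be strictly positive, got {value!r}")

    @property
    def bmi(self) -> float:
        """Body-mass index in kg/m², derived from weight and height."""
        return self.weight / (self.height / 100.0) ** 2
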