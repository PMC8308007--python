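"""Domain types and censoring semantics.

A measured element level in a digested sample is exactly one of three
things: a quantified concentration (µg·kg⁻¹ of original powder), a
left-censored observation below its reporting limit (printed ``<X``),
or an above-range observation that exceeded the top calibration
standard and could not be quantified (printed ``NR*``). How a censored
or above-range value enters the downstream intake arithmetic is an
explicit, recorded policy — never an implicit substitution.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .elements import PANEL_INDEX


class Status(str, enum.Enum):
    QUANTIFIED = "quantified"
    BELOW_LIMIT = "below_limit"
    ABOVE_RANGE = "above_range"


class CensorPolicy(str, enum.Enum):
    """Substitution rule for below-limit values: 0, L/2 or L."""

    ZERO = "zero"
    HALF_LIMIT = "half_limit"
    AT_LIMIT = "at_limit"


class AboveRangePolicy(str, enum.Enum):
    EXCLUDE = "exclude"
    ERROR = "error"


class CRConvention(str, enum.Enum):
    """How the slope factor combines with intake.

    ``TABLE_MATCH`` divides intake by the slope-factor constant and is the
    package default; ``LITERAL`` multiplies. Both are kept so sensitivity
    to the convention is a one-flag change; reports name the mode used.
    """

    TABLE_MATCH = "table_match"
    LITERAL = "literal"


#: Sentinel returned by :func:`apply_censor_policy` for values that cannot
#: contribute a number (above-range observations).
EXCLUDED = object()


@dataclass(frozen=True)
class ConcentrationValue:
    """One element level: quantified value XOR censoring limit XOR above-range."""

    status: Status
    value: float | None = None
    limit: float | None = None

    def __post_init__(self) -> None:
        if self.status is Status.QUANTIFIED:
            if self.value is None or self.limit is not None:
                raise ValueError("quantified value must carry value only")
            if not math.isfinite(self.value) or self.value < 0:
                raise ValueError(f"negative or non-finite concentration: {self.value}")
        elif self.status is Status.BELOW_LIMIT:
            if self.limit is None or self.value is not None:
                raise ValueError("below_limit value must carry limit only")
            if not math.isfinite(self.limit) or self.limit <= 0:
                raise ValueError(f"reporting limit must be positive: {self.limit}")
        else:
            if self.value is not None or self.limit is not None:
                raise ValueError("above_range carries no numeric value")

    @classmethod
    def quantified(cls, value: float) -> "ConcentrationValue":
        return cls(Status.QUANTIFIED, value=float(value))

    @classmethod
    def below_limit(cls, limit: float) -> "ConcentrationValue":
        return cls(Status.BELOW_LIMIT, limit=float(limit))

    @classmethod
    def above_range(cls) -> "ConcentrationValue":
        return cls(Status.ABOVE_RANGE)


@dataclass(frozen=True)
class SampleRecord:
    """One powder sample: identity, serving/digestion masses, element levels.

    Masses are grams as printed on packaging and weighed at digestion;
    conversion to kg happens at a single point in the intake arithmetic.
    ``returned_volume`` (mL of digest) is optional — it is only needed to
    back-calculate from instrument readings, not to assess a finished panel.
    """

    sample_id: str
    protein_type: str
    serving_mass: float
    weighed_mass: float
    concentrations: dict[str, ConcentrationValue] = field(default_factory=dict)
    returned_volume: float | None = None

    def __post_init__(self) -> None:
        if self.serving_mass <= 0:
            raise ValueError(f"{self.sample_id}: serving_mass must be > 0")
        if self.weighed_mass <= 0:
            raise ValueError(f"{self.sample_id}: weighed_mass must be > 0")
        if self.returned_volume is not None and self.returned_volume <= 0:
            raise ValueError(f"{self.sample_id}: returned_volume must be > 0")
        for el in self.concentrations:
            if el not in PANEL_INDEX:
                raise ValueError(f"{self.sample_id}: unknown element {el!r}")


@dataclass(frozen=True)
class ToxReference:
    """Per-element toxicological constants.

    rfd: oral reference dose, µg·kg⁻¹·day⁻¹. csf: cancer slope factor,
    (µg·kg⁻¹·day⁻¹)⁻¹, used under the convention in ``CRConvention``.
    rda/ul: recommended daily allowance and tolerable upper limit, µg·day⁻¹.
    Membership in the additive hazard-index list and the carcinogen list is
    carried as data so exclusions (e.g. total Cr) live in the reference
    table, not in code.
    """

    element: str
    rfd: float | None = None
    csf: float | None = None
    rda: float | None = None
    ul: float | None = None
    in_hi_list: bool = False
    in_cr_list: bool = False

    def __post_init__(self) -> None:
        if self.in_hi_list and self.rfd is None:
            raise ValueError(f"{self.element}: hazard-index membership requires an RfD")
        if self.in_cr_list and self.csf is None:
            raise ValueError(f"{self.element}: carcinogen-list membership requires a CSF")
        for name in ("rfd", "csf", "rda", "ul"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{self.element}: {name} must be positive, got {v}")


@dataclass(frozen=True)
class AssessmentConfig:
    """Exposure-scenario knobs: consumer body weight, daily servings, policies."""

    body_weight: float = 70.0
    servings_per_day: int = 1
    censor_policy: CensorPolicy = CensorPolicy.ZERO
    above_range_policy: AboveRangePolicy = AboveRangePolicy.EXCLUDE
    cr_convention: CRConvention = CRConvention.TABLE_MATCH

    def __post_init__(self) -> None:
        object.__setattr__(self, "censor_policy", CensorPolicy(self.censor_policy))
        object.__setattr__(
            self, "above_range_policy", AboveRangePolicy(self.above_range_policy)
        )
        object.__setattr__(self, "cr_convention", CRConvention(self.cr_convention))
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")
        if self.servings_per_day < 1:
            raise ValueError("servings_per_day must be >= 1")


def apply_censor_policy(
    c: ConcentrationValue,
    policy: CensorPolicy | str = CensorPolicy.ZERO,
    above_range: AboveRangePolicy | str = AboveRangePolicy.EXCLUDE,
):
    """Resolve a concentration to a number (µg·kg⁻¹) or the EXCLUDED marker.

    Quantified values pass through untouched. Below-limit values become
    0, limit/2 or the limit itself depending on ``policy``. Above-range
    values are excluded (or raise, under the ``error`` policy) because no
    defensible number exists for them without re-analysis at higher dilution.
    """
    policy = CensorPolicy(policy)
    above_range = AboveRangePolicy(above_range)
    if c.status is Status.QUANTIFIED:
        return c.value
    if c.status is Status.BELOW_LIMIT:
        if policy is CensorPolicy.ZERO:
            return 0.0
        if policy is CensorPolicy.HALF_LIMIT:
            return 0.5 * c.limit
        return c.limit
    if above_range is AboveRangePolicy.ERROR:
        raise ValueError("above-range concentration cannot be resolved to a number")
    return EXCLUDED
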