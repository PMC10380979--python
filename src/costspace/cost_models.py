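"""Expected-cost models for binary classifiers with and without a reject option.

Two cost models are provided.  MISC charges only misclassification errors:

    c = rho (1 - se) c0 + (1 - rho) (1 - sp) c1

where ``rho`` is the frequency of pathogenic (positive) variants, ``c0`` the
cost of calling a pathogenic variant benign (false negative) and ``c1`` the
cost of calling a benign variant pathogenic (false positive).  MISC+REJ adds
a rejection term for classifiers that may abstain:

    c = alpha rho (1 - se) c0 + alpha (1 - rho) (1 - sp) c1 + (1 - alpha) c2

with ``alpha`` the coverage (fraction of inputs that receive a call) and
``c2`` the cost of a rejection.  Costs are normalised by their total
``cT = c0 + c1 (+ c2)`` so that a clinical scenario is a point of a compact
"clinical space": the unit interval of ``rc1`` values under MISC, or the
triangle T = {rc0, rc1 >= 0, rc0 + rc1 <= 1} under MISC+REJ.

All coefficient arithmetic runs on :class:`fractions.Fraction`; decimal
inputs (``0.92``, ``"0.92"``) are carried exactly, which keeps the
downstream line-arrangement geometry free of rounding artefacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Union

__all__ = [
    "ValidationError",
    "PredictorProfile",
    "Prevalence",
    "CostVector",
    "ScenarioMISC",
    "ScenarioMISCREJ",
    "BoundaryLine",
    "as_fraction",
    "misc_expected_cost",
    "misc_normalized_cost",
    "miscrej_normalized_cost",
    "misc_line_coefficients",
    "miscrej_plane_coefficients",
    "boundary_line",
]

Number = Union[int, float, str, Fraction]


class ValidationError(ValueError):
    """Raised when a profile, prevalence, cost vector or scenario is invalid."""


def as_fraction(x: Number) -> Fraction:
    """Convert a number to an exact Fraction.

    Floats are converted through their shortest decimal representation
    (``repr``), so ``0.92`` becomes 23/25 rather than its binary expansion;
    this is what keeps typical performance-table entries exactly rational.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, bool):
        raise ValidationError(f"boolean is not a valid numeric value: {x!r}")
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        if not math.isfinite(x):
            raise ValidationError(f"non-finite value: {x!r}")
        try:
            return Fraction(repr(x))
        except ValueError:
            # repr in scientific notation (very small/large magnitudes):
            # fall back to the exact binary value
            return Fraction(x)
    if isinstance(x, str):
        try:
            return Fraction(x)
        except (ValueError, ZeroDivisionError) as exc:
            raise ValidationError(f"cannot parse number: {x!r}") from exc
    raise ValidationError(f"cannot convert {type(x).__name__} to a number")


def _unit(x: Number, name: str, *, lo_open: bool = False, hi_open: bool = False) -> Fraction:
    f = as_fraction(x)
    if f < 0 or f > 1 or (lo_open and f == 0) or (hi_open and f == 1):
        lo = "(" if lo_open else "["
        hi = ")" if hi_open else "]"
        raise ValidationError(f"{name} must be in {lo}0, 1{hi}, got {f}")
    return f


@dataclass(frozen=True)
class PredictorProfile:
    """One classifier's operating point: sensitivity, specificity, coverage.

    ``alpha`` (coverage) is the fraction of inputs the predictor emits a call
    for; the rejection rate is ``1 - alpha``.  Under MISC coverage is ignored
    (treated as 1).
    """

    name: str
    se: Fraction
    sp: Fraction
    alpha: Fraction = Fraction(1)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("predictor name must be non-empty")
        object.__setattr__(self, "se", _unit(self.se, "sensitivity"))
        object.__setattr__(self, "sp", _unit(self.sp, "specificity"))
        object.__setattr__(self, "alpha", _unit(self.alpha, "coverage"))

    @property
    def reject_rate(self) -> Fraction:
        return 1 - self.alpha


@dataclass(frozen=True)
class Prevalence:
    """Frequency of pathogenic variants among those tested, strictly in (0, 1)."""

    rho: Fraction

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rho", _unit(self.rho, "rho", lo_open=True, hi_open=True)
        )


def _as_rho(rho: Union[Prevalence, Number]) -> Fraction:
    if isinstance(rho, Prevalence):
        return rho.rho
    return Prevalence(as_fraction(rho)).rho


@dataclass(frozen=True)
class CostVector:
    """Raw (unnormalised) misclassification/rejection costs.

    ``c2`` is present only under MISC+REJ.  Units are the user's (monetary,
    QALY, ...); only ratios matter once normalised by ``cT``.
    """

    c0: Fraction
    c1: Fraction
    c2: Optional[Fraction] = None

    def __post_init__(self) -> None:
        for nm in ("c0", "c1", "c2"):
            v = getattr(self, nm)
            if v is None:
                continue
            f = as_fraction(v)
            if f < 0:
                raise ValidationError(f"{nm} must be non-negative, got {f}")
            object.__setattr__(self, nm, f)
        if self.total <= 0:
            raise ValidationError("total cost magnitude cT must be positive")

    @property
    def total(self) -> Fraction:
        return self.c0 + self.c1 + (self.c2 if self.c2 is not None else 0)

    def normalized(self) -> tuple:
        """Return (rc0, rc1) or (rc0, rc1, rc2); they sum to 1."""
        t = self.total
        if self.c2 is None:
            return (self.c0 / t, self.c1 / t)
        return (self.c0 / t, self.c1 / t, self.c2 / t)


@dataclass(frozen=True)
class ScenarioMISC:
    """A MISC clinical scenario: the normalised false-positive cost rc1.

    The clinical space is the open interval (0, 1); the endpoints are
    accepted here for cost evaluation (partitions are defined on the open
    interior).
    """

    rc1: Fraction

    def __post_init__(self) -> None:
        object.__setattr__(self, "rc1", _unit(self.rc1, "rc1"))

    @property
    def rc0(self) -> Fraction:
        return 1 - self.rc1


@dataclass(frozen=True)
class ScenarioMISCREJ:
    """A MISC+REJ clinical scenario: a point (rc0, rc1) of the triangle T."""

    rc0: Fraction
    rc1: Fraction

    def __post_init__(self) -> None:
        object.__setattr__(self, "rc0", _unit(self.rc0, "rc0"))
        object.__setattr__(self, "rc1", _unit(self.rc1, "rc1"))
        if self.rc0 + self.rc1 > 1:
            raise ValidationError(
                f"({self.rc0}, {self.rc1}) lies outside T: rc0 + rc1 > 1"
            )

    @property
    def rc2(self) -> Fraction:
        return 1 - self.rc0 - self.rc1


@dataclass(frozen=True)
class BoundaryLine:
    """The equal-cost locus of two predictors: a*rc0 + b*rc1 + c = 0.

    If the two predictors have identical (se, sp, alpha) their cost planes
    coincide everywhere; all three coefficients vanish and ``coincident`` is
    set.  If a = b = 0 but c != 0 the locus is empty (one predictor is
    cheaper on all of T) and ``is_empty`` is set.
    """

    a: Fraction
    b: Fraction
    c: Fraction
    pair: tuple = field(default=("", ""))

    @property
    def coincident(self) -> bool:
        return self.a == 0 and self.b == 0 and self.c == 0

    @property
    def is_empty(self) -> bool:
        return self.a == 0 and self.b == 0 and self.c != 0

    def normalized(self) -> tuple:
        """Canonical (a, b, c) up to positive scaling, for deduplication."""
        for lead in (self.a, self.b, self.c):
            if lead != 0:
                return (self.a / abs(lead), self.b / abs(lead), self.c / abs(lead))
        return (Fraction(0), Fraction(0), Fraction(0))

    def __call__(self, rc0: Number, rc1: Number) -> Fraction:
        return self.a * as_fraction(rc0) + self.b * as_fraction(rc1) + self.c


# ---------------------------------------------------------------------------
# cost evaluation


def misc_expected_cost(
    profile: PredictorProfile, rho: Union[Prevalence, Number], costs: CostVector
) -> float:
    """Average misclassification cost of a predictor, in the units of c0/c1."""
    if costs.c2 is not None:
        raise ValidationError("MISC takes a cost vector without a rejection cost c2")
    r = _as_rho(rho)
    c = r * (1 - profile.se) * costs.c0 + (1 - r) * (1 - profile.sp) * costs.c1
    return float(c)


def misc_line_coefficients(
    profile: PredictorProfile, rho: Union[Prevalence, Number]
) -> tuple:
    """Exact (slope, intercept) of the MISC cost line rc = slope*rc1 + intercept."""
    r = _as_rho(rho)
    slope = (1 - r) * (1 - profile.sp) - r * (1 - profile.se)
    intercept = r * (1 - profile.se)
    return slope, intercept


def misc_normalized_cost(
    profile: PredictorProfile,
    rho: Union[Prevalence, Number],
    scenario: Union[ScenarioMISC, Number],
) -> float:
    """Normalised MISC cost rc in [0, 1] at the scenario's rc1."""
    if not isinstance(scenario, ScenarioMISC):
        scenario = ScenarioMISC(as_fraction(scenario))
    slope, intercept = misc_line_coefficients(profile, rho)
    return float(slope * scenario.rc1 + intercept)


def miscrej_plane_coefficients(
    profile: PredictorProfile, rho: Union[Prevalence, Number]
) -> tuple:
    """Exact (A, B, C) of the MISC+REJ cost plane rc = A*rc0 + B*rc1 + C."""
    r = _as_rho(rho)
    a = profile.alpha
    A = a * r * (1 - profile.se) + a - 1
    B = a * (1 - r) * (1 - profile.sp) + a - 1
    C = 1 - a
    return A, B, C


def miscrej_normalized_cost(
    profile: PredictorProfile,
    rho: Union[Prevalence, Number],
    scenario: Union[ScenarioMISCREJ, tuple],
) -> float:
    """Normalised MISC+REJ cost rc in [0, 1] at the scenario's (rc0, rc1)."""
    if not isinstance(scenario, ScenarioMISCREJ):
        rc0, rc1 = scenario
        scenario = ScenarioMISCREJ(as_fraction(rc0), as_fraction(rc1))
    A, B, C = miscrej_plane_coefficients(profile, rho)
    return float(A * scenario.rc0 + B * scenario.rc1 + C)


def boundary_line(
    p_i: PredictorProfile, p_j: PredictorProfile, rho: Union[Prevalence, Number]
) -> BoundaryLine:
    """Equal-cost line l_ij between two predictors under MISC+REJ.

    Coefficients are the exact difference of the two cost planes:

        {rho [ai (1-se_i) - aj (1-se_j)] + ai - aj} rc0
      + {(1-rho) [ai (1-sp_i) - aj (1-sp_j)] + ai - aj} rc1
      + aj - ai = 0

    A pair with identical (se, sp, alpha) has no dividing line; the returned
    object carries ``coincident=True`` (detected by exact coefficient
    comparison, never by tolerance).
    """
    if p_i.name == p_j.name:
        raise ValidationError("boundary_line needs two distinct predictor identities")
    Ai, Bi, Ci = miscrej_plane_coefficients(p_i, rho)
    Aj, Bj, Cj = miscrej_plane_coefficients(p_j, rho)
    return BoundaryLine(Ai - Aj, Bi - Bj, Ci - Cj, pair=(p_i.name, p_j.name))
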