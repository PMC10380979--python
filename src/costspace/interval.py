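"""Partition of the 1-D clinical space under the MISC cost model.

Each predictor's normalised cost is a line in rc1.  The interval I = (0, 1)
is split at every in-range pairwise crossing; between consecutive crossings
no two cost lines intersect, so the cheapest predictor at an interval's
midpoint is cheapest on the whole interval.  Adjacent intervals won by the
same predictor are merged.  All arithmetic is exact rational.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import List, Optional, Sequence, Union

from .cost_models import (
    Number,
    Prevalence,
    PredictorProfile,
    ValidationError,
    misc_line_coefficients,
)

__all__ = ["Crossing", "IntervalAssignment", "pairwise_crossing", "partition_interval",
           "interval_fractions"]


@dataclass(frozen=True)
class Crossing:
    """Outcome of solving rc(M_i) = rc(M_j) in rc1.

    ``kind`` is one of:
      ``"crossing"``   -- a unique solution inside (0, 1), stored in ``rc1``;
      ``"outside"``    -- a unique solution, but outside the clinical space
                          (location still reported in ``rc1``);
      ``"parallel"``   -- equal slopes, different intercepts: no solution;
      ``"coincident"`` -- identical cost lines.
    """

    kind: str
    rc1: Optional[Fraction] = None


@dataclass(frozen=True)
class IntervalAssignment:
    """One open sub-interval (lo, hi) of I and its cost-optimal predictor."""

    lo: Fraction
    hi: Fraction
    predictor: str
    ties: tuple = field(default=())

    @property
    def length(self) -> Fraction:
        return self.hi - self.lo

    def as_dict(self) -> dict:
        return {
            "lo": float(self.lo),
            "hi": float(self.hi),
            "predictor": self.predictor,
            "length": float(self.length),
            "ties": list(self.ties),
        }


def pairwise_crossing(
    p_i: PredictorProfile, p_j: PredictorProfile, rho: Union[Prevalence, Number]
) -> Crossing:
    """Solve rc(M_i) = rc(M_j) for rc1 under MISC (coverage ignored)."""
    si, bi = misc_line_coefficients(p_i, rho)
    sj, bj = misc_line_coefficients(p_j, rho)
    if si == sj:
        return Crossing("coincident" if bi == bj else "parallel")
    x = (bj - bi) / (si - sj)
    if 0 < x < 1:
        return Crossing("crossing", x)
    return Crossing("outside", x)


def partition_interval(
    profiles: Sequence[PredictorProfile], rho: Union[Prevalence, Number]
) -> List[IntervalAssignment]:
    """Split I = (0, 1) into sub-intervals, each with a unique optimal predictor.

    Ties at a midpoint (exact-rational equality of the minimal cost) are
    broken by input order; the full tie set is recorded on the interval.
    """
    if not profiles:
        raise ValidationError("at least one predictor profile is required")
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate predictor names in profile list")

    lines = [misc_line_coefficients(p, rho) for p in profiles]

    # Step 1-2: in-range pairwise crossings, deduplicated and sorted.
    cuts = set()
    n = len(profiles)
    for i in range(n - 1):
        si, bi = lines[i]
        for j in range(i + 1, n):
            sj, bj = lines[j]
            if si == sj:
                continue
            x = (bj - bi) / (si - sj)
            if 0 < x < 1:
                cuts.add(x)
    bounds = [Fraction(0)] + sorted(cuts) + [Fraction(1)]

    # Step 3: cheapest predictor at each midpoint.
    raw: List[IntervalAssignment] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mid = (lo + hi) / 2
        costs = [s * mid + b for s, b in lines]
        best = min(costs)
        tied = tuple(names[k] for k, c in enumerate(costs) if c == best)
        raw.append(
            IntervalAssignment(lo, hi, tied[0], ties=tied if len(tied) > 1 else ())
        )

    # Step 4: unify adjacent intervals sharing a winner.
    merged: List[IntervalAssignment] = []
    for iv in raw:
        if merged and merged[-1].predictor == iv.predictor:
            prev = merged[-1]
            ties = tuple(t for t in prev.ties if t in iv.ties)
            merged[-1] = IntervalAssignment(prev.lo, iv.hi, prev.predictor, ties=ties)
        else:
            merged.append(iv)
    return merged


def interval_fractions(partition: Sequence[IntervalAssignment]) -> dict:
    """Total length owned by each predictor: its fraction of clinical scenarios."""
    out: dict = {}
    for iv in partition:
        out[iv.predictor] = out.get(iv.predictor, Fraction(0)) + iv.length
    return {k: float(v) for k, v in out.items()}
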