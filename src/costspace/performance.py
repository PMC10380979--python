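"""Estimation of sensitivity, specificity and coverage from labeled calls.

A labeled prediction table has one row per variant with its true class
(pathogenic/benign) and, per predictor, either a discrete call
(pathogenic/benign/rejected) or a continuous score.  Scores are turned into
calls by a plug-in rule: a pair of thresholds whose in-between band is
rejected (e.g. REVEL calls with scores in (0.249, 0.733) discarded).

Rates are conditional on acceptance: se = TP/Np and sp = TN/Nb count only
covered (non-rejected) variants, while coverage alpha = N/Ntot counts the
rejections.  This keeps the rejection rate out of the error rates, which the
MISC+REJ cost model weighs separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .cost_models import PredictorProfile, ValidationError

__all__ = [
    "PATHOGENIC",
    "BENIGN",
    "REJECTED",
    "EstimationError",
    "PluginRule",
    "ConfusionCounts",
    "ProfileEstimate",
    "apply_plugin_rule",
    "estimate_profile",
    "predictor_columns",
]

PATHOGENIC = "pathogenic"
BENIGN = "benign"
REJECTED = "rejected"
_LABELS = frozenset({PATHOGENIC, BENIGN})
_CALLS = frozenset({PATHOGENIC, BENIGN, REJECTED})


class EstimationError(ValueError):
    """Raised when a profile cannot be estimated (e.g. every row rejected)."""


@dataclass(frozen=True)
class PluginRule:
    """Score thresholds converting a continuous predictor into a reject classifier.

    With ``higher_is_pathogenic`` (the usual orientation): scores at or below
    ``benign_max`` are called benign, scores at or above ``pathogenic_min``
    are called pathogenic, scores strictly between are rejected.  With
    ``lower_is_pathogenic`` the band mirrors: pathogenic at or below
    ``pathogenic_min``, benign at or above ``benign_max``.  Set
    ``inclusive=False`` to reject scores landing exactly on a threshold.
    """

    benign_max: float
    pathogenic_min: float
    orientation: str = "higher_is_pathogenic"
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.orientation not in ("higher_is_pathogenic", "lower_is_pathogenic"):
            raise ValidationError(f"unknown orientation: {self.orientation!r}")
        if not (np.isfinite(self.benign_max) and np.isfinite(self.pathogenic_min)):
            raise ValidationError("plug-in thresholds must be finite")
        if self.orientation == "higher_is_pathogenic":
            if self.benign_max > self.pathogenic_min:
                raise ValidationError(
                    "benign_max must not exceed pathogenic_min for "
                    "higher_is_pathogenic"
                )
        else:
            if self.pathogenic_min > self.benign_max:
                raise ValidationError(
                    "pathogenic_min must not exceed benign_max for "
                    "lower_is_pathogenic"
                )


def apply_plugin_rule(scores: Sequence[float], rule: PluginRule) -> List[str]:
    """Map scores to calls; scores inside the rejection band are rejected."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValidationError("scores must be finite")
    calls = []
    for s in arr:
        if rule.orientation == "higher_is_pathogenic":
            is_b = s <= rule.benign_max if rule.inclusive else s < rule.benign_max
            is_p = s >= rule.pathogenic_min if rule.inclusive else s > rule.pathogenic_min
        else:
            is_p = s <= rule.pathogenic_min if rule.inclusive else s < rule.pathogenic_min
            is_b = s >= rule.benign_max if rule.inclusive else s > rule.benign_max
        if is_p:
            calls.append(PATHOGENIC)
        elif is_b:
            calls.append(BENIGN)
        else:
            calls.append(REJECTED)
    return calls


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion counts over covered variants plus the rejection bookkeeping."""

    TP: int
    TN: int
    FP: int
    FN: int
    rejected: int
    N_tot: int

    @property
    def Np(self) -> int:
        return self.TP + self.FN

    @property
    def Nb(self) -> int:
        return self.TN + self.FP

    @property
    def N(self) -> int:
        return self.Np + self.Nb

    def __post_init__(self) -> None:
        if self.N + self.rejected != self.N_tot:
            raise ValidationError("counts do not add up to the table size")


@dataclass(frozen=True)
class ProfileEstimate:
    """Estimated (se, sp, alpha) with provenance counts.

    ``se`` (resp. ``sp``) is None when no covered pathogenic (benign)
    variants were available to estimate it.
    """

    name: str
    se: Optional[float]
    sp: Optional[float]
    alpha: float
    counts: ConfusionCounts

    def to_profile(self) -> PredictorProfile:
        if self.se is None or self.sp is None:
            missing = "sensitivity" if self.se is None else "specificity"
            raise EstimationError(
                f"{self.name}: {missing} is undefined (no covered variants of "
                "the corresponding class)"
            )
        return PredictorProfile(self.name, self.se, self.sp, self.alpha)

    def standard_errors(self) -> dict:
        """Simple binomial standard errors for se, sp and alpha."""
        c = self.counts

        def se_of(p, n):
            if p is None or n == 0:
                return None
            return float(np.sqrt(p * (1 - p) / n))

        return {
            "se": se_of(self.se, c.Np),
            "sp": se_of(self.sp, c.Nb),
            "alpha": se_of(self.alpha, c.N_tot),
        }


def predictor_columns(table: pd.DataFrame) -> dict:
    """Map predictor name -> column kind ('call' or 'score') in a labeled table."""
    out = {}
    for col in table.columns:
        if col.endswith("_call"):
            out[col[:-5]] = "call"
        elif col.endswith("_score"):
            out[col[:-6]] = "score"
    return out


def _calls_for(table: pd.DataFrame, predictor: str,
               rule: Optional[PluginRule]) -> pd.Series:
    call_col, score_col = f"{predictor}_call", f"{predictor}_score"
    if call_col in table.columns:
        calls = table[call_col].where(table[call_col].notna(), REJECTED)
        bad = set(calls.unique()) - _CALLS
        if bad:
            raise ValidationError(f"{predictor}: invalid call values {sorted(bad)}")
        return calls
    if score_col in table.columns:
        if rule is None:
            raise ValidationError(
                f"{predictor}: a plug-in rule is required for a score column"
            )
        scores = table[score_col]
        missing = scores.isna()
        calls = pd.Series(REJECTED, index=table.index, dtype=object)
        if (~missing).any():
            calls.loc[~missing] = apply_plugin_rule(
                scores[~missing].to_numpy(dtype=float), rule
            )
        return calls
    raise ValidationError(f"no column {call_col!r} or {score_col!r} in the table")


def estimate_profile(
    table: pd.DataFrame, predictor: str, rule: Optional[PluginRule] = None
) -> ProfileEstimate:
    """Estimate (se, sp, alpha) for one predictor from a labeled table.

    Missing predictor output counts as rejected (towards alpha) and is
    excluded from the error rates.  Raises :class:`EstimationError` if every
    row is rejected.
    """
    if "label" not in table.columns:
        raise ValidationError("the table needs a 'label' column")
    labels = table["label"]
    bad = set(labels.dropna().unique()) - _LABELS
    if bad or labels.isna().any():
        raise ValidationError(
            f"true labels must be one of {sorted(_LABELS)}; offending values: "
            f"{sorted(map(str, bad)) or ['<missing>']}"
        )

    calls = _calls_for(table, predictor, rule)
    covered = calls != REJECTED
    n_tot = len(table)
    rejected = int((~covered).sum())

    is_path = labels == PATHOGENIC
    tp = int(((calls == PATHOGENIC) & is_path).sum())
    fn = int(((calls == BENIGN) & is_path).sum())
    tn = int(((calls == BENIGN) & ~is_path).sum())
    fp = int(((calls == PATHOGENIC) & ~is_path).sum())
    counts = ConfusionCounts(tp, tn, fp, fn, rejected, n_tot)

    if n_tot == 0:
        raise EstimationError("empty table")
    if counts.N == 0:
        raise EstimationError(
            f"{predictor}: every row rejected (alpha = 0); se/sp undefined"
        )

    se = tp / counts.Np if counts.Np else None
    sp = tn / counts.Nb if counts.Nb else None
    alpha = counts.N / n_tot
    return ProfileEstimate(predictor, se, sp, alpha, counts)
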