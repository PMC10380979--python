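"""Synthetic fixtures and the brute-force Monte-Carlo oracle.

The oracle samples clinical scenarios uniformly (rc1 on (0,1) for MISC;
(rc0, rc1) uniformly on the triangle T for MISC+REJ, via the square-fold
construction) and counts, per predictor, the fraction of scenarios where it
has the minimal normalised cost.  It is an independent check of the exact
interval/triangle partitions: winning fractions must agree with interval
lengths / region areas up to sampling error.

Generators emulate the statistical structure of a benchmark variant set:
two classes with frequencies rho and 1 - rho, per-predictor acceptance
Bernoulli(alpha), and correctness among accepted calls Bernoulli(se) on
pathogenic rows and Bernoulli(sp) on benign rows.  They do not simulate
predictor score distributions or variant biology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .cost_models import (
    PredictorProfile,
    ValidationError,
    misc_line_coefficients,
    miscrej_plane_coefficients,
)
from .performance import BENIGN, PATHOGENIC, REJECTED

__all__ = [
    "OracleEstimate",
    "oracle_fractions",
    "generate_profiles",
    "generate_labeled_table",
    "sample_triangle",
]


@dataclass(frozen=True)
class OracleEstimate:
    """Monte-Carlo winning fractions, comparable to a partition's fractions."""

    fractions: Dict[str, float]
    n_samples: int
    model: str
    seed: int

    def max_abs_difference(self, fractions: Dict[str, float]) -> float:
        names = set(self.fractions) | set(fractions)
        return max(
            abs(self.fractions.get(k, 0.0) - fractions.get(k, 0.0)) for k in names
        )


def sample_triangle(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points on T via the square fold: reflect points with x+y > 1."""
    pts = rng.random((n, 2))
    over = pts.sum(axis=1) > 1
    pts[over] = 1.0 - pts[over]
    return pts


def oracle_fractions(
    profiles: Sequence[PredictorProfile],
    rho,
    model: str,
    n_samples: int = 10**6,
    seed: int = 0,
) -> OracleEstimate:
    """Winner-count fractions over uniformly sampled clinical scenarios.

    Ties at a sampled point go to the tied predictor earliest in input
    order, mirroring the partition's tie-break.
    """
    if model not in ("misc", "miscrej"):
        raise ValidationError(f"model must be 'misc' or 'miscrej', got {model!r}")
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    if not profiles:
        raise ValidationError("at least one predictor profile is required")
    rng = np.random.default_rng(seed)
    names = [p.name for p in profiles]

    if model == "misc":
        coefs = np.array(
            [[float(v) for v in misc_line_coefficients(p, rho)] for p in profiles]
        )  # (N, 2): slope, intercept
        x = rng.random(n_samples)
        costs = np.outer(x, coefs[:, 0]) + coefs[:, 1]
    else:
        coefs = np.array(
            [[float(v) for v in miscrej_plane_coefficients(p, rho)] for p in profiles]
        )  # (N, 3): A, B, C
        pts = sample_triangle(n_samples, rng)
        costs = pts @ coefs[:, :2].T + coefs[:, 2]

    winners = np.argmin(costs, axis=1)  # argmin takes the first minimum: input order
    counts = np.bincount(winners, minlength=len(profiles))
    fractions = {nm: int(c) / n_samples for nm, c in zip(names, counts)}
    return OracleEstimate(fractions, n_samples, model, seed)


def generate_profiles(
    n: int,
    seed: int = 0,
    se_range: Tuple[float, float] = (0.5, 1.0),
    sp_range: Tuple[float, float] = (0.5, 1.0),
    alpha_range: Tuple[float, float] = (0.4, 1.0),
    decimals: int = 3,
) -> list:
    """Random predictor profiles with unique names M01, M02, ...

    Values are rounded to ``decimals`` places, as performance tables are
    printed, which also keeps exact-rational coefficients small.
    """
    for nm, (lo, hi) in (("se", se_range), ("sp", sp_range), ("alpha", alpha_range)):
        if not (0 <= lo <= hi <= 1) or (nm == "alpha" and lo <= 0):
            raise ValidationError(f"invalid {nm} range ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n)))
    out = []
    for i in range(n):
        se = round(rng.uniform(*se_range), decimals)
        sp = round(rng.uniform(*sp_range), decimals)
        alpha = round(rng.uniform(*alpha_range), decimals)
        out.append(PredictorProfile(f"M{i + 1:0{width}d}", se, sp, max(alpha, 10**-decimals)))
    return out


def generate_labeled_table(
    n_variants: int,
    rho,
    profiles_truth: Sequence[PredictorProfile],
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled prediction table drawn from known (se, sp, alpha) truth values.

    Row labels are Bernoulli(rho) pathogenic; each predictor accepts a row
    with probability alpha and, when it does, is correct with probability se
    (pathogenic rows) or sp (benign rows).  ``estimate_profile`` on the
    output recovers the generating parameters up to binomial error.
    """
    rho_f = float(rho.rho) if hasattr(rho, "rho") else float(rho)
    if not 0 < rho_f < 1:
        raise ValidationError("rho must be strictly between 0 and 1")
    if n_variants < 0:
        raise ValidationError("n_variants must be non-negative")
    rng = np.random.default_rng(seed)
    is_path = rng.random(n_variants) < rho_f
    labels = np.where(is_path, PATHOGENIC, BENIGN)
    data = {
        "variant_id": [f"v{i + 1:06d}" for i in range(n_variants)],
        "label": labels,
    }
    for p in profiles_truth:
        accepted = rng.random(n_variants) < float(p.alpha)
        p_correct = np.where(is_path, float(p.se), float(p.sp))
        correct = rng.random(n_variants) < p_correct
        called_path = np.where(correct, is_path, ~is_path)
        calls = np.where(
            accepted, np.where(called_path, PATHOGENIC, BENIGN), REJECTED
        )
        data[f"{p.name}_call"] = calls
    return pd.DataFrame(data)
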