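"""Table readers/writers, run configuration, and the analysis driver.

Profile tables are CSV/TSV with header ``name,sensitivity,specificity,coverage``
(coverage optional, defaulting to 1).  Labeled prediction tables have
``variant_id,label`` followed by one ``<name>_call`` or ``<name>_score``
column per predictor.  Plug-in rules are JSON objects
``{predictor, benign_max, pathogenic_min, orientation}``.  The dialect
(comma vs tab) is chosen by file extension.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .cost_models import PredictorProfile, ValidationError
from .interval import interval_fractions, partition_interval
from .performance import PluginRule, estimate_profile, predictor_columns
from .synthetic import oracle_fractions
from .triangle import partition_grouped, partition_triangle

__all__ = [
    "read_profiles",
    "write_profiles",
    "read_labeled_table",
    "write_labeled_table",
    "read_rules",
    "RunConfig",
    "run_analysis",
]

_PROFILE_COLUMNS = ("name", "sensitivity", "specificity", "coverage")


def _sep(path: Union[str, Path]) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab", ".txt")) else ","


def read_profiles(path: Union[str, Path]) -> List[PredictorProfile]:
    """Read a predictor performance table; rows are validated with locations."""
    df = pd.read_csv(path, sep=_sep(path))
    missing = set(_PROFILE_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    if "coverage" not in df.columns:
        df["coverage"] = 1.0
    profiles = []
    for i, row in df.iterrows():
        try:
            profiles.append(
                PredictorProfile(
                    str(row["name"]),
                    row["sensitivity"],
                    row["specificity"],
                    row["coverage"],
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {i + 2}: {exc}") from exc
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValidationError(f"{path}: duplicate predictor names")
    return profiles


def write_profiles(
    profiles: Sequence[PredictorProfile], path: Union[str, Path]
) -> None:
    df = pd.DataFrame(
        {
            "name": [p.name for p in profiles],
            "sensitivity": [float(p.se) for p in profiles],
            "specificity": [float(p.sp) for p in profiles],
            "coverage": [float(p.alpha) for p in profiles],
        }
    )
    df.to_csv(path, sep=_sep(path), index=False)


def read_labeled_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path))
    for col in ("variant_id", "label"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if not predictor_columns(df):
        raise ValidationError(
            f"{path}: no predictor columns (expected '<name>_call' or "
            "'<name>_score')"
        )
    return df


def write_labeled_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table.to_csv(path, sep=_sep(path), index=False)


def read_rules(path: Union[str, Path]) -> Dict[str, PluginRule]:
    """Read plug-in rules from JSON (a single object or a list of them)."""
    with open(path) as fh:
        raw = json.load(fh)
    if isinstance(raw, dict):
        raw = [raw]
    rules = {}
    for entry in raw:
        try:
            rules[entry["predictor"]] = PluginRule(
                benign_max=float(entry["benign_max"]),
                pathogenic_min=float(entry["pathogenic_min"]),
                orientation=entry.get("orientation", "higher_is_pathogenic"),
                inclusive=bool(entry.get("inclusive", True)),
            )
        except KeyError as exc:
            raise ValidationError(f"{path}: rule entry missing field {exc}") from exc
    return rules


@dataclass
class RunConfig:
    """Everything needed to regenerate a partition report bit-identically."""

    model: str  # "misc" | "miscrej"
    rho: Union[float, List[float]]
    profiles_path: Optional[str] = None
    table_path: Optional[str] = None
    rules_path: Optional[str] = None
    group_size: Optional[int] = None
    seed: int = 0
    oracle_samples: Optional[int] = None

    def __post_init__(self) -> None:
        if self.model not in ("misc", "miscrej"):
            raise ValidationError(f"model must be 'misc' or 'miscrej', got {self.model!r}")
        if (self.profiles_path is None) == (self.table_path is None):
            raise ValidationError(
                "exactly one input mode: a profile table or a labeled table"
            )
        for r in self.rho_values:
            if not 0 < r < 1:
                raise ValidationError(f"rho must be in (0, 1), got {r}")

    @property
    def rho_values(self) -> List[float]:
        return list(self.rho) if isinstance(self.rho, (list, tuple)) else [self.rho]

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "rho": self.rho_values,
            "profiles_path": self.profiles_path,
            "table_path": self.table_path,
            "rules_path": self.rules_path,
            "group_size": self.group_size,
            "seed": self.seed,
            "oracle_samples": self.oracle_samples,
        }


def _load_profiles(config: RunConfig) -> List[PredictorProfile]:
    if config.profiles_path is not None:
        return read_profiles(config.profiles_path)
    table = read_labeled_table(config.table_path)
    rules = read_rules(config.rules_path) if config.rules_path else {}
    profiles = []
    for name in predictor_columns(table):
        est = estimate_profile(table, name, rules.get(name))
        profiles.append(est.to_profile())
    return profiles


def run_analysis(config: RunConfig) -> dict:
    """Partition the clinical space per the config; return a JSON-able report."""
    profiles = _load_profiles(config)
    results = []
    for rho in config.rho_values:
        entry: dict = {"rho": rho}
        if config.model == "misc":
            part = partition_interval(profiles, rho)
            entry["intervals"] = [iv.as_dict() for iv in part]
            entry["fractions"] = interval_fractions(part)
        else:
            if config.group_size and len(profiles) > config.group_size:
                part = partition_grouped(profiles, rho, config.group_size)
            else:
                part = partition_triangle(profiles, rho)
            entry.update(part.as_dict())
        if config.oracle_samples:
            est = oracle_fractions(
                profiles, rho, config.model, config.oracle_samples, config.seed
            )
            entry["oracle_fractions"] = est.fractions
        results.append(entry)
    return {
        "software": {"name": "costspace", "version": __version__},
        "config": config.as_dict(),
        "inputs": {
            "profiles": [
                {
                    "name": p.name,
                    "sensitivity": float(p.se),
                    "specificity": float(p.sp),
                    "coverage": float(p.alpha),
                }
                for p in profiles
            ]
        },
        "results": results,
    }
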