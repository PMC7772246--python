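"""Shared in-memory containers.

The package passes data between stages as thin wrappers around pandas
objects: a :class:`ScoreMatrix` holds the subjects x variables battery
scores with an explicit missingness convention (NaN), per-variable
metadata (domain, sign convention), and round-trips to plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DOMAINS = ("cognition", "motor", "sensory", "emotion")

#: Canonical ability-trait labels, in factor order.
TRAIT_LABELS = (
    "Motor-endurance",
    "Emotional processing",
    "Executive and cognitive function",
    "Social interaction",
)


@dataclass
class ScoreMatrix:
    """Subjects x variables score table.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are subjects, columns are battery variables. Missing entries
        are NaN; the missing mask is derived, never stored separately.
    variable_meta : pandas.DataFrame
        Indexed by variable name with columns ``domain`` (one of
        :data:`DOMAINS`) and ``sign_flip`` (bool; True for variables where
        larger raw values mean worse performance, e.g. dexterity
        completion times).
    """

    values: pd.DataFrame
    variable_meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing_meta = [c for c in self.values.columns if c not in self.variable_meta.index]
        if missing_meta:
            raise ValueError(f"variable_meta does not cover columns: {missing_meta}")
        bad = set(self.variable_meta["domain"]) - set(DOMAINS)
        if bad:
            raise ValueError(f"unknown domains: {sorted(bad)}")

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness indicator (True where the value is absent)."""
        return self.values.isna()

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "ScoreMatrix":
        return ScoreMatrix(self.values.copy(), self.variable_meta.copy())

    # -- plain-text round trip -------------------------------------------
    def to_csv(self, values_path: str | Path, meta_path: str | Path | None = None) -> None:
        self.values.to_csv(values_path, index_label="subject")
        if meta_path is not None:
            self.variable_meta.to_csv(meta_path, index_label="variable")

    @classmethod
    def from_csv(cls, values_path: str | Path, meta_path: str | Path) -> "ScoreMatrix":
        values = pd.read_csv(values_path, index_col="subject")
        meta = pd.read_csv(meta_path, index_col="variable")
        meta["sign_flip"] = meta["sign_flip"].astype(bool)
        return cls(values, meta)


@dataclass
class ScalingParams:
    """Per-variable reference mean and standard deviation.

    Fitted on a reference (normative) cohort and then applied unchanged to
    any other cohort, so both live on the reference z-score scale.
    """

    mean: pd.Series
    sd: pd.Series
    ddof: int = 0

    def __post_init__(self) -> None:
        if (self.sd <= 0).any():
            bad = list(self.sd.index[self.sd <= 0])
            raise ValueError(f"non-positive reference sd for: {bad}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean": self.mean.to_dict(),
            "sd": self.sd.to_dict(),
            "ddof": self.ddof,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalingParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            mean=pd.Series(payload["mean"]),
            sd=pd.Series(payload["sd"]),
            ddof=int(payload.get("ddof", 0)),
        )


@dataclass
class BrainFeatureSet:
    """Per-subject brain feature table with feature provenance.

    ``features`` holds one row per subject; ``feature_meta`` is indexed by
    feature name with a ``kind`` column in {connectivity, degree,
    morphology, demographic} and, for connectivity features, the IC pair
    ``(i, j)`` the edge connects.
    """

    features: pd.DataFrame
    feature_meta: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    FEATURE_KINDS = ("connectivity", "degree", "morphology", "demographic")

    def __post_init__(self) -> None:
        missing = [c for c in self.features.columns if c not in self.feature_meta.index]
        if missing:
            raise ValueError(f"feature_meta does not cover: {missing[:5]} ...")
        bad = set(self.feature_meta["kind"]) - set(self.FEATURE_KINDS)
        if bad:
            raise ValueError(f"unknown feature kinds: {sorted(bad)}")
        if self.features.isna().any().any():
            raise ValueError("brain feature table contains missing entries")

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    def of_kind(self, *kinds: str) -> pd.DataFrame:
        keep = self.feature_meta.index[self.feature_meta["kind"].isin(kinds)]
        return self.features[[c for c in self.features.columns if c in set(keep)]]


def conn_feature_name(i: int, j: int) -> str:
    """Canonical name for the connectivity feature between ICs i < j."""
    if not i < j:
        raise ValueError("expected i < j")
    return f"conn_{i}_{j}"


def upper_triangle_pairs(n_ics: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle IC pairs, the connectivity feature order."""
    return [(i, j) for i in range(n_ics) for j in range(i + 1, n_ics)]
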