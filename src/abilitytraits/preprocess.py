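"""Filtering, imputation and cross-cohort reference scaling.

The reference (normative) cohort defines the scale: subjects are kept when
adult (age >= 18) and when strictly more than 70% of their variables are
observed; remaining gaps are filled with column means; the cohort is then
z-scored by its own means/sds. Any second cohort is scaled by the
*reference* parameters so both live in the same units. Variables whose raw
convention is "larger is worse" (sign_flip) are negated after scaling so
every scaled variable reads "larger is better".
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ScalingParams, ScoreMatrix

__all__ = [
    "filter_subjects",
    "impute_mean",
    "fit_reference_scaling",
    "apply_scaling",
    "invert_scaling",
]


def filter_subjects(
    m: ScoreMatrix,
    demo: pd.DataFrame,
    min_age: float = 18.0,
    min_completeness: float = 0.7,
) -> tuple[ScoreMatrix, dict]:
    """Retain adult subjects with strictly more than ``min_completeness`` observed.

    Returns the filtered matrix (subject order preserved) and an exclusion
    report with per-criterion counts.
    """
    missing_demo = m.values.index.difference(demo.index)
    if len(missing_demo):
        raise ValueError(f"demographics missing for subjects: {list(missing_demo)[:5]}")
    age_ok = demo.loc[m.values.index, "age"] >= min_age
    completeness = 1.0 - m.mask.mean(axis=1)
    comp_ok = completeness > min_completeness
    keep = age_ok & comp_ok
    report = {
        "n_input": m.n_subjects,
        "n_excluded_age": int((~age_ok).sum()),
        "n_excluded_completeness": int((age_ok & ~comp_ok).sum()),
        "n_kept": int(keep.sum()),
        "min_age": min_age,
        "min_completeness": min_completeness,
    }
    if report["n_kept"] == 0:
        raise ValueError(f"no subjects left after filtering: {report}")
    out = ScoreMatrix(m.values.loc[keep].copy(), m.variable_meta.copy())
    return out, report


def write_exclusion_report(report: dict, path: str | Path) -> None:
    pd.Series(report).to_csv(path, sep="\t", header=False)


def impute_mean(m: ScoreMatrix) -> ScoreMatrix:
    """Replace missing cells by the column mean of the observed cells.

    Column means are conserved exactly; a fully missing column is an error
    because its mean is undefined.
    """
    all_missing = m.mask.all(axis=0)
    if all_missing.any():
        bad = list(all_missing.index[all_missing])
        raise ValueError(f"cannot impute all-missing column(s): {bad}")
    out = m.copy()
    out.values = out.values.fillna(out.values.mean(axis=0))
    return out


def fit_reference_scaling(reference: ScoreMatrix, ddof: int = 0) -> ScalingParams:
    """Per-variable mean/sd of an imputed reference cohort.

    Population sd (ddof=0) by default: the reference cohort is treated as
    the normative population, not a sample from one.
    """
    if reference.mask.any().any():
        raise ValueError("reference must be imputed before fitting scaling params")
    mean = reference.values.mean(axis=0)
    sd = reference.values.std(axis=0, ddof=ddof)
    zero_var = sd <= 0
    if zero_var.any():
        raise ValueError(
            f"zero-variance column(s): {list(sd.index[zero_var])}; cannot z-score"
        )
    return ScalingParams(mean=mean, sd=sd, ddof=ddof)


def apply_scaling(m: ScoreMatrix, params: ScalingParams) -> ScoreMatrix:
    """z-score by the reference parameters, then negate sign_flip variables."""
    missing_cols = [c for c in m.values.columns if c not in params.mean.index]
    if missing_cols:
        raise ValueError(f"scaling params missing for columns: {missing_cols}")
    out = m.copy()
    z = (out.values - params.mean[out.values.columns]) / params.sd[out.values.columns]
    flip = out.variable_meta.loc[out.values.columns, "sign_flip"].to_numpy(dtype=bool)
    z.loc[:, z.columns[flip]] *= -1.0
    out.values = z
    return out


def invert_scaling(m: ScoreMatrix, params: ScalingParams) -> ScoreMatrix:
    """Undo :func:`apply_scaling` (used to verify the round trip)."""
    out = m.copy()
    z = out.values.copy()
    flip = out.variable_meta.loc[z.columns, "sign_flip"].to_numpy(dtype=bool)
    z.loc[:, z.columns[flip]] *= -1.0
    out.values = z * params.sd[z.columns] + params.mean[z.columns]
    return out
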