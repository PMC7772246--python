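"""Falconer ACE heritability from twin and sibling pairs.

Pair resemblance is measured as the double-entry regression slope (each
pair entered in both orders), which for standardized traits equals the
intraclass correlation. Falconer's identities then give the variance
decomposition: MZ twins share all genetics and the shared environment, so
rMZ = A + C; DZ twins share half the genetics, so rDZ = A/2 + C; and the
components exhaust the variance, A + C + E = 1. Hence

    A = 2 (rMZ - rDZ),   C = 2 rDZ - rMZ,   E = 1 - rMZ,

which sum to one identically. Estimates are reported only when both pair
regressions are significant; a negative A or C is a model breakdown
(reported, never silently clamped). Standard errors come from a
pair-level bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthgen import RELATIONS

__all__ = [
    "ACEEstimate",
    "enumerate_pairs",
    "kinship_distance_profile",
    "pair_resemblance",
    "falconer_ace",
    "gender_correct",
]


@dataclass
class ACEEstimate:
    """Variance decomposition with gating diagnostics.

    A is the broad-sense heritability H^2; raw (unclamped) values are
    retained even under breakdown so the failure mode stays visible.
    """

    A: float
    C: float
    E: float
    r_mz: float
    r_dz: float
    p_mz: float
    p_dz: float
    se_A: float
    se_C: float
    se_E: float
    status: str  # ok | not_significant | breakdown

    def clamped(self) -> tuple[float, float, float]:
        """Components clamped to [0, 1] for reporting."""
        return tuple(float(np.clip(v, 0.0, 1.0)) for v in (self.A, self.C, self.E))


# ---------------------------------------------------------------------------
# pair bookkeeping
# ---------------------------------------------------------------------------

def enumerate_pairs(
    kinship: pd.DataFrame,
    cohort: pd.Index,
    n_unrelated: int = 200,
    seed: int | None = None,
) -> dict[str, list[tuple[str, str]]]:
    """Pair lists per relation, plus a without-replacement unrelated sample.

    Unrelated pairs are drawn among cohort subjects avoiding any pair that
    appears in the kinship table (in either order).
    """
    known = set(RELATIONS) - {"unrelated"}
    bad = set(kinship["relation"]) - known
    if bad:
        raise ValueError(f"unknown relation label(s): {sorted(bad)}")
    cohort_set = set(cohort)
    for col in ("subject_a", "subject_b"):
        absent = set(kinship[col]) - cohort_set
        if absent:
            raise ValueError(f"kinship references subjects absent from cohort: {sorted(absent)[:5]}")

    pairs: dict[str, list[tuple[str, str]]] = {
        rel: [tuple(r) for r in kinship.loc[kinship["relation"] == rel,
                                            ["subject_a", "subject_b"]].itertuples(index=False)]
        for rel in sorted(known)
    }

    related = {frozenset(p) for ps in pairs.values() for p in ps}
    rng = np.random.default_rng(seed)
    ids = np.asarray(cohort)
    unrelated: list[tuple[str, str]] = []
    seen: set[frozenset] = set()
    attempts = 0
    while len(unrelated) < n_unrelated and attempts < 50 * n_unrelated:
        a, b = rng.choice(len(ids), size=2, replace=False)
        key = frozenset((ids[a], ids[b]))
        attempts += 1
        if key in related or key in seen:
            continue
        seen.add(key)
        unrelated.append((str(ids[a]), str(ids[b])))
    pairs["unrelated"] = unrelated
    return pairs


def kinship_distance_profile(
    scores: pd.DataFrame, pairs: dict[str, list[tuple[str, str]]]
) -> pd.DataFrame:
    """Mean and sd of pairwise Euclidean distance per relation.

    Works in any subject-level coordinate space: the ability-trait space
    or the space of stability-selected brain features. Expected distance
    grows as pair correlation falls, so genetic overlap orders the means.
    """
    rows = []
    for rel, ps in pairs.items():
        if not ps:
            rows.append({"relation": rel, "mean": np.nan, "sd": np.nan, "n_pairs": 0})
            continue
        a_idx = [p[0] for p in ps]
        b_idx = [p[1] for p in ps]
        diff = scores.loc[a_idx].to_numpy() - scores.loc[b_idx].to_numpy()
        dist = np.sqrt((diff**2).sum(axis=1))
        rows.append(
            {"relation": rel, "mean": float(dist.mean()),
             "sd": float(dist.std(ddof=1)) if len(dist) > 1 else np.nan,
             "n_pairs": len(dist)}
        )
    return pd.DataFrame(rows).set_index("relation")


# ---------------------------------------------------------------------------
# Falconer estimation
# ---------------------------------------------------------------------------

def _pair_values(values: pd.Series, pairs) -> tuple[np.ndarray, np.ndarray]:
    a = values.loc[[p[0] for p in pairs]].to_numpy(dtype=float)
    b = values.loc[[p[1] for p in pairs]].to_numpy(dtype=float)
    return a, b


def pair_resemblance(values: pd.Series, pairs) -> tuple[float, float]:
    """Double-entry regression slope and p-value for a set of pairs.

    Each pair contributes both (a, b) and (b, a), removing the arbitrary
    within-pair ordering; the slope of the double-entered regression is
    the intraclass correlation for standardized traits.
    """
    a, b = _pair_values(values, pairs)
    x = np.concatenate([a, b])
    y = np.concatenate([b, a])
    if np.std(x) == 0:
        raise ValueError("zero-variance trait; resemblance undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue)


def falconer_ace(
    values: pd.Series,
    mz_pairs,
    dz_pairs,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int | None = None,
) -> ACEEstimate:
    """Estimate A, C, E from MZ and DZ pair resemblance.

    ``status`` is ``not_significant`` unless both pair regressions reach
    ``p < alpha``, and ``breakdown`` when A or C comes out negative; raw
    component values are reported in every case. Bootstrap SEs resample
    pairs within each zygosity.
    """
    if len(mz_pairs) < 3 or len(dz_pairs) < 3:
        raise ValueError("need at least 3 pairs per zygosity")
    if values.std(ddof=0) == 0:
        raise ValueError("zero-variance trait")

    r_mz, p_mz = pair_resemblance(values, mz_pairs)
    r_dz, p_dz = pair_resemblance(values, dz_pairs)
    A = 2.0 * (r_mz - r_dz)
    C = 2.0 * r_dz - r_mz
    E = 1.0 - r_mz

    if p_mz >= alpha or p_dz >= alpha:
        status = "not_significant"
    elif A < 0 or C < 0:
        status = "breakdown"
    else:
        status = "ok"

    se_A = se_C = se_E = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        mz = list(mz_pairs)
        dz = list(dz_pairs)
        boot = np.empty((n_boot, 3))
        for b in range(n_boot):
            mz_b = [mz[i] for i in rng.integers(len(mz), size=len(mz))]
            dz_b = [dz[i] for i in rng.integers(len(dz), size=len(dz))]
            try:
                rm, _ = pair_resemblance(values, mz_b)
                rd, _ = pair_resemblance(values, dz_b)
            except ValueError:
                boot[b] = np.nan
                continue
            boot[b] = (2 * (rm - rd), 2 * rd - rm, 1 - rm)
        se_A, se_C, se_E = np.nanstd(boot, axis=0, ddof=1)

    return ACEEstimate(
        A=A, C=C, E=E, r_mz=r_mz, r_dz=r_dz, p_mz=p_mz, p_dz=p_dz,
        se_A=float(se_A), se_C=float(se_C), se_E=float(se_E), status=status,
    )


def gender_correct(values: pd.Series, gender: pd.Series) -> pd.Series:
    """Residualize a trait on binary gender (OLS), removing its mean effect.

    Residuals have mean zero and are exactly uncorrelated with gender,
    letting a single pooled twin analysis replace gender-separated runs.
    """
    g = gender.loc[values.index].to_numpy(dtype=float)
    if len(np.unique(g)) < 2:
        raise ValueError("gender correction needs both genders present")
    y = values.to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return pd.Series(resid, index=values.index, name=values.name)


def ace_table(
    estimates: dict[str, ACEEstimate],
) -> pd.DataFrame:
    """Assemble per-trait ACE results into a report table."""
    rows = []
    for trait, est in estimates.items():
        rows.append(
            {
                "trait": trait,
                "A": est.A, "se_A": est.se_A,
                "C": est.C, "se_C": est.se_C,
                "E": est.E, "se_E": est.se_E,
                "p_mz": est.p_mz, "p_dz": est.p_dz,
                "status": est.status,
            }
        )
    return pd.DataFrame(rows).set_index("trait")
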