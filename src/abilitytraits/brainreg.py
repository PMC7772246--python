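"""Brain-feature regression with resampled L1 ensembles.

Traits are regressed on z-scored brain features with L1-regularized
linear models. One "run" draws a fresh 70/30 train/test split, picks the
penalty by 5-fold cross-validation inside the training subjects only (or
uses a fixed override), fits one lasso per trait with all predictors
entered simultaneously, and scores out-of-sample r-squared and a p-value
from regressing observed on predicted values. An ensemble repeats this
100 times over independent splits; features present (nonzero coefficient)
in at least 80% of runs form the stable interpretation set.

The penalty is the ``alpha`` of the mean-squared-error lasso objective
``1/(2n) ||y - Xb||^2 + alpha ||b||_1`` with X and y z-scored; the named
defaults 0.05 (prediction) and 0.095 (interpretation) are tied to that
scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV

from .datatypes import BrainFeatureSet

__all__ = [
    "RegressionConfig",
    "RunFit",
    "EnsembleResult",
    "nodal_degrees",
    "fit_lasso_cv",
    "run_ensemble",
    "prevalent_features",
    "select_input_combination",
    "attach_demographics",
]


@dataclass
class RegressionConfig:
    train_fraction: float = 0.7
    cv_folds: int = 5
    lambda_grid: np.ndarray = field(default_factory=lambda: np.logspace(-3, 0, 30))
    lambda_optimal: float = 0.05
    lambda_interpret: float = 0.095
    prevalence_threshold: float = 0.8
    include_demographics: bool = True
    seed: int | None = None

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.lambda_interpret < self.lambda_optimal:
            raise ValueError("lambda_interpret must be >= lambda_optimal")
        if not 0.0 < self.prevalence_threshold <= 1.0:
            raise ValueError("prevalence_threshold must lie in (0, 1]")


# ---------------------------------------------------------------------------
# degree features
# ---------------------------------------------------------------------------

def nodal_degrees(
    conn: np.ndarray, densities: np.ndarray | None = None
) -> np.ndarray:
    """Per-node degrees of the thresholded connectome at several densities.

    For each density d the ``ceil(d * n(n-1)/2)`` strongest edges by
    absolute weight are kept and binarized (ties broken by upper-triangle
    row-major order); output concatenates the per-node degree vectors over
    densities (length ``n_nodes * n_densities``).
    """
    conn = np.asarray(conn, dtype=float)
    if conn.ndim != 2 or conn.shape[0] != conn.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if not np.allclose(conn, conn.T, atol=1e-10):
        raise ValueError("connectivity matrix must be symmetric")
    if densities is None:
        densities = np.arange(1, 11) / 100.0
    n = conn.shape[0]
    iu = np.triu_indices(n, k=1)
    weights = np.abs(conn[iu])
    n_edges = len(weights)
    order = np.argsort(-weights, kind="stable")
    out = []
    for d in densities:
        m = min(int(np.ceil(d * n_edges)), n_edges)
        keep = order[:m]
        deg = np.zeros(n)
        np.add.at(deg, iu[0][keep], 1)
        np.add.at(deg, iu[1][keep], 1)
        out.append(deg)
    return np.concatenate(out)


def degree_feature_set(fs: BrainFeatureSet, densities=None) -> BrainFeatureSet:
    """Replace connectivity features by nodal degrees at graded densities."""
    from .synthgen import connectivity_matrix  # local import, no cycle at module load

    if densities is None:
        densities = np.arange(1, 11) / 100.0
    n_ics = fs.provenance["n_ics"]
    rows = [nodal_degrees(connectivity_matrix(fs, s), densities) for s in fs.features.index]
    names = [
        f"degree_ic{i}_d{int(round(d * 100))}" for d in densities for i in range(n_ics)
    ]
    deg = pd.DataFrame(np.vstack(rows), index=fs.features.index, columns=names)
    other = fs.of_kind("morphology", "demographic")
    features = pd.concat([deg, other], axis=1)
    meta = pd.DataFrame(
        {"kind": ["degree"] * len(names), "ic_pair": [""] * len(names)},
        index=pd.Index(names, name="feature"),
    )
    meta = pd.concat([meta, fs.feature_meta.loc[other.columns]])
    prov = dict(fs.provenance)
    prov["densities"] = list(np.asarray(densities, dtype=float))
    return BrainFeatureSet(features, meta, prov)


def attach_demographics(fs: BrainFeatureSet, demo: pd.DataFrame) -> BrainFeatureSet:
    """Append age/gender columns (kind 'demographic') aligned on subjects."""
    demo = demo.loc[fs.features.index, ["age", "gender"]].astype(float)
    features = pd.concat([fs.features, demo], axis=1)
    meta = pd.concat(
        [
            fs.feature_meta,
            pd.DataFrame(
                {"kind": ["demographic", "demographic"], "ic_pair": ["", ""]},
                index=pd.Index(["age", "gender"], name="feature"),
            ),
        ]
    )
    return BrainFeatureSet(features, meta, dict(fs.provenance))


# ---------------------------------------------------------------------------
# single run
# ---------------------------------------------------------------------------

@dataclass
class RunFit:
    split_seed: int
    alphas: pd.Series            # selected penalty per trait
    coefficients: pd.DataFrame   # features x traits
    oos_r2: pd.Series
    oos_p: pd.Series
    train_index: np.ndarray
    test_index: np.ndarray

    @property
    def mean_oos_r2(self) -> float:
        return float(self.oos_r2.mean())


def _design(X: BrainFeatureSet, cfg: RegressionConfig) -> pd.DataFrame:
    feats = X.features
    if not cfg.include_demographics:
        demo_cols = X.feature_meta.index[X.feature_meta["kind"] == "demographic"]
        feats = feats.drop(columns=[c for c in demo_cols if c in feats.columns])
    return feats


def _zscore(A: np.ndarray) -> np.ndarray:
    sd = A.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (A - A.mean(axis=0)) / sd


def fit_lasso_cv(
    X: BrainFeatureSet,
    y: pd.DataFrame,
    cfg: RegressionConfig,
    split_seed: int = 0,
    alpha_override: float | None = None,
) -> RunFit:
    """One resampling run: split, tune the penalty in-sample, score OOS.

    The 30% hold-out never touches penalty selection; the 5-fold CV runs
    inside the 70% training subjects only. ``alpha_override`` skips the CV
    and fits at a fixed penalty (used for the sparse interpretation
    models).
    """
    cfg.validate()
    if not X.features.index.equals(y.index):
        raise ValueError("feature and trait tables must share the subject index")
    feats = _design(X, cfg)
    rng = np.random.default_rng(split_seed)
    n = feats.shape[0]
    perm = rng.permutation(n)
    n_train = int(round(cfg.train_fraction * n))
    train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])

    Xz = _zscore(feats.to_numpy(dtype=float))
    alphas, coefs, r2s, ps = {}, {}, {}, {}
    for trait in y.columns:
        yt = np.asarray(y[trait], dtype=float)
        if np.std(yt[train_idx]) == 0 or np.std(yt[test_idx]) == 0:
            raise ValueError(f"constant trait values for {trait!r} in a split")
        yz = (yt - yt[train_idx].mean()) / yt[train_idx].std(ddof=0)
        if alpha_override is None:
            cv = LassoCV(
                alphas=cfg.lambda_grid,
                cv=cfg.cv_folds,
                random_state=int(rng.integers(2**31)),
                max_iter=5000,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cv.fit(Xz[train_idx], yz[train_idx])
            alpha = float(cv.alpha_)
        else:
            alpha = float(alpha_override)
        model = Lasso(alpha=alpha, max_iter=10000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xz[train_idx], yz[train_idx])
        pred = model.predict(Xz[test_idx])
        resid = yz[test_idx] - pred
        sstot = ((yz[test_idx] - yz[test_idx].mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / sstot
        if np.std(pred) < 1e-12:
            p = 1.0
        else:
            p = float(stats.linregress(pred, yz[test_idx]).pvalue)
        alphas[trait] = alpha
        coefs[trait] = model.coef_
        r2s[trait] = float(r2)
        ps[trait] = p

    return RunFit(
        split_seed=split_seed,
        alphas=pd.Series(alphas),
        coefficients=pd.DataFrame(coefs, index=feats.columns),
        oos_r2=pd.Series(r2s),
        oos_p=pd.Series(ps),
        train_index=train_idx,
        test_index=test_idx,
    )


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

_NONZERO = 1e-10


@dataclass
class EnsembleResult:
    runs: list[RunFit]
    prevalence: pd.DataFrame         # features x traits, fraction of runs nonzero
    mean_coefficients: pd.DataFrame  # mean over runs where nonzero
    sign_conflict: pd.DataFrame      # bool, features x traits
    oos_r2_mean: pd.Series
    oos_r2_sd: pd.Series
    n_failures: int = 0

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def pooled_r2_mean(self) -> float:
        """Grand mean OOS r-squared over traits and runs."""
        return float(np.mean([r.oos_r2.to_numpy() for r in self.runs]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_runs": self.n_runs,
                    "n_failures": self.n_failures,
                    "oos_r2_mean": self.oos_r2_mean.to_dict(),
                    "oos_r2_sd": self.oos_r2_sd.to_dict(),
                    "per_run_r2": [r.oos_r2.to_dict() for r in self.runs],
                    "alphas": [r.alphas.to_dict() for r in self.runs],
                },
                indent=1,
            )
        )


def run_ensemble(
    X: BrainFeatureSet,
    y: pd.DataFrame,
    cfg: RegressionConfig,
    n_runs: int = 100,
    alpha_override: float | None = None,
) -> EnsembleResult:
    """Repeat the split/tune/score run over independent splits.

    Aggregates per-feature prevalence (fraction of runs with a nonzero
    coefficient), sign-consistent mean coefficients, and the mean and sd
    of out-of-sample r-squared per trait. A failed run is recorded and the
    ensemble continues; more than 10% failures aborts.
    """
    cfg.validate()
    seed_seq = np.random.SeedSequence(0 if cfg.seed is None else cfg.seed)
    split_seeds = [int(s.generate_state(1)[0] % 2**31) for s in seed_seq.spawn(n_runs)]
    runs: list[RunFit] = []
    failures = 0
    for s in split_seeds:
        try:
            runs.append(fit_lasso_cv(X, y, cfg, split_seed=s, alpha_override=alpha_override))
        except Exception as exc:  # noqa: BLE001 - run-level fault tolerance
            failures += 1
            warnings.warn(f"ensemble run with split seed {s} failed: {exc}")
            if failures > 0.1 * n_runs:
                raise RuntimeError(
                    f"{failures} of {n_runs} ensemble runs failed; aborting"
                ) from exc

    coef_stack = np.stack([r.coefficients.to_numpy() for r in runs])  # runs x feat x traits
    nonzero = np.abs(coef_stack) > _NONZERO
    prevalence = nonzero.mean(axis=0)
    with np.errstate(invalid="ignore"):
        mean_coef = np.where(
            nonzero.sum(axis=0) > 0,
            coef_stack.sum(axis=0) / np.maximum(nonzero.sum(axis=0), 1),
            0.0,
        )
    pos = (coef_stack > _NONZERO).any(axis=0)
    neg = (coef_stack < -_NONZERO).any(axis=0)
    sign_conflict = pos & neg

    feats = runs[0].coefficients.index
    traits = runs[0].coefficients.columns
    r2 = pd.DataFrame([r.oos_r2 for r in runs])
    return EnsembleResult(
        runs=runs,
        prevalence=pd.DataFrame(prevalence, index=feats, columns=traits),
        mean_coefficients=pd.DataFrame(mean_coef, index=feats, columns=traits),
        sign_conflict=pd.DataFrame(sign_conflict, index=feats, columns=traits),
        oos_r2_mean=r2.mean(),
        oos_r2_sd=r2.std(ddof=1),
        n_failures=failures,
    )


def prevalent_features(
    er: EnsembleResult,
    feature_meta: pd.DataFrame | None = None,
    threshold: float = 0.8,
    exclude_kinds: tuple[str, ...] = ("morphology",),
) -> dict[str, pd.DataFrame]:
    """Stable feature lists per trait: prevalence >= threshold, sign-consistent.

    Features whose coefficient sign flips across runs are flagged and
    excluded; morphology decoys are excluded by default (they overfit to
    particular splits rather than generalize). Returns, per trait, a table
    of feature, prevalence and mean coefficient sorted by |coefficient|.
    """
    out: dict[str, pd.DataFrame] = {}
    for trait in er.prevalence.columns:
        sel = er.prevalence[trait] >= threshold
        sel &= ~er.sign_conflict[trait]
        if feature_meta is not None and exclude_kinds:
            kinds = feature_meta.reindex(er.prevalence.index)["kind"]
            sel &= ~kinds.isin(exclude_kinds).to_numpy()
        tab = pd.DataFrame(
            {
                "prevalence": er.prevalence.loc[sel, trait],
                "mean_coefficient": er.mean_coefficients.loc[sel, trait],
            }
        ).sort_values("mean_coefficient", key=np.abs, ascending=False)
        if tab.empty:
            warnings.warn(f"no features reach prevalence {threshold} for {trait!r}")
        out[trait] = tab
    return out


def select_input_combination(
    candidates: dict[str, BrainFeatureSet],
    y: pd.DataFrame,
    cfg: RegressionConfig,
    n_runs: int = 5,
) -> tuple[str, pd.DataFrame]:
    """Pick the candidate feature set with the best mean hold-out r-squared.

    Ties break by declared (insertion) order of ``candidates``.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate feature sets to compare")
    rows = []
    for name, fs in candidates.items():
        ens = run_ensemble(fs, y, cfg, n_runs=n_runs, alpha_override=cfg.lambda_optimal)
        rows.append(
            {"candidate": name, "mean_oos_r2": float(ens.oos_r2_mean.mean()),
             "sd_oos_r2": float(ens.oos_r2_sd.mean()), "n_features": fs.features.shape[1]}
        )
    scoreboard = pd.DataFrame(rows).set_index("candidate")
    best = scoreboard["mean_oos_r2"].idxmax()  # idxmax keeps first on ties
    return str(best), scoreboard
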