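"""Gaussian-mixture subgrouping in ability-trait space.

Subjects are clustered with a spherical Gaussian mixture fitted by EM on
the reference cohort's trait scores. The component count is selected by
BIC, with partition stability over random subsamples (mean pairwise ARI)
reported alongside. A frozen model assigns any new cohort to the same
clusters without refitting, which is what makes cross-cohort comparisons
of cluster composition meaningful.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

__all__ = [
    "ClusterModel",
    "fit_gmm",
    "select_k",
    "assign_clusters",
    "adjusted_rand_index",
    "cluster_covariate_profile",
]


@dataclass
class ClusterModel:
    """K-component spherical Gaussian mixture over trait space."""

    weights: np.ndarray       # (K,), simplex
    means: np.ndarray         # (K, d)
    variances: np.ndarray     # (K,), spherical
    log_likelihood: float
    bic: float
    n_obs: int

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def n_params(self) -> int:
        # (K-1) mixing weights + K*d means + K spherical variances
        d = self.means.shape[1]
        return (self.K - 1) + self.K * d + self.K

    def log_responsibilities(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = self.means.shape[1]
        log_p = np.empty((X.shape[0], self.K))
        for k in range(self.K):
            log_p[:, k] = (
                np.log(self.weights[k])
                - 0.5 * d * np.log(2 * np.pi * self.variances[k])
                - 0.5 * ((X - self.means[k]) ** 2).sum(axis=1) / self.variances[k]
            )
        return log_p - logsumexp(log_p, axis=1, keepdims=True)

    def model_hash(self) -> str:
        """Digest of the fitted parameters; transfer must leave it unchanged."""
        h = hashlib.sha256()
        for arr in (self.weights, self.means, self.variances):
            h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
        return h.hexdigest()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "weights": self.weights.tolist(),
                    "means": self.means.tolist(),
                    "variances": self.variances.tolist(),
                    "log_likelihood": self.log_likelihood,
                    "bic": self.bic,
                    "n_obs": self.n_obs,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        d = json.loads(Path(path).read_text())
        return cls(
            weights=np.asarray(d["weights"]),
            means=np.asarray(d["means"]),
            variances=np.asarray(d["variances"]),
            log_likelihood=float(d["log_likelihood"]),
            bic=float(d["bic"]),
            n_obs=int(d["n_obs"]),
        )


def fit_gmm(
    t: pd.DataFrame, K: int, n_restarts: int = 10, seed: int | None = None
) -> ClusterModel:
    """EM fit of a spherical K-component mixture; best of ``n_restarts``.

    k-means++ seeding, convergence at a log-likelihood change below 1e-6.
    BIC uses ``-2 logL + p log n`` with ``p = (K-1) + K d + K``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    X = np.asarray(t, dtype=float)
    gm = GaussianMixture(
        n_components=K,
        covariance_type="spherical",
        n_init=n_restarts,
        init_params="k-means++",
        tol=1e-6,
        max_iter=500,
        reg_covar=1e-8,
        random_state=None if seed is None else int(seed) % (2**32),
    )
    gm.fit(X)
    n = X.shape[0]
    loglik = float(gm.score(X) * n)
    cm = ClusterModel(
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        variances=gm.covariances_.copy(),
        log_likelihood=loglik,
        bic=float(-2.0 * loglik + _n_params(K, X.shape[1]) * np.log(n)),
        n_obs=n,
    )
    return cm


def _n_params(K: int, d: int) -> int:
    return (K - 1) + K * d + K


def select_k(
    t: pd.DataFrame,
    k_range=range(1, 9),
    n_subsets: int = 20,
    subsample_frac: float = 0.8,
    n_restarts: int = 10,
    seed: int | None = None,
) -> tuple[int, pd.Series, pd.Series]:
    """Choose the component count by BIC; report subsample ARI stability.

    Stability per K is the mean pairwise ARI between partitions obtained by
    refitting on random ``subsample_frac`` subsets, each pair compared on
    its shared subjects. Pass ``n_subsets=0`` to skip the stability sweep.

    Returns ``(K_best, bic_curve, ari_stability)``.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be nonempty")
    rng = np.random.default_rng(seed)
    X = np.asarray(t, dtype=float)
    n = X.shape[0]

    bic = {}
    for K in k_range:
        bic[K] = fit_gmm(t, K, n_restarts=n_restarts, seed=int(rng.integers(2**31))).bic
    bic_curve = pd.Series(bic, name="bic")
    K_best = int(bic_curve.idxmin())

    stability = {}
    if n_subsets >= 2:
        m = int(round(subsample_frac * n))
        for K in k_range:
            subsets, labelings = [], []
            for _ in range(n_subsets):
                idx = rng.choice(n, size=m, replace=False)
                cm = fit_gmm(
                    pd.DataFrame(X[idx]), K, n_restarts=n_restarts,
                    seed=int(rng.integers(2**31)),
                )
                labels = np.full(n, -1)
                labels[idx] = cm.log_responsibilities(X[idx]).argmax(axis=1)
                subsets.append(set(idx.tolist()))
                labelings.append(labels)
            aris = []
            for a in range(n_subsets):
                for b in range(a + 1, n_subsets):
                    shared = np.array(sorted(subsets[a] & subsets[b]))
                    if len(shared) < 2:
                        continue
                    aris.append(
                        adjusted_rand_index(labelings[a][shared], labelings[b][shared])
                    )
            stability[K] = float(np.mean(aris)) if aris else np.nan
    ari_stability = pd.Series(stability, name="ari_stability", dtype=float)
    return K_best, bic_curve, ari_stability


def assign_clusters(
    cm: ClusterModel, t: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels and posterior responsibilities for any cohort.

    Pure evaluation of the frozen mixture — the model is never updated by
    the cohort being assigned, so the same clusters transfer across
    datasets.
    """
    X = np.asarray(t, dtype=float)
    if X.shape[1] != cm.means.shape[1]:
        raise ValueError(
            f"trait dimension {X.shape[1]} != model dimension {cm.means.shape[1]}"
        )
    resp = np.exp(cm.log_responsibilities(X))
    return resp.argmax(axis=1), resp


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement between two partitions.

    Contingency-table form: with n_ij the pair-count table, the index is
    (sum_ij C(n_ij,2) - E) / (max - E) where E is the expectation under
    random partitions with the same marginals. 1 means identical
    partitions (up to relabeling); independent partitions score ~0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    n = len(a)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(contingency, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0  # both partitions trivial (all-singletons or single-block)
    return float((sum_ij - expected) / (max_index - expected))


def cluster_covariate_profile(
    labels: np.ndarray, demo: pd.DataFrame, covariates: tuple[str, ...] = ("age", "gender")
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster covariate summaries and outlier-vs-rest Welch t-tests.

    For each covariate the "outlier" cluster is the one whose mean deviates
    most from the grand mean; Welch two-sample t-tests compare it against
    every other cluster. Clusters with fewer than two members are skipped
    with a note.
    """
    labels = np.asarray(labels)
    if len(labels) != len(demo):
        raise ValueError("labels and demographics must cover the same subjects")
    ks = np.unique(labels)
    profile_rows = []
    for k in ks:
        sel = demo.loc[labels == k]
        row = {"cluster": int(k), "n": len(sel)}
        for cov in covariates:
            row[f"{cov}_mean"] = sel[cov].mean()
            row[f"{cov}_sd"] = sel[cov].std(ddof=1)
        profile_rows.append(row)
    profile = pd.DataFrame(profile_rows).set_index("cluster")

    test_rows = []
    for cov in covariates:
        grand = demo[cov].mean()
        deviations = (profile[f"{cov}_mean"] - grand).abs()
        outlier = int(deviations.idxmax())
        x = demo.loc[labels == outlier, cov]
        for k in ks:
            if k == outlier:
                continue
            y = demo.loc[labels == k, cov]
            if len(x) < 2 or len(y) < 2:
                test_rows.append(
                    {"covariate": cov, "outlier": outlier, "other": int(k),
                     "t": np.nan, "df": np.nan, "p": np.nan,
                     "note": "cluster with < 2 members; test skipped"}
                )
                continue
            res = stats.ttest_ind(x, y, equal_var=False)
            test_rows.append(
                {"covariate": cov, "outlier": outlier, "other": int(k),
                 "t": float(res.statistic), "df": float(res.df),
                 "p": float(res.pvalue), "note": ""}
            )
    return profile, pd.DataFrame(test_rows)
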