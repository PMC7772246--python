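"""Latent ability-trait extraction.

Dimensionality is chosen by Horn's parallel analysis, the common-factor
model is fitted by maximum likelihood (diagonal uniqueness — the model
that generalizes probabilistic PCA's isotropic noise), the solution is
varimax-rotated toward block structure, and any cohort can then be scored
with the frozen decomposition. Scoring a second cohort never refits
anything: the reference cohort alone determines the model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA, FactorAnalysis

from .datatypes import TRAIT_LABELS, ScoreMatrix

__all__ = [
    "FactorModel",
    "parallel_analysis",
    "fit_factor_model",
    "compare_fa_pca",
    "varimax_rotate",
    "varimax_criterion",
    "score_subjects",
    "variance_explained",
]

_HEYWOOD_FLOOR = 1e-3


def _factor_labels(k: int) -> list[str]:
    if k == len(TRAIT_LABELS):
        return list(TRAIT_LABELS)
    return [f"factor_{i + 1}" for i in range(k)]


@dataclass
class FactorModel:
    """Frozen maximum-likelihood factor decomposition.

    ``loadings`` is the (possibly rotated) vars x k pattern matrix,
    ``uniquenesses`` the per-variable residual variances, and ``rotation``
    the orthogonal matrix mapping the unrotated ML solution onto
    ``loadings``. The model-implied covariance ``L L' + diag(psi)`` is
    invariant under ``rotation``.
    """

    loadings: pd.DataFrame
    uniquenesses: pd.Series
    rotation: np.ndarray
    log_likelihood: float
    n_obs: int

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def communalities(self) -> pd.Series:
        return (self.loadings**2).sum(axis=1)

    def implied_covariance(self) -> np.ndarray:
        L = self.loadings.to_numpy()
        return L @ L.T + np.diag(self.uniquenesses.to_numpy())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variables": list(self.loadings.index),
            "factor_labels": list(self.loadings.columns),
            "loadings": self.loadings.to_numpy().tolist(),
            "uniquenesses": self.uniquenesses.to_numpy().tolist(),
            "rotation": np.asarray(self.rotation).tolist(),
            "log_likelihood": self.log_likelihood,
            "n_obs": self.n_obs,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FactorModel":
        d = json.loads(Path(path).read_text())
        idx = pd.Index(d["variables"], name="variable")
        return cls(
            loadings=pd.DataFrame(d["loadings"], index=idx, columns=d["factor_labels"]),
            uniquenesses=pd.Series(d["uniquenesses"], index=idx),
            rotation=np.asarray(d["rotation"]),
            log_likelihood=float(d["log_likelihood"]),
            n_obs=int(d["n_obs"]),
        )


# ---------------------------------------------------------------------------
# dimensionality
# ---------------------------------------------------------------------------

def parallel_analysis(
    m: ScoreMatrix,
    n_noise: int = 100,
    criterion: str = "mean",
    seed: int | None = None,
) -> int:
    """Horn's parallel analysis on the correlation matrix.

    Eigenvalues of the data correlation matrix are compared rank-by-rank
    with the summary (mean by default, 95th percentile optionally) of
    eigenvalues from ``n_noise`` same-shape white-noise datasets; the
    retained count is the run of leading data eigenvalues exceeding their
    noise counterpart.
    """
    if m.mask.any().any():
        raise ValueError("parallel analysis requires an imputed score matrix")
    X = m.values.to_numpy(dtype=float)
    n, p = X.shape
    if n < p:
        warnings.warn(f"fewer subjects ({n}) than variables ({p}); eigenvalues unstable")
    rng = np.random.default_rng(seed)

    data_eigs = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    noise_eigs = np.empty((n_noise, p))
    for b in range(n_noise):
        Z = rng.standard_normal((n, p))
        noise_eigs[b] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    if criterion == "mean":
        ref = noise_eigs.mean(axis=0)
    elif criterion in ("p95", "percentile95"):
        ref = np.percentile(noise_eigs, 95, axis=0)
    else:
        raise ValueError(f"unknown criterion {criterion!r}; use 'mean' or 'p95'")

    exceeds = data_eigs > ref
    k = 0
    for flag in exceeds:
        if not flag:
            break
        k += 1
    return k


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_factor_model(m: ScoreMatrix, k: int) -> FactorModel:
    """ML common-factor fit with diagonal uniquenesses.

    Heywood cases (uniqueness collapsing to zero) are clamped at
    ``1e-3`` with a warning rather than allowed to degenerate.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if m.mask.any().any():
        raise ValueError("impute before fitting the factor model")
    X = m.values.to_numpy(dtype=float)
    n, p = X.shape
    if k >= p:
        raise ValueError(
            f"k = {k} with {p} variables leaves no room for unique variances; "
            "the common-factor model is degenerate"
        )
    fa = FactorAnalysis(n_components=k, svd_method="lapack", max_iter=2000)
    fa.fit(X)
    loadings = fa.components_.T.copy()  # p x k
    uniq = fa.noise_variance_.copy()
    if (uniq < _HEYWOOD_FLOOR).any():
        warnings.warn(
            f"Heywood case: {(uniq < _HEYWOOD_FLOOR).sum()} uniqueness(es) "
            f"clamped at {_HEYWOOD_FLOOR}"
        )
        uniq = np.maximum(uniq, _HEYWOOD_FLOOR)
    loglik = float(fa.score(X) * n)
    idx = m.values.columns.copy()
    fm = FactorModel(
        loadings=pd.DataFrame(loadings, index=idx, columns=_factor_labels(k)),
        uniquenesses=pd.Series(uniq, index=idx),
        rotation=np.eye(k),
        log_likelihood=loglik,
        n_obs=n,
    )
    return fm


def compare_fa_pca(m: ScoreMatrix, k: int) -> dict[str, float]:
    """Log-likelihoods of the diagonal-noise FA model vs isotropic-noise PCA.

    The FA likelihood can never fall below probabilistic PCA's on the same
    data because the isotropic model is nested in the diagonal one.
    """
    X = m.values.to_numpy(dtype=float)
    n = X.shape[0]
    fm = fit_factor_model(m, k)
    pca = PCA(n_components=k).fit(X)
    return {"fa": fm.log_likelihood, "ppca": float(pca.score(X) * n)}


# ---------------------------------------------------------------------------
# rotation
# ---------------------------------------------------------------------------

def varimax_criterion(L: np.ndarray) -> float:
    """Column-wise variance of squared loadings (the quantity varimax maximizes)."""
    L2 = np.asarray(L) ** 2
    p = L2.shape[0]
    return float(np.sum(L2.var(axis=0)) * p)


def _varimax_rotation(
    L: np.ndarray, kaiser: bool = True, tol: float = 1e-8, max_iter: int = 1000
) -> np.ndarray:
    """Orthogonal rotation R maximizing the varimax criterion of ``L @ R``."""
    L = np.asarray(L, dtype=float)
    p, k = L.shape
    if k == 1:
        return np.eye(1)
    if kaiser:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        R = u @ vt
        d_old, d = d, s.sum()
        if d_old != 0 and d / d_old < 1 + tol:
            break
    return R


def varimax_rotate(fm: FactorModel, kaiser: bool = True) -> FactorModel:
    """Varimax-rotate a fitted model; canonicalize factor order and signs.

    Factors are sorted by explained variance (descending) and each factor's
    sign is fixed so its largest-|loading| variable loads positively
    (ties broken toward the lowest variable index). Communalities and the
    model-implied covariance are unchanged.
    """
    L = fm.loadings.to_numpy()
    R = _varimax_rotation(L, kaiser=kaiser)
    Lr = L @ R

    order = np.argsort(-(Lr**2).sum(axis=0), kind="stable")
    Lr = Lr[:, order]
    R = R[:, order]
    signs = np.ones(Lr.shape[1])
    for j in range(Lr.shape[1]):
        i_max = int(np.argmax(np.abs(Lr[:, j])))  # argmax takes lowest index on ties
        if Lr[i_max, j] < 0:
            signs[j] = -1.0
    Lr = Lr * signs
    R = R * signs

    return replace(
        fm,
        loadings=pd.DataFrame(Lr, index=fm.loadings.index, columns=fm.loadings.columns),
        rotation=fm.rotation @ R,
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_subjects(fm: FactorModel, m: ScoreMatrix) -> pd.DataFrame:
    """Regression (Thurstone) factor scores from the frozen loadings.

    ``F = Z Psi^{-1} L (L' Psi^{-1} L + I)^{-1}`` — the posterior mean of
    the latent traits given z-scored data. Deterministic and linear, so
    the identical decomposition transfers to any cohort scaled with the
    reference parameters.
    """
    missing = [v for v in fm.loadings.index if v not in m.values.columns]
    if missing:
        raise ValueError(f"score matrix lacks model variables: {missing}")
    Z = m.values[list(fm.loadings.index)].to_numpy(dtype=float)
    L = fm.loadings.to_numpy()
    psi_inv = 1.0 / fm.uniquenesses.to_numpy()
    A = L.T * psi_inv  # k x p
    W = (A.T) @ np.linalg.inv(A @ L + np.eye(fm.k))  # p x k
    scores = Z @ W
    return pd.DataFrame(scores, index=m.values.index, columns=fm.loadings.columns)


def variance_explained(fm: FactorModel) -> float:
    """Fraction of total standardized variance carried by the common factors.

    Computed as sum of communalities over the total model-implied variance
    (communality + uniqueness per variable); for z-scored data the
    denominator is approximately the variable count.
    """
    comm = fm.communalities.to_numpy()
    total = comm + fm.uniquenesses.to_numpy()
    return float(comm.sum() / total.sum())
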