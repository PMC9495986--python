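"""Per-gene linear models, empirical-Bayes variance moderation, moderated
t-tests, BH adjustment and DEG marking.

The variance model: residual variances s2_g given the true gene variance are
scaled chi-square with d_g degrees of freedom; the prior on gene variances is
scaled inverse chi-square with hyperparameters (d0, s0_sq). Hyperparameters
are estimated by matching the mean and dispersion of log s2_g through the
digamma/trigamma functions; d0 may be infinite (all genes share s0_sq).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_model import DEG_TABLE_COLUMNS
from .design import ModelMatrix

__all__ = [
    "EBHyperparams",
    "GeneFitCollection",
    "fit_linear_models",
    "estimate_eb_hyperparams",
    "trigamma_inverse",
    "moderated_t_test",
    "bh_adjust",
    "mark_degs",
    "build_deg_table",
]


@dataclass(frozen=True)
class EBHyperparams:
    """Prior degrees of freedom (may be ``inf``) and prior variance.

    ``d0 = 0`` disables moderation entirely (ordinary per-gene t-tests).
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError(f"d0 must be >= 0, got {self.d0}")
        if not (self.s0_sq > 0):
            raise ValueError(f"s0_sq must be > 0, got {self.s0_sq}")


@dataclass(frozen=True)
class GeneFitCollection:
    """Vectorized per-gene least-squares results.

    coefficients: genes x p; s_sq: residual variances; df: residual degrees of
    freedom (common to all genes); xtx_inv: p x p unscaled covariance of the
    coefficients (identity weights) or None when per-gene weights were used,
    in which case ``cov_per_gene`` holds genes x p x p matrices.
    """

    coefficients: np.ndarray
    s_sq: np.ndarray
    df: int
    xtx_inv: np.ndarray | None
    cov_per_gene: np.ndarray | None = None

    def contrast_variance(self, c: np.ndarray) -> np.ndarray:
        """Unscaled variance of c'beta per gene (v_g)."""
        if self.xtx_inv is not None:
            v = float(c @ self.xtx_inv @ c)
            return np.full(self.coefficients.shape[0], v)
        return np.einsum("i,gij,j->g", c, self.cov_per_gene, c)


def fit_linear_models(
    values: np.ndarray,
    mm: ModelMatrix,
    weights: np.ndarray | None = None,
) -> GeneFitCollection:
    """Gene-wise (weighted) least squares of expression on the model matrix.

    ``values`` is genes x samples; ``weights``, if given, is a genes x samples
    matrix of positive observation weights (the voom path).
    """
    X = mm.matrix
    n, p = X.shape
    rank = mm.rank
    if rank < p:
        raise ValueError("model matrix is rank deficient")
    df = n - rank
    if df <= 0:
        raise ValueError(
            f"no residual degrees of freedom: {n} samples, rank {rank} model"
        )
    Y = np.asarray(values, dtype=float)
    if Y.shape[1] != n:
        raise ValueError(f"{Y.shape[1]} samples in data vs {n} rows in model matrix")
    if weights is None:
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = Y @ X @ xtx_inv
        resid = Y - beta @ X.T
        s_sq = np.sum(resid**2, axis=1) / df
        return GeneFitCollection(beta, s_sq, df, xtx_inv)
    W = np.asarray(weights, dtype=float)
    if W.shape != Y.shape:
        raise ValueError("weights shape must match values shape")
    if np.any(W <= 0):
        raise ValueError("weights must be strictly positive")
    G = Y.shape[0]
    beta = np.empty((G, p))
    s_sq = np.empty(G)
    cov = np.empty((G, p, p))
    for g in range(G):
        w = W[g]
        Xw = X * w[:, None]
        xtwx_inv = np.linalg.inv(X.T @ Xw)
        b = xtwx_inv @ (Xw.T @ Y[g])
        r = Y[g] - X @ b
        beta[g] = b
        s_sq[g] = float(np.sum(w * r**2)) / df
        cov[g] = xtwx_inv
    return GeneFitCollection(beta, s_sq, df, None, cov)


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by monotone bisection."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    lo, hi = 1e-6, 1e8
    if special.polygamma(1, hi) > x:  # beyond representable: effectively infinite y
        return np.inf
    if special.polygamma(1, lo) < x:
        return lo
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid) > x:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10 * max(1.0, lo):
            break
    return 0.5 * (lo + hi)


def estimate_eb_hyperparams(
    s_sq: np.ndarray, df: np.ndarray | int
) -> EBHyperparams:
    """Closed-form moment estimator of (d0, s0_sq) from residual variances.

    Works on e_g = log s2_g - digamma(d_g/2) + log(d_g/2); the excess of the
    empirical dispersion of e over the trigamma term determines d0. Zero
    variances are excluded (log undefined) but still receive moderation
    downstream.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    d = np.broadcast_to(np.asarray(df, dtype=float), s_sq.shape)
    usable = (s_sq > 0) & (d > 0)
    s = s_sq[usable]
    dg = d[usable]
    G = s.size
    if G < 10:
        raise ValueError(f"need >= 10 genes with positive variance and df, got {G}")
    e = np.log(s) - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    ebar = float(np.mean(e))
    excess = float(
        np.mean((e - ebar) ** 2) * G / (G - 1) - np.mean(special.polygamma(1, dg / 2.0))
    )
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(ebar))
    else:
        d0 = 2.0 * trigamma_inverse(excess)
        if np.isinf(d0):
            s0_sq = float(np.exp(ebar))
        else:
            s0_sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBHyperparams(d0=d0, s0_sq=s0_sq)


def moderated_t_test(
    fit: GeneFitCollection, hp: EBHyperparams, c: np.ndarray
) -> pd.DataFrame:
    """Moderated t-statistics and two-sided p-values for one contrast.

    Posterior variance s~2 = (d0 s0^2 + d s2)/(d0 + d); the statistic is
    Student-t with d0 + d degrees of freedom (normal when d0 is infinite).
    With d0 = 0 this is exactly the classical per-gene t-test.
    """
    v = fit.contrast_variance(np.asarray(c, dtype=float))
    if np.any(v <= 0):
        raise ValueError("non-positive contrast variance")
    log2_fc = fit.coefficients @ np.asarray(c, dtype=float)
    d = float(fit.df)
    if np.isinf(hp.d0):
        s_tilde_sq = np.full_like(fit.s_sq, hp.s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (hp.d0 * hp.s0_sq + d * fit.s_sq) / (hp.d0 + d)
        df_total = hp.d0 + d
    with np.errstate(divide="ignore"):
        t = log2_fc / np.sqrt(s_tilde_sq * v)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame({"log2_fc": log2_fc, "stat": t, "p_value": p})


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, exact monotone enforcement."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def mark_degs(
    q: np.ndarray, log2_fc: np.ndarray, theta_f: float, alpha: float
) -> np.ndarray:
    """Three-state marking: sign(log2FC) iff q < alpha and |log2FC| > theta_f.

    Both inequalities are strict; everything else is 0.
    """
    if theta_f < 0:
        raise ValueError("theta_f must be >= 0")
    q = np.asarray(q, dtype=float)
    log2_fc = np.asarray(log2_fc, dtype=float)
    sig = (q < alpha) & (np.abs(log2_fc) > theta_f)
    return np.where(sig, np.sign(log2_fc).astype(int), 0).astype(int)


def build_deg_table(
    entry_ids: tuple[str, ...],
    avg_expression: np.ndarray,
    stats_frame: pd.DataFrame,
    q_value: np.ndarray,
    marking: np.ndarray,
) -> pd.DataFrame:
    """Assemble the per-contrast DEG table in its fixed column order."""
    n = len(entry_ids)
    for name, arr in (
        ("avg_expression", avg_expression),
        ("q_value", q_value),
        ("marking", marking),
    ):
        if len(arr) != n:
            raise ValueError(f"{name} has {len(arr)} rows for {n} entries")
    if len(stats_frame) != n:
        raise ValueError(f"stats frame has {len(stats_frame)} rows for {n} entries")
    table = pd.DataFrame(
        {
            "entry_id": list(entry_ids),
            "avg_expr": np.asarray(avg_expression, dtype=float),
            "log2_fc": stats_frame["log2_fc"].to_numpy(),
            "stat": stats_frame["stat"].to_numpy(),
            "p_value": stats_frame["p_value"].to_numpy(),
            "q_value": np.asarray(q_value, dtype=float),
            "marking": np.asarray(marking, dtype=int),
        }
    )
    assert list(table.columns) == DEG_TABLE_COLUMNS
    return table
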