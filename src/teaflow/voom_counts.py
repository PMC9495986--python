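"""Count-data entry point: log-cpm transformation plus precision weights from
a fitted mean-variance trend, feeding the moderated-t arm.

log-cpm uses the offset form log2((count + 0.5) / (libsize + 1) * 1e6). The
weight for each observation is the inverse fourth power of the predicted
square-root residual standard deviation at that observation's fitted log
count, where the prediction comes from a lowess trend (span 0.5, tricube
weights, 3 robustness iterations) of sqrt-s.d. on mean log count, linearly
extrapolated beyond the fitted range. No library-size normalization factors
(TMM and friends) are applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core_model import ExpressionMatrix
from .design import ModelMatrix
from .moderated_t import fit_linear_models

__all__ = ["CountMatrix", "log_cpm", "voom_weights"]

LOWESS_SPAN = 0.5
LOWESS_ITER = 3


@dataclass(frozen=True)
class CountMatrix:
    """Entries x samples matrix of non-negative integer counts."""

    entry_ids: tuple[str, ...]
    sample_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.issubdtype(v.dtype, np.integer):
            if not np.allclose(v, np.round(v)):
                raise ValueError("counts must be integers")
            v = np.round(v).astype(np.int64)
        if np.any(v < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.entry_ids), len(self.sample_names)):
            raise ValueError("count matrix shape does not match its labels")
        lib = v.sum(axis=0)
        if np.any(lib == 0):
            bad = [self.sample_names[j] for j in np.where(lib == 0)[0]]
            raise ValueError(f"zero library size for samples {bad}")

    @property
    def library_sizes(self) -> np.ndarray:
        return self.values.sum(axis=0)


def log_cpm(c: CountMatrix) -> ExpressionMatrix:
    """log2 counts per million with +0.5 count / +1 library-size offsets."""
    lib = c.library_sizes.astype(float)
    vals = np.log2((c.values + 0.5) / (lib + 1.0)[None, :] * 1e6)
    return ExpressionMatrix(c.entry_ids, c.sample_names, vals)


def _interp_extrap(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """np.interp with linear extrapolation using the edge slopes."""
    y = np.interp(x, xp, fp)
    if len(xp) >= 2:
        left = x < xp[0]
        right = x > xp[-1]
        if left.any():
            slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
            y[left] = fp[0] + slope * (x[left] - xp[0])
        if right.any():
            slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
            y[right] = fp[-1] + slope * (x[right] - xp[-1])
    return y


def voom_weights(c: CountMatrix, mm: ModelMatrix) -> np.ndarray:
    """Per-cell precision weights from the mean-variance trend.

    Returns a genes x samples matrix of finite positive weights.
    """
    if c.values.shape[0] < 50:
        raise ValueError(
            f"trend fitting needs >= 50 genes, got {c.values.shape[0]}"
        )
    lib = c.library_sizes.astype(float)
    y = log_cpm(c)
    fit = fit_linear_models(y.values, mm)
    fitted_logcpm = fit.coefficients @ mm.matrix.T
    # per-gene mean log2 count and sqrt residual s.d.
    mean_log_count = y.values.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sqrt_sd = fit.s_sq**0.25
    if np.all(sqrt_sd == 0):
        raise ValueError("degenerate mean-variance trend: all residual s.d. zero")
    trend = lowess(
        sqrt_sd,
        mean_log_count,
        frac=LOWESS_SPAN,
        it=LOWESS_ITER,
        return_sorted=True,
    )
    xp, fp = trend[:, 0], trend[:, 1]
    xp, idx = np.unique(xp, return_index=True)
    fp = fp[idx]
    # predict at each cell's fitted count on the log2 scale
    fitted_count_log2 = fitted_logcpm + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    pred = _interp_extrap(fitted_count_log2.ravel(), xp, fp).reshape(
        fitted_count_log2.shape
    )
    pred = np.maximum(pred, 1e-6)  # guard: sqrt-sd trend must stay positive
    w = pred**-4.0
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("non-finite or non-positive voom weights")
    return w
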