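"""Raw intensity preparation: load/merge, background correction (normexp),
quantile normalization, median-polish summarization, control handling and
replicate collapsing.

The raw input format is a plain-text table per sample with columns
``feature_id,intensity,control_class,replicate_key`` (linear-scale positive
intensities; ``control_class`` in {none, negative, other}). Two platform
flavors are supported: ``probeset`` (probes summarized into probe sets via
median polish, RMA-style) and ``single_probe`` (replicate probes collapsed by
their mean).

Background correction runs on linear intensities; log2 is taken on the
corrected values. The normexp model is observed X = S + B with
S ~ Exponential(alpha) and B ~ Normal(mu, sigma^2); the correction is the
posterior mean E[S | X = x].
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize, special

from .core_model import (
    ExpressionMatrix,
    RawIntensityBatch,
    RawSample,
    write_expression_matrix,
)

__all__ = [
    "NormexpParams",
    "load_raw_batch",
    "read_raw_sample",
    "estimate_normexp_params",
    "normexp_correct",
    "quantile_normalize",
    "median_polish_summarize",
    "collapse_replicates",
    "split_controls",
    "estimate_unexpressed_threshold",
    "prepare_pipeline",
]

logger = logging.getLogger("teaflow")

SIGMA_FLOOR = 1e-6
ALPHA_FLOOR = 1e-6


@dataclass(frozen=True)
class NormexpParams:
    """Background mean/s.d. and exponential signal mean, linear scale."""

    mu: float
    sigma: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and self.alpha > 0):
            raise ValueError(
                f"sigma and alpha must be positive, got sigma={self.sigma}, "
                f"alpha={self.alpha}"
            )


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def read_raw_sample(path: str | Path) -> RawSample:
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["feature_id", "intensity", "control_class", "replicate_key"]:
            raise ValueError(
                f"{path}: expected header "
                "'feature_id,intensity,control_class,replicate_key', "
                f"got {header}"
            )
        fids, vals, classes, keys = [], [], [], []
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise ValueError(f"{path}: row {i} has {len(row)} fields, expected 4")
            fids.append(row[0])
            try:
                vals.append(float(row[1]))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric intensity {row[1]!r} at row {i}"
                ) from None
            classes.append(row[2])
            keys.append(row[3])
    return RawSample(
        sample_name=path.stem,
        feature_ids=tuple(fids),
        intensities=np.array(vals),
        control_classes=tuple(classes),
        replicate_keys=tuple(keys),
    )


def load_raw_batch(directory: str | Path, pattern: str = r".*\.csv$") -> RawIntensityBatch:
    """Load every file in *directory* whose name matches *pattern* (regex)."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    rx = re.compile(pattern)
    paths = sorted(p for p in directory.iterdir() if p.is_file() and rx.search(p.name))
    if len(paths) < 2:
        raise ValueError(
            f"pattern {pattern!r} matched {len(paths)} file(s) in {directory}; "
            "need at least 2 samples"
        )
    samples = tuple(read_raw_sample(p) for p in paths)
    return RawIntensityBatch(samples)


# ---------------------------------------------------------------------------
# Normexp
# ---------------------------------------------------------------------------


def _normexp_negloglik(params: np.ndarray, x: np.ndarray) -> float:
    mu, log_sigma, log_alpha = params
    sigma = np.exp(log_sigma)
    alpha = np.exp(log_alpha)
    # density of X = S + B: (1/a) exp((mu - x)/a + s^2/(2 a^2)) * Phi((x - mu - s^2/a)/s)
    z = (x - mu - sigma**2 / alpha) / sigma
    ll = (
        -np.log(alpha)
        + (mu - x) / alpha
        + sigma**2 / (2 * alpha**2)
        + special.log_ndtr(z)
    )
    return -float(np.sum(ll))


def estimate_normexp_params(
    intensities: np.ndarray, negative_controls: np.ndarray | None = None
) -> NormexpParams:
    """Estimate normexp parameters.

    With negative controls: mu and sigma are their mean and s.d. (sigma floored
    to avoid degeneracy) and alpha is the foreground mean excess over mu.
    Without controls: maximum likelihood on the convolution density.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 50:
        raise ValueError(f"need >= 50 intensities to estimate normexp, got {x.size}")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("intensities must be positive and finite")
    scale = float(np.mean(x))
    if negative_controls is not None and len(negative_controls) > 0:
        nc = np.asarray(negative_controls, dtype=float)
        if np.any(nc <= 0):
            raise ValueError("negative control intensities must be positive")
        mu = float(np.mean(nc))
        sigma = max(float(np.std(nc, ddof=1)) if nc.size > 1 else 0.0,
                    SIGMA_FLOOR * scale)
        alpha = max(scale - mu, ALPHA_FLOOR * scale)
        return NormexpParams(mu=mu, sigma=sigma, alpha=alpha)
    # MLE, initialized from low-quantile summaries
    q5 = float(np.percentile(x, 5))
    low = x[x < np.percentile(x, 10)]
    sigma0 = float(np.std(low, ddof=1)) if low.size > 1 else scale * 0.01
    sigma0 = max(sigma0, SIGMA_FLOOR * scale)
    alpha0 = max(float(np.mean(x - q5)), ALPHA_FLOOR * scale)
    x0 = np.array([q5, np.log(sigma0), np.log(alpha0)])
    res = optimize.minimize(
        _normexp_negloglik,
        x0,
        args=(x,),
        method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(
            f"normexp MLE did not converge: {res.message} "
            f"(nit={res.nit}, fun={res.fun:.6g}, x={res.x})"
        )
    mu, sigma, alpha = res.x[0], float(np.exp(res.x[1])), float(np.exp(res.x[2]))
    return NormexpParams(mu=float(mu), sigma=max(sigma, SIGMA_FLOOR * scale),
                         alpha=max(alpha, ALPHA_FLOOR * scale))


def normexp_correct(x: np.ndarray | float, p: NormexpParams) -> np.ndarray:
    """Posterior mean of the signal, E[S | X = x].

    S | X=x is Normal(m, sigma^2) truncated to (0, inf) with
    m = x - mu - sigma^2/alpha, so E[S|X=x] = m + sigma * phi(m/s)/Phi(m/s).
    The Mills ratio phi/Phi is evaluated in log space for stability; the
    result is strictly positive and non-decreasing in x.
    """
    xv = np.asarray(x, dtype=float)
    m = xv - p.mu - p.sigma**2 / p.alpha
    z = m / p.sigma
    # phi(z)/Phi(z) = exp(log phi - log Phi); stable for z << 0
    mills = np.exp(-0.5 * z**2 - 0.5 * np.log(2 * np.pi) - special.log_ndtr(z))
    out = m + p.sigma * mills
    # truncated-normal mean is mathematically > 0; clamp guards rounding only
    out = np.maximum(out, np.finfo(float).tiny)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Normalization / summarization
# ---------------------------------------------------------------------------


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force identical per-sample distributions by rank-wise averaging.

    Tied values within a column receive the mean of the reference values over
    their tied rank span.
    """
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    v = m.values
    order = np.argsort(v, axis=0, kind="stable")
    reference = np.mean(np.take_along_axis(v, order, axis=0), axis=1)
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        col = v[:, j]
        oj = order[:, j]
        sorted_col = col[oj]
        assigned = reference.copy()
        # average reference over runs of equal values (tie spans)
        start = 0
        for i in range(1, len(sorted_col) + 1):
            if i == len(sorted_col) or sorted_col[i] != sorted_col[start]:
                if i - start > 1:
                    assigned[start:i] = np.mean(reference[start:i])
                start = i
        out[oj, j] = assigned
    return m.with_values(out)


def median_polish_summarize(
    probe_values: np.ndarray, max_iter: int = 10, tol: float = 1e-4
) -> np.ndarray:
    """Two-way median polish; returns overall + column effects per sample."""
    v = np.asarray(probe_values, dtype=float)
    if v.ndim != 2 or v.size == 0:
        raise ValueError("probe_values must be a non-empty 2-D array")
    resid = v.copy()
    row_eff = np.zeros(v.shape[0])
    col_eff = np.zeros(v.shape[1])
    overall = 0.0
    for _ in range(max_iter):
        rm = np.median(resid, axis=1)
        resid -= rm[:, None]
        row_eff += rm
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta
        cm = np.median(resid, axis=0)
        resid -= cm[None, :]
        col_eff += cm
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta
        change = max(np.max(np.abs(rm)), np.max(np.abs(cm)))
        if change < tol:
            break
    return overall + col_eff


def collapse_replicates(
    m: ExpressionMatrix, replicate_keys: tuple[str, ...]
) -> ExpressionMatrix:
    """One row per replicate key, value = mean of member rows per sample.

    Output rows follow the first-appearance order of keys.
    """
    if len(replicate_keys) != m.n_entries:
        raise ValueError(
            f"{len(replicate_keys)} replicate keys for {m.n_entries} entries"
        )
    seen: dict[str, list[int]] = {}
    order: list[str] = []
    for i, k in enumerate(replicate_keys):
        if k not in seen:
            seen[k] = []
            order.append(k)
        seen[k].append(i)
    out = np.empty((len(order), m.n_samples))
    for r, k in enumerate(order):
        out[r] = m.values[seen[k]].mean(axis=0)
    return ExpressionMatrix(tuple(order), m.sample_names, out)


def summarize_probesets(
    m: ExpressionMatrix, replicate_keys: tuple[str, ...]
) -> ExpressionMatrix:
    """Median-polish each probe set (grouped by replicate key) into one row."""
    if len(replicate_keys) != m.n_entries:
        raise ValueError(
            f"{len(replicate_keys)} replicate keys for {m.n_entries} entries"
        )
    seen: dict[str, list[int]] = {}
    order: list[str] = []
    for i, k in enumerate(replicate_keys):
        if k not in seen:
            seen[k] = []
            order.append(k)
        seen[k].append(i)
    out = np.empty((len(order), m.n_samples))
    for r, k in enumerate(order):
        out[r] = median_polish_summarize(m.values[seen[k]])
    return ExpressionMatrix(tuple(order), m.sample_names, out)


# ---------------------------------------------------------------------------
# Controls
# ---------------------------------------------------------------------------


def split_controls(batch: RawIntensityBatch) -> tuple[RawIntensityBatch, np.ndarray]:
    """Drop control features; return them plus pooled negative-control log2
    intensities (across all samples) for threshold estimation."""
    classes = batch.samples[0].control_classes
    keep = [i for i, c in enumerate(classes) if c == "none"]
    neg = [i for i, c in enumerate(classes) if c == "negative"]
    if not keep:
        raise ValueError("all features are flagged as controls")
    neg_log2 = np.log2(
        np.concatenate([s.intensities[neg] for s in batch.samples])
    ) if neg else np.array([])
    new_samples = tuple(
        RawSample(
            sample_name=s.sample_name,
            feature_ids=tuple(s.feature_ids[i] for i in keep),
            intensities=s.intensities[keep],
            control_classes=tuple(s.control_classes[i] for i in keep),
            replicate_keys=tuple(s.replicate_keys[i] for i in keep),
        )
        for s in batch.samples
    )
    return RawIntensityBatch(new_samples), neg_log2


def estimate_unexpressed_threshold(neg_control_log2: np.ndarray) -> float:
    """95th percentile (linear interpolation) of negative-control log2 values.

    Negative controls stay unhybridized, so their intensity distribution
    estimates the expected intensity of unexpressed genes; the threshold is
    logged and can be overridden downstream.
    """
    v = np.asarray(neg_control_log2, dtype=float)
    if v.size == 0:
        raise ValueError("no negative-control intensities available")
    if v.size < 10:
        logger.warning(
            "only %d negative-control values; using their maximum as threshold",
            v.size,
        )
        return float(np.max(v))
    t = float(np.percentile(v, 95))
    logger.info("unexpressed-intensity threshold (95th pct of negatives): %.4f", t)
    return t


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def prepare_pipeline(
    directory: str | Path,
    platform: str,
    pattern: str = r".*\.csv$",
    remove_controls: bool = True,
    output_csv: str | Path | None = None,
    qc_dir: str | Path | None = None,
):
    """Full preparation: load, correct, normalize, summarize, write.

    Returns ``(matrix, qc_artifacts, threshold_or_None)``. ``qc_artifacts``
    maps names to data frames of pre-/post-normalization QC statistics.
    """
    from . import qc_metrics  # deferred: qc is optional plumbing here

    if platform not in ("probeset", "single_probe"):
        raise ValueError(f"platform must be 'probeset' or 'single_probe', got {platform!r}")
    logger.info("prepare: loading %s with pattern %r", directory, pattern)
    batch = load_raw_batch(directory, pattern)
    logger.info(
        "prepare: %d samples x %d features", len(batch.samples), len(batch.feature_ids)
    )

    raw = batch.intensity_matrix()
    pre_matrix = ExpressionMatrix(batch.feature_ids, batch.sample_names, np.log2(raw))
    qc: dict[str, object] = {}
    qc["pre_distribution"] = qc_metrics.distribution_summary(pre_matrix)[0]

    classes = batch.samples[0].control_classes
    neg_idx = [i for i, c in enumerate(classes) if c == "negative"]
    corrected = np.empty_like(raw)
    for j, s in enumerate(batch.samples):
        neg = s.intensities[neg_idx] if neg_idx else None
        params = estimate_normexp_params(s.intensities, neg)
        logger.info(
            "normexp sample %s: mu=%.4g sigma=%.4g alpha=%.4g",
            s.sample_name, params.mu, params.sigma, params.alpha,
        )
        corrected[:, j] = normexp_correct(raw[:, j], params)

    log_m = ExpressionMatrix(batch.feature_ids, batch.sample_names, np.log2(corrected))
    norm_m = quantile_normalize(log_m)
    qc["post_distribution"] = qc_metrics.distribution_summary(norm_m)[0]

    threshold = None
    keys = batch.samples[0].replicate_keys
    if remove_controls:
        keep_mask = np.array([c == "none" for c in classes])
        if not keep_mask.any():
            raise ValueError("all features are flagged as controls")
        if neg_idx:
            # threshold from corrected+normalized negative-control values
            neg_log2 = norm_m.values[neg_idx].ravel()
            threshold = estimate_unexpressed_threshold(neg_log2)
        norm_m = norm_m.subset_entries(np.where(keep_mask)[0])
        keys = tuple(k for k, keep in zip(keys, keep_mask) if keep)

    if platform == "probeset":
        final = summarize_probesets(norm_m, keys)
    else:
        final = collapse_replicates(norm_m, keys)
    logger.info("prepare: final matrix %d x %d", final.n_entries, final.n_samples)

    if output_csv is not None:
        write_expression_matrix(final, output_csv)
    if qc_dir is not None:
        qc_dir = Path(qc_dir)
        qc_dir.mkdir(parents=True, exist_ok=True)
        for name, frame in qc.items():
            frame.to_csv(qc_dir / f"{name}.csv", index=False)
    return final, qc, threshold
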