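"""QC statistics: MA statistics against the leave-one-out median profile,
loess-linearity sample ordering, PCA, hierarchical clustering, distribution
summaries, per-group mean-variance points, and marked-set overlap counts.

All operations are pure: the input matrix is never modified and repeated
calls return identical results. Basic matplotlib renderings are provided for
the CLI's figures directory.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core_model import ExpressionMatrix

__all__ = [
    "ma_statistics",
    "order_by_loess_linearity",
    "pca_coords",
    "hierarchical_tree",
    "distribution_summary",
    "mean_variance_points",
    "overlap_counts",
    "render_qc_figures",
]

MA_LOWESS_SPAN = 0.3


def ma_statistics(m: ExpressionMatrix, sample: str) -> pd.DataFrame:
    """Per-entry (A, M) of one sample against the others' median profile.

    ref_g = median over the other samples; M = sample - ref; A = (sample+ref)/2.
    """
    if m.n_samples < 3:
        raise ValueError("MA statistics need at least 3 samples")
    if sample not in m.sample_names:
        raise ValueError(f"unknown sample {sample!r}")
    j = m.sample_names.index(sample)
    others = np.delete(m.values, j, axis=1)
    ref = np.median(others, axis=1)
    x = m.values[:, j]
    return pd.DataFrame(
        {"entry_id": list(m.entry_ids), "A": (x + ref) / 2.0, "M": x - ref}
    )


def _linearity_score(a: np.ndarray, mvals: np.ndarray) -> float:
    """RMS deviation of the loess curve of M on A from its own straight line."""
    fit = lowess(mvals, a, frac=MA_LOWESS_SPAN, it=3, return_sorted=True)
    xs, ys = fit[:, 0], fit[:, 1]
    coef = np.polynomial.polynomial.polyfit(xs, ys, 1)
    line = coef[0] + coef[1] * xs
    return float(np.sqrt(np.mean((ys - line) ** 2)))


def order_by_loess_linearity(m: ExpressionMatrix) -> pd.DataFrame:
    """Samples sorted least-linear first by the MA-loess linearity score."""
    if m.n_samples < 3:
        raise ValueError("ordering needs at least 3 samples")
    rows = []
    for s in m.sample_names:
        ma = ma_statistics(m, s)
        score = _linearity_score(ma["A"].to_numpy(), ma["M"].to_numpy())
        rows.append((s, score))
    frame = pd.DataFrame(rows, columns=["sample_name", "score"])
    frame = frame.sort_values(
        ["score", "sample_name"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    frame.insert(0, "order", np.arange(1, len(frame) + 1))
    return frame


def pca_coords(m: ExpressionMatrix, n_components: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample coordinates from entry-centered SVD plus explained fractions.

    Sign convention: within each component the largest-magnitude loading is
    made positive, so results are deterministic.
    """
    max_comp = min(m.n_samples - 1, m.n_entries)
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components must be in [1, {max_comp}], got {n_components}"
        )
    x = m.values.T  # samples as observations
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for k in range(len(s)):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    coords = u[:, :n_components] * s[:n_components]
    total = float(np.sum(s**2))
    explained = (s**2 / total) if total > 0 else np.zeros_like(s)
    frame = pd.DataFrame(
        coords,
        index=pd.Index(m.sample_names, name="sample_name"),
        columns=[f"PC{k + 1}" for k in range(n_components)],
    ).reset_index()
    return frame, explained


def hierarchical_tree(m: ExpressionMatrix) -> np.ndarray:
    """Complete-linkage merge matrix on Euclidean sample distances.

    Returns the scipy linkage matrix (n-1 x 4); merge heights are monotone
    non-decreasing for complete linkage.
    """
    if m.n_samples < 2:
        raise ValueError("clustering needs at least 2 samples")
    d = pdist(m.values.T, metric="euclidean")
    return linkage(d, method="complete")


def distribution_summary(
    m: ExpressionMatrix, grid_points: int = 512
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Five-number summaries and shared-grid Gaussian kernel densities.

    Returns ``(summary, density)`` frames; densities use Silverman bandwidth
    on a common grid spanning the matrix range.
    """
    rows = []
    for j, s in enumerate(m.sample_names):
        col = m.values[:, j]
        q1, med, q3 = np.percentile(col, [25, 50, 75])
        rows.append((s, float(np.min(col)), float(q1), float(med), float(q3),
                     float(np.max(col))))
    summary = pd.DataFrame(
        rows, columns=["sample_name", "min", "q1", "median", "q3", "max"]
    )
    lo, hi = float(np.min(m.values)), float(np.max(m.values))
    span = hi - lo if hi > lo else 1.0
    # generous padding so kernel tails are captured by trapezoid integration
    grid = np.linspace(lo - 0.25 * span, hi + 0.25 * span, grid_points)
    dens: dict[str, np.ndarray] = {"x": grid}
    for j, s in enumerate(m.sample_names):
        col = m.values[:, j]
        if np.ptp(col) == 0:
            # degenerate sample: narrow Gaussian spike at the shared value
            sd = 1e-3 * span
            dens[s] = stats.norm.pdf(grid, loc=col[0], scale=sd)
        else:
            kde = stats.gaussian_kde(col, bw_method="silverman")
            dens[s] = kde(grid)
    return summary, pd.DataFrame(dens)


def mean_variance_points(
    m: ExpressionMatrix, groups: tuple[str, ...]
) -> dict[str, pd.DataFrame]:
    """Per group: per-entry sample mean and unbiased variance."""
    if len(groups) != m.n_samples:
        raise ValueError(f"{len(groups)} group labels for {m.n_samples} samples")
    out: dict[str, pd.DataFrame] = {}
    for lv in sorted(set(groups)):
        idx = [i for i, g in enumerate(groups) if g == lv]
        if len(idx) < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 samples")
        sub = m.values[:, idx]
        out[lv] = pd.DataFrame(
            {
                "entry_id": list(m.entry_ids),
                "mean": sub.mean(axis=1),
                "variance": sub.var(axis=1, ddof=1),
            }
        )
    return out


def overlap_counts(set_a: set[str], set_b: set[str]) -> tuple[int, int, int]:
    """(only in a, shared, only in b) — the Venn counts."""
    a, b = set(set_a), set(set_b)
    return len(a - b), len(a & b), len(b - a)


def render_qc_figures(m: ExpressionMatrix, groups: tuple[str, ...] | None,
                      out_dir) -> list[str]:
    """Render basic QC figures (boxplot, density, PCA, dendrogram) as PNG."""
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot([m.values[:, j] for j in range(m.n_samples)],
               tick_labels=list(m.sample_names))
    ax.set_ylabel("log2 expression")
    plt.setp(ax.get_xticklabels(), rotation=90)
    fig.tight_layout()
    p = out_dir / "boxplot.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(str(p))

    _, dens = distribution_summary(m)
    fig, ax = plt.subplots(figsize=(6, 4))
    for s in m.sample_names:
        ax.plot(dens["x"], dens[s], label=s, lw=0.8)
    ax.set_xlabel("log2 expression")
    ax.set_ylabel("density")
    fig.tight_layout()
    p = out_dir / "density.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(str(p))

    if m.n_samples >= 3:
        coords, explained = pca_coords(m, 2)
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(coords["PC1"], coords["PC2"])
        for _, row in coords.iterrows():
            ax.annotate(row["sample_name"], (row["PC1"], row["PC2"]), fontsize=7)
        ax.set_xlabel(f"PC1 ({explained[0] * 100:.1f}%)")
        ax.set_ylabel(f"PC2 ({explained[1] * 100:.1f}%)")
        fig.tight_layout()
        p = out_dir / "pca.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(str(p))

    z = hierarchical_tree(m)
    fig, ax = plt.subplots(figsize=(6, 4))
    dendrogram(z, labels=list(m.sample_names), ax=ax)
    plt.setp(ax.get_xticklabels(), rotation=90)
    fig.tight_layout()
    p = out_dir / "dendrogram.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(str(p))
    return written
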