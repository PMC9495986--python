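"""Seeded synthetic-data generators with known ground truth.

Three generators cover the pipeline's three entry points: a log2 expression
matrix with a known differentially expressed subset (variances drawn from a
scaled inverse chi-square prior so the moderated-t model is exactly
satisfied), a raw intensity batch following the exponential-signal-plus-
normal-background model, and a negative-binomial count matrix for the voom
path. Each generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_model import ExpressionMatrix
from .voom_counts import CountMatrix

__all__ = [
    "ExpressionTruth",
    "CountTruth",
    "generate_expression_dataset",
    "generate_raw_batch",
    "generate_count_dataset",
]


@dataclass(frozen=True)
class ExpressionTruth:
    de_ids: tuple[str, ...]
    de_signs: dict[str, int]
    groups: tuple[str, ...]
    batch_labels: tuple[str, ...] | None


@dataclass(frozen=True)
class CountTruth:
    de_ids: tuple[str, ...]
    de_signs: dict[str, int]
    groups: tuple[str, ...]


def generate_expression_dataset(
    genes: int,
    n_per_group: int,
    de_fraction: float,
    log2fc: float,
    d0: float = 4.0,
    s0_sq: float = 0.05,
    batch_shift: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Two-group log2 expression data with a known DE subset.

    Gene variances are s0_sq * d0 / chi2_{d0}; baseline means are
    Normal(7, 1.5^2); DE genes get a +/-log2fc shift (random sign) in the
    test group. With ``batch_shift`` nonzero, a random half of the samples
    receives an additive shift and the assignment is recorded in the truth.
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError(f"de_fraction must be in [0, 1], got {de_fraction}")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    groups = ("control",) * n_per_group + ("treated",) * n_per_group
    sigma_sq = s0_sq * d0 / rng.chisquare(d0, size=genes)
    base = rng.normal(7.0, 1.5, size=genes)
    n_de = int(round(genes * de_fraction))
    de_idx = rng.choice(genes, size=n_de, replace=False)
    signs = rng.choice([-1, 1], size=n_de)
    shift = np.zeros(genes)
    shift[de_idx] = signs * log2fc
    means = np.tile(base[:, None], (1, n))
    means[:, n_per_group:] += shift[:, None]
    values = means + rng.normal(size=(genes, n)) * np.sqrt(sigma_sq)[:, None]
    batch_labels = None
    if batch_shift != 0.0:
        half = rng.permutation(n)[: n // 2]
        values[:, half] += batch_shift
        labels = np.array(["b1"] * n)
        labels[half] = "b2"
        batch_labels = tuple(labels)
    ids = tuple(f"gene_{i + 1}" for i in range(genes))
    de_ids = tuple(ids[i] for i in sorted(de_idx))
    sign_map = {ids[i]: int(s) for i, s in zip(de_idx, signs)}
    matrix = ExpressionMatrix(
        ids,
        tuple(f"s{j + 1}_{g}" for j, g in enumerate(groups)),
        values,
    )
    return matrix, ExpressionTruth(de_ids, sign_map, groups, batch_labels)


def generate_raw_batch(
    out_dir: str | Path,
    probesets: int = 50,
    probes_per_set: int = 4,
    samples: int = 4,
    mu: float = 100.0,
    sigma: float = 10.0,
    alpha: float = 500.0,
    n_neg_controls: int = 50,
    seed: int = 0,
) -> tuple[list[Path], np.ndarray]:
    """Write one raw CSV per sample; returns (paths, true log2 expression).

    Intensity = Normal(mu, sigma^2) background + Exponential(alpha * factor)
    signal, truncated positive; negative controls carry background only. The
    true expression factor per probe set is shared across samples.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    factors = rng.lognormal(mean=0.0, sigma=1.0, size=probesets)
    paths = []
    n_feat = probesets * probes_per_set
    for s in range(samples):
        lines = ["feature_id,intensity,control_class,replicate_key"]
        bg = rng.normal(mu, sigma, size=n_feat + n_neg_controls)
        sig = rng.exponential(
            np.repeat(alpha * factors, probes_per_set)
        )
        for i in range(n_feat):
            ps = i // probes_per_set
            val = float(max(bg[i] + sig[i], 1e-3))
            lines.append(f"p{i + 1},{val!r},none,ps{ps + 1}")
        for k in range(n_neg_controls):
            val = float(max(bg[n_feat + k], 1e-3))
            lines.append(f"neg{k + 1},{val!r},negative,neg{k + 1}")
        path = out_dir / f"sample_{s + 1}.csv"
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        paths.append(path)
    true_log2 = np.log2(alpha * factors)
    return paths, true_log2


def generate_count_dataset(
    genes: int,
    n_per_group: int,
    de_fraction: float,
    fold: float,
    dispersion: float = 0.1,
    lib_size: float = 1e6,
    seed: int = 0,
) -> tuple[CountMatrix, CountTruth]:
    """Negative-binomial two-group counts with a known DE subset.

    Baseline relative abundances are drawn log-normal and scaled to
    ``lib_size``; DE genes are multiplied by ``fold`` (or 1/fold, random
    direction) in the test group. NB parameterized by its dispersion phi:
    variance = m + phi * m^2.
    """
    if dispersion <= 0:
        raise ValueError(f"dispersion must be > 0, got {dispersion}")
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError(f"de_fraction must be in [0, 1], got {de_fraction}")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    groups = ("control",) * n_per_group + ("treated",) * n_per_group
    rel = rng.lognormal(mean=0.0, sigma=1.0, size=genes)
    rel /= rel.sum()
    n_de = int(round(genes * de_fraction))
    de_idx = rng.choice(genes, size=n_de, replace=False)
    signs = rng.choice([-1, 1], size=n_de)
    mult = np.ones(genes)
    mult[de_idx] = np.where(signs > 0, fold, 1.0 / fold)
    mean = np.tile((rel * lib_size)[:, None], (1, n))
    mean[:, n_per_group:] *= mult[:, None]
    # NB via gamma-Poisson: shape 1/phi, scale m*phi
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    counts = rng.poisson(lam)
    ids = tuple(f"gene_{i + 1}" for i in range(genes))
    matrix = CountMatrix(
        ids,
        tuple(f"s{j + 1}_{g}" for j, g in enumerate(groups)),
        counts,
    )
    de_ids = tuple(ids[i] for i in sorted(de_idx))
    sign_map = {ids[i]: int(s) for i, s in zip(de_idx, signs)}
    return matrix, CountTruth(de_ids, sign_map, groups)
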