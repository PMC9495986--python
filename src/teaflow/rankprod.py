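"""Non-parametric DEG detection by rank products with permutation PFP.

For a two-group contrast, every test-vs-reference sample pair (within the
same batch stratum, or within the same pair for paired designs) yields one
log2-ratio column. Genes are ranked within each column (rank 1 = strongest)
and the rank product is the geometric mean of a gene's ranks. Significance
comes from permutations that independently shuffle gene labels within each
column: the pooled permuted rank products give a per-gene p estimate and the
proportion of false positives PFP = E_g / rank(RP_g).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import ExpressionMatrix

__all__ = [
    "RankProdResult",
    "compute_pairwise_ratios",
    "rank_product_stat",
    "permutation_pfp",
    "rankprod_analysis",
]


@dataclass(frozen=True)
class RankProdResult:
    """Per-gene up/down rank products with permutation p and PFP estimates."""

    rp_up: np.ndarray
    rp_down: np.ndarray
    p_up: np.ndarray
    p_down: np.ndarray
    pfp_up: np.ndarray
    pfp_down: np.ndarray


def compute_pairwise_ratios(
    m: ExpressionMatrix,
    groups: tuple[str, ...],
    contrast: tuple[str, str],
    pairing: tuple[str, ...] | None = None,
    batches: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Genes x K matrix of test-minus-reference log2 differences.

    Unpaired: all test x reference sample pairs within each batch stratum
    (no cross-batch pairs). Paired: one column per pair id.
    """
    test, ref = contrast
    n = m.n_samples
    if len(groups) != n:
        raise ValueError(f"{len(groups)} group labels for {n} samples")
    v = m.values
    if pairing is not None:
        pairs: dict[str, dict[str, int]] = {}
        for i, (g, p) in enumerate(zip(groups, pairing)):
            if g in (test, ref):
                pairs.setdefault(p, {})[g] = i
        cols = []
        for pid in sorted(pairs):
            members = pairs[pid]
            if set(members) != {test, ref}:
                raise ValueError(
                    f"pair {pid!r} lacks one of the contrast levels {test}/{ref}"
                )
            cols.append(v[:, members[test]] - v[:, members[ref]])
        if not cols:
            raise ValueError("no complete pairs for this contrast")
        return np.column_stack(cols)
    strata = batches if batches is not None else ("_all",) * n
    cols = []
    for b in sorted(set(strata)):
        t_idx = [i for i in range(n) if strata[i] == b and groups[i] == test]
        r_idx = [i for i in range(n) if strata[i] == b and groups[i] == ref]
        if (t_idx and not r_idx) or (r_idx and not t_idx):
            raise ValueError(
                f"batch stratum {b!r} has samples from only one contrast level"
            )
        for ti in t_idx:
            for ri in r_idx:
                cols.append(v[:, ti] - v[:, ri])
    if not cols:
        raise ValueError(f"no {test} x {ref} sample pairs available")
    return np.column_stack(cols)


def _column_ranks(ratios: np.ndarray, descending: bool) -> np.ndarray:
    """Average-tie ranks per column; rank 1 = largest (descending) or smallest."""
    x = -ratios if descending else ratios
    return np.apply_along_axis(stats.rankdata, 0, x)


def rank_product_stat(ratios: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (RP_up, RP_down): geometric means of the per-column ranks."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.ndim != 2 or ratios.shape[0] < 2:
        raise ValueError("need a genes x comparisons matrix with >= 2 genes")
    up_ranks = _column_ranks(ratios, descending=True)
    down_ranks = _column_ranks(ratios, descending=False)
    rp_up = np.exp(np.mean(np.log(up_ranks), axis=1))
    rp_down = np.exp(np.mean(np.log(down_ranks), axis=1))
    return rp_up, rp_down


def _perm_p_pfp(
    log_ranks: np.ndarray, observed_rp: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation counts for one direction.

    Shuffling gene labels within a column is equivalent to shuffling that
    column of the (log-)rank matrix, so the observed log-ranks are permuted
    directly instead of re-ranking.
    """
    G, K = log_ranks.shape
    obs_order = np.argsort(observed_rp, kind="stable")
    obs_sorted = observed_rp[obs_order]
    counts = np.zeros(G, dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permuted(log_ranks, axis=0)
        rp_perm = np.exp(np.mean(perm, axis=1))
        rp_perm.sort()
        counts += np.searchsorted(rp_perm, obs_sorted, side="right")
    c = np.empty(G, dtype=np.int64)
    c[obs_order] = counts
    e = c / n_perm
    p = c / (n_perm * G)
    rank_asc = stats.rankdata(observed_rp, method="average")
    pfp = e / rank_asc
    return p, pfp


def permutation_pfp(
    ratios: np.ndarray,
    rp_up: np.ndarray,
    rp_down: np.ndarray,
    n_perm: int,
    seed: int,
) -> RankProdResult:
    """Permutation p and PFP per direction; deterministic for a fixed seed."""
    if n_perm < 100:
        raise ValueError(f"need >= 100 permutations, got {n_perm}")
    up_ranks = _column_ranks(ratios, descending=True)
    down_ranks = _column_ranks(ratios, descending=False)
    rng_up = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    rng_down = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    p_up, pfp_up = _perm_p_pfp(np.log(up_ranks), rp_up, n_perm, rng_up)
    p_down, pfp_down = _perm_p_pfp(np.log(down_ranks), rp_down, n_perm, rng_down)
    return RankProdResult(rp_up, rp_down, p_up, p_down, pfp_up, pfp_down)


def rankprod_analysis(
    ratios: np.ndarray, n_perm: int, seed: int
) -> tuple[RankProdResult, pd.DataFrame]:
    """Run both directions and merge them into one signed table.

    Per gene the direction with the smaller p estimate wins (sign +1 for up,
    -1 for down); an exact tie keeps the up-direction statistic but a zero
    sign so the marking stays 0. Raw PFP is kept in ``pfp_raw``; the table's
    ``pfp`` column is clipped to [0, 1].
    """
    rp_up, rp_down = rank_product_stat(ratios)
    res = permutation_pfp(ratios, rp_up, rp_down, n_perm, seed)
    up_wins = res.p_up < res.p_down
    tie = res.p_up == res.p_down
    sign = np.where(tie, 0, np.where(up_wins, 1, -1))
    use_up = up_wins | tie
    table = pd.DataFrame(
        {
            "rp": np.where(use_up, res.rp_up, res.rp_down),
            "p_value": np.where(use_up, res.p_up, res.p_down),
            "pfp_raw": np.where(use_up, res.pfp_up, res.pfp_down),
            "direction": sign,
        }
    )
    table["pfp"] = np.clip(table["pfp_raw"], 0.0, 1.0)
    return res, table
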