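"""Conservative low-expression filtering.

An entry is retained iff its expression exceeds theta_E (strictly) in at
least a kappa fraction of the samples of at least one experimental group.
The comparison of the presence fraction against kappa is exact (rational
arithmetic on counts, no float rounding). theta_F is never applied as a row
filter: genes below it stay in the computation and are only marked
non-differentially expressed downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .core_model import ExpressionMatrix

__all__ = ["FilterParams", "filter_by_expression", "default_theta_e"]

logger = logging.getLogger("teaflow")


@dataclass(frozen=True)
class FilterParams:
    kappa: float
    theta_e: float
    theta_f: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must be in [0, 1], got {self.kappa}")
        if self.theta_f < 0:
            raise ValueError(f"theta_f must be >= 0, got {self.theta_f}")


def default_theta_e(m: ExpressionMatrix) -> float:
    """Fallback expression threshold: 20th percentile of all values.

    Used when no negative-control estimate is available; both choices are
    logged so users can override.
    """
    t = float(np.percentile(m.values, 20))
    logger.info("theta_e defaulted to 20th percentile of expression: %.4f", t)
    return t


def filter_by_expression(
    m: ExpressionMatrix,
    groups: tuple[str, ...],
    kappa: float,
    theta_e: float,
) -> tuple[ExpressionMatrix, tuple[str, ...]]:
    """Return (retained matrix, dropped entry ids)."""
    if not 0.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must be in [0, 1], got {kappa}")
    if len(groups) != m.n_samples:
        raise ValueError(f"{len(groups)} group labels for {m.n_samples} samples")
    levels = sorted(set(groups))
    above = m.values > theta_e  # strict
    keep = np.zeros(m.n_entries, dtype=bool)
    for lv in levels:
        idx = [i for i, g in enumerate(groups) if g == lv]
        counts = above[:, idx].sum(axis=1)
        n = len(idx)
        # exact rational comparison: count/n >= kappa
        keep |= np.array([Fraction(int(c), n) >= kappa for c in counts])
    dropped = tuple(
        eid for eid, k in zip(m.entry_ids, keep) if not k
    )
    if not keep.any():
        raise ValueError(
            "filtering dropped every entry; lower theta_e or kappa "
            f"(theta_e={theta_e}, kappa={kappa})"
        )
    retained = m.subset_entries(np.where(keep)[0])
    logger.info(
        "filter: retained %d / %d entries (kappa=%g, theta_e=%g)",
        retained.n_entries, m.n_entries, kappa, theta_e,
    )
    return retained, dropped
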