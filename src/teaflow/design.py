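"""Design-label parsing, model matrices, and contrast vectors.

Label shorthand: a comma-separated list where each item is either a literal
label or ``k*label`` meaning ``label`` repeated ``k`` times, expanded
left-to-right. Labels apply to samples order-wise (label *i* goes to matrix
column *i*), so a correspondence table (label <-> original sample name) is
emitted alongside every analysis.

The model uses a group-means parameterization: one indicator column per group
level and no intercept, so a contrast is a simple +1/-1 vector. Batch,
pairing and extra covariates enter as reference-dropped indicator columns
(levels sorted lexicographically, the first level is the reference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import DesignSpec

__all__ = [
    "ModelMatrix",
    "parse_design_labels",
    "build_design_matrix",
    "contrast_vector",
    "correspondence_table",
]


@dataclass(frozen=True)
class ModelMatrix:
    """Samples x coefficients indicator matrix with recorded column names."""

    matrix: np.ndarray
    column_names: tuple[str, ...]
    group_columns: dict[str, int]  # group level -> column index

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape[1] != len(self.column_names):
            raise ValueError("column name count does not match matrix width")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


def parse_design_labels(spec: str) -> list[str]:
    """Expand ``"2*a,b"`` to ``["a", "a", "b"]``."""
    if not isinstance(spec, str) or not spec.strip():
        raise ValueError("empty design label specification")
    out: list[str] = []
    for item in spec.split(","):
        item = item.strip()
        if not item:
            raise ValueError(f"empty item in label specification {spec!r}")
        if "*" in item:
            count_s, _, label = item.partition("*")
            try:
                count = int(count_s)
            except ValueError:
                raise ValueError(
                    f"multiplier {count_s!r} in {item!r} is not an integer"
                ) from None
            if count <= 0:
                raise ValueError(f"multiplier must be positive in {item!r}")
            label = label.strip()
            if not label:
                raise ValueError(f"empty label in {item!r}")
            out.extend([label] * count)
        else:
            out.append(item)
    return out


def _indicator_block(
    labels: tuple[str, ...], prefix: str, drop_reference: bool
) -> tuple[np.ndarray, list[str]]:
    levels = sorted(set(labels))
    if drop_reference:
        levels = levels[1:]
    cols = np.zeros((len(labels), len(levels)))
    for j, lv in enumerate(levels):
        cols[:, j] = [1.0 if x == lv else 0.0 for x in labels]
    return cols, [f"{prefix}{lv}" for lv in levels]


def build_design_matrix(d: DesignSpec, sample_names: tuple[str, ...]) -> ModelMatrix:
    """Group-means design plus reference-dropped batch/pairing/extra blocks.

    Raises on rank deficiency (e.g. a batch perfectly confounded with group),
    naming the offending covariate blocks.
    """
    n = len(sample_names)
    if len(d.group_labels) != n:
        raise ValueError(
            f"{len(d.group_labels)} group labels for {n} samples "
            f"(samples: {list(sample_names)})"
        )
    blocks: list[np.ndarray] = []
    names: list[str] = []
    group_levels = sorted(set(d.group_labels))
    gmat, gnames = _indicator_block(d.group_labels, "group:", drop_reference=False)
    blocks.append(gmat)
    names.extend(gnames)
    group_columns = {lv: i for i, lv in enumerate(group_levels)}
    optional = [
        ("batch:", d.batch_labels),
        ("pair:", d.pairing_labels),
    ] + [(f"{name}:", labels) for name, labels in d.extra_covariates]
    for prefix, labels in optional:
        if labels is None:
            continue
        if len(labels) != n:
            raise ValueError(f"{prefix[:-1]} labels do not match sample count {n}")
        bmat, bnames = _indicator_block(tuple(labels), prefix, drop_reference=True)
        if bmat.shape[1]:
            blocks.append(bmat)
            names.extend(bnames)
    matrix = np.hstack(blocks)
    rank = int(np.linalg.matrix_rank(matrix))
    if rank < matrix.shape[1]:
        # identify columns that add no rank when appended left to right
        collinear = []
        prev = 0
        for j in range(1, matrix.shape[1] + 1):
            r = int(np.linalg.matrix_rank(matrix[:, :j]))
            if r == prev:
                collinear.append(names[j - 1])
            prev = r
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {matrix.shape[1]} "
            f"columns); collinear columns: {collinear or names}"
        )
    return ModelMatrix(matrix, tuple(names), group_columns)


def contrast_vector(contrast: tuple[str, str], mm: ModelMatrix) -> np.ndarray:
    """+1 at the test group column, -1 at the reference column, 0 elsewhere."""
    test, ref = contrast
    if test == ref:
        raise ValueError(f"contrast {test}-{ref} would be the zero vector")
    for lv in (test, ref):
        if lv not in mm.group_columns:
            raise ValueError(
                f"contrast level {lv!r} not among groups {sorted(mm.group_columns)}"
            )
    c = np.zeros(mm.matrix.shape[1])
    c[mm.group_columns[test]] = 1.0
    c[mm.group_columns[ref]] = -1.0
    return c


def correspondence_table(
    labels: tuple[str, ...], sample_names: tuple[str, ...]
) -> pd.DataFrame:
    """Order-wise mapping between applied labels and original sample names."""
    if len(labels) != len(sample_names):
        raise ValueError("label count does not match sample count")
    return pd.DataFrame(
        {
            "position": np.arange(1, len(labels) + 1),
            "sample_name": list(sample_names),
            "label": list(labels),
        }
    )
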