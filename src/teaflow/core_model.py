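"""Domain types and serialization: expression matrices, DEG tables, analysis
options, and annotation joining.

The expression matrix CSV dialect is fixed: comma separator, ``.`` decimal
point, UTF-8, mandatory header row, first column holds entry identifiers.
Missing values are rejected — upstream preparation must produce complete data.
Writers are byte-deterministic: floats are emitted with ``repr`` (shortest
round-trip form), so ``read(write(x))`` recovers ``x`` exactly.
"""

from __future__ import annotations

import csv
import io
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "RawIntensityBatch",
    "RawSample",
    "DesignSpec",
    "AnalysisOptions",
    "AnnotationTable",
    "DEG_TABLE_COLUMNS",
    "ANNOTATION_COLUMNS",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_options",
    "write_options",
    "read_annotation",
    "annotate_table",
    "write_deg_table",
]

DEG_TABLE_COLUMNS = [
    "entry_id",
    "avg_expr",
    "log2_fc",
    "stat",
    "p_value",
    "q_value",
    "marking",
]

ANNOTATION_COLUMNS = [
    "entry_id",
    "gene_symbol",
    "gene_name",
    "source_name",
    "source_version",
]

CONTROL_CLASSES = ("none", "negative", "other")


class SchemaError(ValueError):
    """Raised when a document violates the strict options/annotation schema."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen[x] = seen.get(x, 0) + 1
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Entries x samples matrix of log2 expression values.

    Invariants: entry/sample identifiers unique and non-empty, values
    rectangular and finite.
    """

    entry_ids: tuple[str, ...]
    sample_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "entry_ids", tuple(str(x) for x in self.entry_ids))
        object.__setattr__(
            self, "sample_names", tuple(str(x) for x in self.sample_names)
        )
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if not self.entry_ids:
            raise ValueError("expression matrix needs at least one entry")
        if not self.sample_names:
            raise ValueError("expression matrix needs at least one sample")
        if any(x == "" for x in self.entry_ids):
            raise ValueError("empty entry id")
        if any(x == "" for x in self.sample_names):
            raise ValueError("empty sample name")
        _check_unique(self.entry_ids, "entry ids")
        _check_unique(self.sample_names, "sample names")
        if vals.shape != (len(self.entry_ids), len(self.sample_names)):
            raise ValueError(
                f"matrix shape {vals.shape} does not match "
                f"{len(self.entry_ids)} entries x {len(self.sample_names)} samples"
            )
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite value at entry {self.entry_ids[bad[0]]!r}, "
                f"sample {self.sample_names[bad[1]]!r}"
            )

    @property
    def n_entries(self) -> int:
        return len(self.entry_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(self.entry_ids, self.sample_names, values)

    def subset_entries(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        ids = tuple(np.asarray(self.entry_ids, dtype=object)[keep])
        return ExpressionMatrix(ids, self.sample_names, self.values[keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.entry_ids, name="entry_id"),
            columns=list(self.sample_names),
        )


@dataclass(frozen=True)
class RawSample:
    """One raw scanner export: linear-scale intensities with control flags."""

    sample_name: str
    feature_ids: tuple[str, ...]
    intensities: np.ndarray
    control_classes: tuple[str, ...]
    replicate_keys: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", vals)
        n = len(self.feature_ids)
        if not (len(vals) == len(self.control_classes) == len(self.replicate_keys) == n):
            raise ValueError("raw sample columns have mismatched lengths")
        _check_unique(self.feature_ids, f"feature ids in sample {self.sample_name!r}")
        if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
            raise ValueError(
                f"sample {self.sample_name!r} has non-positive or non-finite intensities"
            )
        bad = sorted({c for c in self.control_classes if c not in CONTROL_CLASSES})
        if bad:
            raise ValueError(f"unknown control classes {bad}; allowed {CONTROL_CLASSES}")
        if all(c != "none" for c in self.control_classes):
            raise ValueError(
                f"sample {self.sample_name!r} has no non-control features"
            )


@dataclass(frozen=True)
class RawIntensityBatch:
    """Merged raw samples sharing one feature universe."""

    samples: tuple[RawSample, ...]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("empty raw batch")
        ref = self.samples[0].feature_ids
        ref_set = set(ref)
        for s in self.samples[1:]:
            if s.feature_ids != ref:
                extra = sorted(set(s.feature_ids) - ref_set)
                missing = sorted(ref_set - set(s.feature_ids))
                raise ValueError(
                    f"feature universe of sample {s.sample_name!r} differs from "
                    f"{self.samples[0].sample_name!r}: "
                    f"extra={extra[:10]}, missing={missing[:10]}"
                )
        _check_unique([s.sample_name for s in self.samples], "sample names")

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return self.samples[0].feature_ids

    @property
    def sample_names(self) -> tuple[str, ...]:
        return tuple(s.sample_name for s in self.samples)

    def intensity_matrix(self) -> np.ndarray:
        """Features x samples, linear scale."""
        return np.column_stack([s.intensities for s in self.samples])


@dataclass(frozen=True)
class DesignSpec:
    """Per-sample group labels plus optional batch / pairing / extra covariates."""

    group_labels: tuple[str, ...]
    contrasts: tuple[tuple[str, str], ...]
    batch_labels: tuple[str, ...] | None = None
    pairing_labels: tuple[str, ...] | None = None
    extra_covariates: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def __post_init__(self) -> None:
        if not self.group_labels:
            raise ValueError("group labels must be non-empty")
        levels = set(self.group_labels)
        for test, ref in self.contrasts:
            if test == ref:
                raise ValueError(f"contrast {test}-{ref} compares a level to itself")
            for lv in (test, ref):
                if lv not in levels:
                    raise ValueError(
                        f"contrast level {lv!r} not among group levels {sorted(levels)}"
                    )
        n = len(self.group_labels)
        for name, labels in (
            ("batches", self.batch_labels),
            ("pairings", self.pairing_labels),
        ):
            if labels is not None and len(labels) != n:
                raise ValueError(
                    f"{name} has {len(labels)} labels for {n} samples"
                )
        for name, labels in self.extra_covariates:
            if len(labels) != n:
                raise ValueError(
                    f"extra covariate {name!r} has {len(labels)} labels for {n} samples"
                )

    def validate_pairing(self) -> None:
        """Within each contrast, each pair id must occur exactly once per level."""
        if self.pairing_labels is None:
            return
        for test, ref in self.contrasts:
            for level in (test, ref):
                seen: dict[str, int] = {}
                for g, p in zip(self.group_labels, self.pairing_labels):
                    if g == level:
                        seen[p] = seen.get(p, 0) + 1
                bad = sorted(p for p, c in seen.items() if c != 1)
                if bad:
                    raise ValueError(
                        f"pair ids {bad} do not occur exactly once in group {level!r}"
                    )


@dataclass(frozen=True)
class AnalysisOptions:
    """Every analysis knob, serializable to/from the options file."""

    design: DesignSpec
    kappa: float = 0.8
    theta_e: float | None = None
    theta_f: float = 0.5
    alpha: float = 0.05
    run_limma_like: bool = True
    run_rankprod: bool = True
    renormalize: bool = False
    input_kind: str = "microarray"
    rng_seed: int = 0
    permutations: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise SchemaError(f"filter.kappa must be in [0, 1], got {self.kappa}")
        if self.theta_f < 0:
            raise SchemaError(f"filter.theta_f must be >= 0, got {self.theta_f}")
        if not 0.0 < self.alpha < 1.0:
            raise SchemaError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (self.run_limma_like or self.run_rankprod):
            raise SchemaError("at least one of the methods must be enabled")
        if self.input_kind not in ("microarray", "counts"):
            raise SchemaError(
                f"input_kind must be 'microarray' or 'counts', got {self.input_kind!r}"
            )
        if self.permutations < 100:
            raise SchemaError(
                f"permutations must be >= 100, got {self.permutations}"
            )

    @property
    def methods(self) -> tuple[str, ...]:
        out = []
        if self.run_limma_like:
            out.append("limma_like")
        if self.run_rankprod:
            out.append("rankprod")
        return tuple(out)


@dataclass(frozen=True)
class AnnotationTable:
    """entry_id -> (gene_symbol, gene_name, source_name, source_version).

    Missing annotation is an explicit empty string, never NaN.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if list(f.columns) != ANNOTATION_COLUMNS:
            raise SchemaError(
                f"annotation columns must be {ANNOTATION_COLUMNS}, got {list(f.columns)}"
            )
        if f["entry_id"].duplicated().any():
            dups = sorted(f.loc[f["entry_id"].duplicated(), "entry_id"].unique())
            raise ValueError(f"duplicate annotation entry ids: {dups}")
        object.__setattr__(self, "frame", f.fillna("").astype(str))


# ---------------------------------------------------------------------------
# Expression matrix CSV
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read an entries x samples CSV (first column = ids, header = samples)."""
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        sample_names = header[1:]
        ids: list[str] = []
        rows: list[list[float]] = []
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            ids.append(row[0])
            vals = []
            for j, cell in enumerate(row[1:], start=2):
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at row {i}, column {j}"
                    ) from None
            rows.append(vals)
    if not ids:
        raise ValueError(f"{path}: no data rows")
    widths = {len(r) for r in rows}
    if widths != {len(sample_names)}:
        raise ValueError(
            f"{path}: ragged rows, widths {sorted(widths)} vs {len(sample_names)} samples"
        )
    _check_unique(ids, f"entry ids in {path}")
    return ExpressionMatrix(tuple(ids), tuple(sample_names), np.array(rows))


def _fmt(v: float) -> str:
    # repr of a Python float is the shortest string that round-trips exactly
    return repr(float(v))


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix CSV. Two writes of equal matrices are byte-identical."""
    buf = io.StringIO()
    buf.write("entry_id," + ",".join(m.sample_names) + "\n")
    for i, eid in enumerate(m.entry_ids):
        buf.write(eid + "," + ",".join(_fmt(v) for v in m.values[i]) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Options file (flat typed key-value document, TOML syntax, strict schema)
# ---------------------------------------------------------------------------

_OPTION_KEYS = {
    "design.groups": str,
    "design.contrasts": list,
    "design.batches": str,
    "design.pairings": str,
    "filter.kappa": float,
    "filter.theta_e": float,
    "filter.theta_f": float,
    "alpha": float,
    "methods": list,
    "input_kind": str,
    "seed": int,
    "permutations": int,
    "renormalize": bool,
}

_OPTIONAL_KEYS = {"design.batches", "design.pairings", "filter.theta_e"}


def _flatten(doc: dict, prefix: str = "") -> dict[str, object]:
    out: dict[str, object] = {}
    for k, v in doc.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out


def parse_contrast(spec: str) -> tuple[str, str]:
    parts = spec.split("-")
    if len(parts) != 2 or not all(parts):
        raise SchemaError(
            f"contrast {spec!r} must be 'TEST-REFERENCE' with exactly one '-'"
        )
    return parts[0], parts[1]


def read_options(path: str | Path) -> AnalysisOptions:
    """Read and validate an options file. Unknown keys are a hard error."""
    from .design import parse_design_labels  # local import: avoids cycle

    with Path(path).open("rb") as fh:
        doc = tomllib.load(fh)
    flat = _flatten(doc)
    unknown = sorted(set(flat) - set(_OPTION_KEYS))
    if unknown:
        raise SchemaError(f"unknown options keys: {unknown}")
    missing = sorted(
        k
        for k in ("design.groups", "design.contrasts", "methods", "input_kind", "seed")
        if k not in flat
    )
    if missing:
        raise SchemaError(f"missing mandatory options keys: {missing}")
    for k, v in flat.items():
        want = _OPTION_KEYS[k]
        if want is float and isinstance(v, int) and not isinstance(v, bool):
            v = float(v)
            flat[k] = v
        if not isinstance(v, want) or (want is int and isinstance(v, bool)):
            raise SchemaError(
                f"options key {k!r} must be {want.__name__}, got {type(v).__name__}"
            )
    groups = tuple(parse_design_labels(flat["design.groups"]))
    contrasts = tuple(parse_contrast(c) for c in flat["design.contrasts"])
    batches = flat.get("design.batches")
    pairings = flat.get("design.pairings")
    methods = flat["methods"]
    bad = sorted(set(methods) - {"limma_like", "rankprod"})
    if bad:
        raise SchemaError(f"unknown methods: {bad}")
    design = DesignSpec(
        group_labels=groups,
        contrasts=contrasts,
        batch_labels=tuple(parse_design_labels(batches)) if batches else None,
        pairing_labels=tuple(parse_design_labels(pairings)) if pairings else None,
    )
    return AnalysisOptions(
        design=design,
        kappa=flat.get("filter.kappa", 0.8),
        theta_e=flat.get("filter.theta_e"),
        theta_f=flat.get("filter.theta_f", 0.5),
        alpha=flat.get("alpha", 0.05),
        run_limma_like="limma_like" in methods,
        run_rankprod="rankprod" in methods,
        renormalize=flat.get("renormalize", False),
        input_kind=flat["input_kind"],
        rng_seed=flat["seed"],
        permutations=flat.get("permutations", 1000),
    )


def _toml_str(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def write_options(opts: AnalysisOptions, path: str | Path) -> None:
    """Serialize options so that ``read_options(write_options(x)) == x``."""
    d = opts.design
    lines = []
    lines.append(f"alpha = {_fmt(opts.alpha)}")
    lines.append(f"input_kind = {_toml_str(opts.input_kind)}")
    lines.append(
        "methods = [" + ", ".join(_toml_str(m) for m in opts.methods) + "]"
    )
    lines.append(f"permutations = {opts.permutations}")
    lines.append(f"renormalize = {'true' if opts.renormalize else 'false'}")
    lines.append(f"seed = {opts.rng_seed}")
    lines.append("")
    lines.append("[design]")
    lines.append("groups = " + _toml_str(",".join(d.group_labels)))
    lines.append(
        "contrasts = ["
        + ", ".join(_toml_str(f"{t}-{r}") for t, r in d.contrasts)
        + "]"
    )
    if d.batch_labels is not None:
        lines.append("batches = " + _toml_str(",".join(d.batch_labels)))
    if d.pairing_labels is not None:
        lines.append("pairings = " + _toml_str(",".join(d.pairing_labels)))
    lines.append("")
    lines.append("[filter]")
    lines.append(f"kappa = {_fmt(opts.kappa)}")
    if opts.theta_e is not None:
        lines.append(f"theta_e = {_fmt(opts.theta_e)}")
    lines.append(f"theta_f = {_fmt(opts.theta_f)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def default_options_text() -> str:
    """A fully commented defaults document accepted by :func:`read_options`."""
    return (
        "# teaflow analysis options\n"
        "# Edit the values below, then run: teaflow analyze <matrix.csv> <this file> <outdir>\n"
        "\n"
        "# Significance level on the q-value / PFP (strictly-less-than cutoff).\n"
        "alpha = 0.05\n"
        '# "microarray" for log2 expression matrices, "counts" for raw count matrices.\n'
        'input_kind = "microarray"\n'
        "# Any non-empty subset of limma_like (moderated t) and rankprod.\n"
        'methods = ["limma_like", "rankprod"]\n'
        "# Permutations for the rank-product null (>= 100).\n"
        "permutations = 1000\n"
        "# Re-apply quantile normalization before analysis.\n"
        "renormalize = false\n"
        "# Seed for every stochastic stage; identical seed => identical output.\n"
        "seed = 0\n"
        "\n"
        "[design]\n"
        '# Labels applied to the matrix columns order-wise; shorthand "k*label" repeats.\n'
        'groups = "2*control,2*treated"\n'
        '# Each contrast is "TEST-REFERENCE".\n'
        'contrasts = ["treated-control"]\n'
        '# Optional: batches = "2*b1,2*b2"\n'
        '# Optional: pairings = "p1,p2,p1,p2"\n'
        "\n"
        "[filter]\n"
        "# Minimum group-wise presence fraction.\n"
        "kappa = 0.8\n"
        "# Optional log2 expression threshold; omitted => negative-control estimate\n"
        "# when available, else the 20th percentile of the matrix.\n"
        "# theta_e = 4.0\n"
        "# log2 fold-change threshold used only for marking, never for row removal.\n"
        "theta_f = 0.5\n"
    )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path) -> AnnotationTable:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return AnnotationTable(frame)


def annotate_table(
    table: pd.DataFrame | ExpressionMatrix, annotation: AnnotationTable
) -> pd.DataFrame:
    """Left-join annotation columns onto a DEG table or expression matrix.

    Row count, row order and all pre-existing columns are unchanged; entries
    without annotation get empty strings.
    """
    if isinstance(table, ExpressionMatrix):
        frame = table.to_frame().reset_index()
    else:
        frame = table.copy()
        if "entry_id" not in frame.columns:
            raise ValueError("table lacks an 'entry_id' column")
    ann_cols = [c for c in ANNOTATION_COLUMNS if c != "entry_id"]
    frame = frame.drop(columns=[c for c in ann_cols if c in frame.columns])
    out = frame.merge(annotation.frame, on="entry_id", how="left", sort=False)
    out[ann_cols] = out[ann_cols].fillna("")
    return out


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a DEG table CSV with deterministic numeric formatting."""
    cols = list(table.columns)
    expected = DEG_TABLE_COLUMNS
    if cols[: len(expected)] != expected:
        raise ValueError(f"DEG table columns must start with {expected}, got {cols}")
    buf = io.StringIO()
    buf.write(",".join(cols) + "\n")
    for row in table.itertuples(index=False):
        cells = []
        for col, v in zip(cols, row):
            if col == "marking":
                cells.append(str(int(v)))
            elif isinstance(v, (float, np.floating)):
                cells.append(_fmt(v))
            else:
                cells.append(str(v))
        buf.write(",".join(cells) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
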