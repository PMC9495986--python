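# teaflow

A self-contained differential-expression pipeline for one-color microarray
and count-based transcriptomics: raw intensity preparation (normexp
background correction, quantile normalization, RMA-style median-polish
summarization), conservative low-expression filtering, parametric
(empirical-Bayes moderated t) and non-parametric (rank product with
permutation PFP) DEG detection, voom precision weights for counts, QC
statistics, annotation joining, and a deterministic options-file replay
contract.

## CLI

```bash
teaflow --version
teaflow synth expression matrix.csv --genes 500 --n-per-group 5 --seed 1
teaflow initialize options.toml              # commented defaults file
teaflow analyze matrix.csv options.toml out/ # DEG tables + QC + figures
teaflow prepare raw_dir/ matrix.csv --platform probeset --pattern '.*\.csv$'
teaflow annotate out/deg_limma_like_treated-vs-control.csv annotation.csv annotated.csv
```

Exit codes: 0 success, 2 usage/validation error, 1 runtime error. Every
command logs its version, resolved parameters and seed; with identical
inputs, options and seed, `analyze` writes byte-identical DEG tables and QC
data files.

### Raw sample format (`prepare`)

One CSV per sample with header
`feature_id,intensity,control_class,replicate_key`: linear-scale positive
intensities, `control_class` in `{none, negative, other}`, and
`replicate_key` grouping replicate probes (platform `single_probe`, collapsed
by mean) or the probes of a probe set (platform `probeset`, summarized by
median polish). Negative controls provide the unexpressed-intensity
threshold estimate (95th percentile of their normalized log2 values, logged
and overridable via `filter.theta_e`).

### Options file

TOML-syntax, strict schema (unknown keys are errors):

| key | default | meaning |
| --- | --- | --- |
| `design.groups` | required | per-sample labels, order-wise |
| `design.contrasts` | required | list of `"TEST-REFERENCE"` strings |
| `design.batches` / `design.pairings` | optional | per-sample labels |
| `filter.kappa` | 0.8 | minimum group-wise presence fraction |
| `filter.theta_e` | estimated | log2 expression threshold |
| `filter.theta_f` | 0.5 | log2 fold-change threshold (marking only) |
| `alpha` | 0.05 | strict q/PFP cutoff |
| `methods` | both | subset of `limma_like`, `rankprod` |
| `input_kind` | required | `microarray` or `counts` |
| `seed` | required | drives all stochastic stages |
| `permutations` | 1000 | rank-product permutations (>= 100) |
| `renormalize` | false | re-apply quantile normalization |

Label shorthand: comma-separated items, each either a literal label or
`k*label` (repeat `k` times), expanded left to right and applied to matrix
columns order-wise. A correspondence table (label vs. original sample name)
is written with every analysis.

### DEG tables

One CSV per contrast per method with columns
`entry_id,avg_expr,log2_fc,stat,p_value,q_value,marking`. `marking` is 1
(up), -1 (down) or 0: an entry is marked iff its q-value (BH for the
moderated t, PFP for rank product, both clipped to [0,1]) is strictly below
`alpha` AND |log2FC| is strictly above `theta_f`. Genes failing `theta_f`
stay in the tables; they are never removed. When both methods run, per-
direction overlap counts are written for Venn-style comparison. Rank
product's two one-sided results are merged per gene by the direction with
the smaller p estimate (exact tie marks 0).

## Notes and scope

- No network access, no GEO retrieval, no binary vendor formats; annotation
  is a user-supplied CSV (`entry_id,gene_symbol,gene_name,source_name,source_version`).
- Counts path applies no TMM/library-size normalization factors beyond the
  log-cpm offsets.
- Rank-product permutation p-values assume independent comparison columns;
  for unpaired all-pairs comparisons (shared samples) they are approximate,
  while paired designs satisfy the assumption exactly.
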