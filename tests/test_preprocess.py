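import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import integrate, stats

from teaflow.core_model import ExpressionMatrix
from teaflow.preprocess import (
    NormexpParams,
    collapse_replicates,
    estimate_normexp_params,
    estimate_unexpressed_threshold,
    load_raw_batch,
    median_polish_summarize,
    normexp_correct,
    prepare_pipeline,
    quantile_normalize,
    split_controls,
)
from teaflow.synthetic_fixtures import generate_raw_batch


def normexp_integration_oracle(x, mu, sigma, alpha):
    """E[S | X=x] by direct numerical integration of the posterior."""
    m = x - mu - sigma**2 / alpha
    upper = max(m + 12 * sigma, 12 * sigma)
    pts = sorted(
        {p for p in (max(m, 0.0), max(m - 5 * sigma, 0.0),
                     min(max(m + 5 * sigma, 0.0), upper))
         if 0 < p < upper}
    )
    f = lambda s: np.exp(-s / alpha) * stats.norm.pdf(x - s, mu, sigma)
    num, _ = integrate.quad(lambda s: s * f(s), 0, upper, points=pts,
                            limit=400, epsabs=0, epsrel=1e-12)
    den, _ = integrate.quad(f, 0, upper, points=pts,
                            limit=400, epsabs=0, epsrel=1e-12)
    return num / den


class TestLoadRawBatch:
    def _write(self, path, features):
        lines = ["feature_id,intensity,control_class,replicate_key"]
        lines += [f"{f},{v},{c},{k}" for f, v, c, k in features]
        path.write_text("\n".join(lines) + "\n")

    def test_three_files(self, tmp_path):
        feats = [("f1", 10.0, "none", "r1"), ("f2", 20.0, "none", "r2")]
        for i in range(3):
            self._write(tmp_path / f"s{i}.txt", feats)
        batch = load_raw_batch(tmp_path, r".*\.txt$")
        assert len(batch.samples) == 3
        assert batch.sample_names == ("s0", "s1", "s2")

    def test_single_match_rejected(self, tmp_path):
        self._write(tmp_path / "only.txt", [("f1", 1.0, "none", "r1")])
        with pytest.raises(ValueError, match="matched 1"):
            load_raw_batch(tmp_path, r".*\.txt$")

    def test_mismatched_features_named(self, tmp_path):
        self._write(tmp_path / "a.txt", [("f1", 1.0, "none", "r1")])
        self._write(tmp_path / "b.txt", [("fX", 1.0, "none", "r1")])
        with pytest.raises(ValueError, match="fX"):
            load_raw_batch(tmp_path, r".*\.txt$")


class TestNormexpEstimation:
    def test_parameter_recovery_mle(self):
        rng = np.random.default_rng(42)
        n = 100_000
        x = rng.normal(100, 10, n) + rng.exponential(500, n)
        p = estimate_normexp_params(x)
        assert abs(p.mu - 100) / 100 < 0.05
        assert abs(p.sigma - 10) / 10 < 0.05
        assert abs(p.alpha - 500) / 500 < 0.05

    def test_constant_controls_sigma_floored(self):
        x = np.full(100, 600.0)
        p = estimate_normexp_params(x, negative_controls=np.full(20, 100.0))
        assert p.mu == 100.0
        assert p.sigma > 0

    def test_controls_hand_arithmetic(self):
        fg = np.full(100, 600.0)
        p = estimate_normexp_params(fg, np.array([90.0, 100.0, 110.0]))
        assert p.mu == pytest.approx(100.0)
        assert p.alpha == pytest.approx(500.0)
        assert p.sigma == pytest.approx(10.0)

    def test_nonpositive_intensities_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            estimate_normexp_params(np.linspace(-1, 10, 100))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            estimate_normexp_params(np.ones(10))


class TestNormexpCorrect:
    def test_spec_point(self):
        got = normexp_correct(10.0, NormexpParams(5, 1, 10))
        assert got == pytest.approx(
            normexp_integration_oracle(10, 5, 1, 10), rel=1e-9
        )
        assert got == pytest.approx(4.900002, abs=1e-5)

    def test_small_sigma_limit(self):
        p = NormexpParams(5, 1e-4, 10)
        x = 20.0
        assert normexp_correct(x, p) == pytest.approx(x - 5 - 1e-8 / 10, rel=1e-9)

    def test_matches_integration_oracle_on_grid(self):
        p = NormexpParams(5, 1, 10)
        grid = np.linspace(-5, 60, 100)
        got = normexp_correct(grid, p)
        want = np.array([normexp_integration_oracle(x, 5, 1, 10) for x in grid])
        assert np.max(np.abs(got - want) / want) <= 1e-6

    def test_positive_and_monotone(self):
        p = NormexpParams(100, 10, 500)
        grid = np.linspace(-500, 5000, 400)
        out = normexp_correct(grid, p)
        assert np.all(out > 0)
        assert np.all(np.isfinite(out))
        assert np.all(np.diff(out) >= 0)


class TestQuantileNormalize:
    def test_hand_example(self):
        m = ExpressionMatrix(
            ("g1", "g2", "g3"), ("s1", "s2"),
            np.array([[5.0, 2.0], [3.0, 4.0], [1.0, 6.0]]),
        )
        out = quantile_normalize(m)
        np.testing.assert_allclose(
            out.values, [[5.5, 1.5], [3.5, 3.5], [1.5, 5.5]]
        )

    def test_identical_columns_fixed_point(self):
        v = np.tile(np.array([[1.0], [7.0], [3.0]]), (1, 3))
        m = ExpressionMatrix(("a", "b", "c"), ("s1", "s2", "s3"), v)
        np.testing.assert_array_equal(quantile_normalize(m).values, v)

    def test_single_sample_rejected(self):
        m = ExpressionMatrix(("a",), ("s1",), np.array([[1.0]]))
        with pytest.raises(ValueError, match="2 samples"):
            quantile_normalize(m)

    def test_sorted_columns_identical_after(self, rng):
        v = rng.normal(size=(50, 6))
        m = ExpressionMatrix(
            tuple(f"g{i}" for i in range(50)),
            tuple(f"s{j}" for j in range(6)), v,
        )
        out = quantile_normalize(m).values
        ref = np.sort(out[:, 0])
        for j in range(6):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    @settings(max_examples=25, deadline=None)
    @given(
        arrays(np.float64, (20, 5), unique=True,
               elements=st.floats(-50, 50, allow_nan=False))
    )
    def test_idempotent(self, v):
        # tie-free columns: with ties the tie-averaging rule intentionally
        # trades exact distribution equality for within-column consistency
        m = ExpressionMatrix(
            tuple(f"g{i}" for i in range(20)),
            tuple(f"s{j}" for j in range(5)), v,
        )
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_tie_rule_mean_of_rank_span(self):
        # column 1 has a tie over ranks 1-2; reference means are (1.5, 3.5)
        m = ExpressionMatrix(
            ("a", "b"), ("s1", "s2"), np.array([[2.0, 1.0], [2.0, 4.0]])
        )
        out = quantile_normalize(m).values
        # reference = mean of sorted columns = [1.5, 3.0]; ties share 2.25
        np.testing.assert_allclose(out[:, 0], [2.25, 2.25])
        np.testing.assert_allclose(out[:, 1], [1.5, 3.0])


class TestMedianPolish:
    def test_hand_example(self):
        out = median_polish_summarize(np.array([[1.0, 3.0], [2.0, 4.0]]))
        np.testing.assert_allclose(out, [1.5, 3.5])

    def test_single_probe_identity(self):
        out = median_polish_summarize(np.array([[2.0, 5.0, 9.0]]))
        np.testing.assert_allclose(out, [2.0, 5.0, 9.0])

    def test_location_equivariance(self, rng):
        v = rng.normal(size=(7, 4))
        base = median_polish_summarize(v)
        shifted = median_polish_summarize(v + 3.25)
        np.testing.assert_allclose(shifted, base + 3.25, atol=1e-10)

    def test_sample_permutation_equivariance(self, rng):
        v = rng.normal(size=(6, 5))
        perm = rng.permutation(5)
        base = median_polish_summarize(v)
        permuted = median_polish_summarize(v[:, perm])
        np.testing.assert_allclose(permuted, base[perm], atol=1e-10)


class TestCollapseReplicates:
    def _m(self, vals, n_samples=1):
        vals = np.asarray(vals, dtype=float)
        return ExpressionMatrix(
            tuple(f"g{i}" for i in range(vals.shape[0])),
            tuple(f"s{j}" for j in range(vals.shape[1])),
            vals,
        )

    def test_mean_of_members(self):
        m = self._m([[2.0], [4.0]])
        out = collapse_replicates(m, ("A", "A"))
        np.testing.assert_allclose(out.values, [[3.0]])
        assert out.entry_ids == ("A",)

    def test_unique_keys_identity(self):
        m = self._m([[1.0], [2.0]])
        out = collapse_replicates(m, ("k1", "k2"))
        np.testing.assert_array_equal(out.values, m.values)

    def test_counting(self, rng):
        m = self._m(rng.normal(size=(100, 2)))
        keys = tuple(f"k{i % 10}" for i in range(100))
        out = collapse_replicates(m, keys)
        assert out.n_entries == 10

    def test_first_appearance_order(self):
        m = self._m([[1.0], [2.0], [3.0]])
        out = collapse_replicates(m, ("z", "a", "z"))
        assert out.entry_ids == ("z", "a")


class TestControls:
    def _batch(self, tmp_path, classes):
        lines = ["feature_id,intensity,control_class,replicate_key"]
        for i, c in enumerate(classes):
            lines.append(f"f{i},{10.0 * (i + 1)},{c},r{i}")
        for name in ("a.csv", "b.csv"):
            (tmp_path / name).write_text("\n".join(lines) + "\n")
        return load_raw_batch(tmp_path, r".*\.csv$")

    def test_counting(self, tmp_path):
        batch = self._batch(tmp_path, ["none", "negative", "other", "none", "none"])
        out, neg = split_controls(batch)
        assert len(out.feature_ids) == 3

    def test_no_controls_identity(self, tmp_path):
        batch = self._batch(tmp_path, ["none"] * 4)
        out, neg = split_controls(batch)
        assert out.feature_ids == batch.feature_ids
        assert neg.size == 0

    def test_negative_class_only_in_returned_set(self, tmp_path):
        batch = self._batch(tmp_path, ["none", "negative", "other"])
        _, neg = split_controls(batch)
        # f1 has intensity 20 in both samples
        np.testing.assert_allclose(neg, np.log2([20.0, 20.0]))


class TestUnexpressedThreshold:
    def test_uniform_percentile(self, rng):
        v = rng.uniform(2, 4, size=100)
        got = estimate_unexpressed_threshold(v)
        assert got == pytest.approx(np.percentile(v, 95))
        assert got == pytest.approx(3.9, abs=0.15)

    def test_constant(self):
        assert estimate_unexpressed_threshold(np.full(20, 3.0)) == 3.0

    def test_few_values_returns_max(self):
        assert estimate_unexpressed_threshold(np.array([1.0, 5.0, 2.0])) == 5.0

    def test_never_below_median(self, rng):
        v = rng.normal(size=200)
        assert estimate_unexpressed_threshold(v) >= np.median(v)


class TestPreparePipeline:
    def test_probeset_shape(self, tmp_path):
        generate_raw_batch(tmp_path / "raw", probesets=50, probes_per_set=4,
                           samples=4, seed=5)
        m, qc, threshold = prepare_pipeline(tmp_path / "raw", "probeset")
        assert m.n_entries == 50
        assert m.n_samples == 4
        assert np.all(np.isfinite(m.values))
        assert threshold is not None

    def test_single_probe_distinct_keys(self, tmp_path):
        generate_raw_batch(tmp_path / "raw", probesets=30, probes_per_set=2,
                           samples=3, seed=6)
        m, _, _ = prepare_pipeline(tmp_path / "raw", "single_probe")
        assert m.n_entries == 30

    def test_no_control_features_in_output(self, tmp_path):
        generate_raw_batch(tmp_path / "raw", seed=7)
        m, _, _ = prepare_pipeline(tmp_path / "raw", "probeset")
        assert not any(e.startswith("neg") for e in m.entry_ids)

    def test_deterministic_csv(self, tmp_path):
        generate_raw_batch(tmp_path / "raw", seed=8)
        out1 = tmp_path / "m1.csv"
        out2 = tmp_path / "m2.csv"
        prepare_pipeline(tmp_path / "raw", "probeset", output_csv=out1)
        prepare_pipeline(tmp_path / "raw", "probeset", output_csv=out2)
        assert out1.read_bytes() == out2.read_bytes()
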