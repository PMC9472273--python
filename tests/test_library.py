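import math

import numpy as np
import pytest
from scipy import stats

from screenbo import (
    LibraryFormatError,
    MeasurementOracle,
    NoiseModel,
    ScreeningLibrary,
    compute_hit_threshold,
    generate_friedman3_library,
    generate_linear_library,
    load_library_csv,
    noise_variance,
    write_library_csv,
)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

class TestLinearGenerator:
    def test_canonical_pool_shape(self):
        lib = generate_linear_library(5000, 10, 5, seed=0)
        assert len(lib) == 5000
        assert lib.n_features == 10
        assert lib.activity_range > 0

    def test_deterministic_under_fixed_seed(self):
        a = generate_linear_library(100, 4, 4, seed=3)
        b = generate_linear_library(100, 4, 4, seed=3)
        assert np.array_equal(a.true_activities, b.true_activities)
        assert np.array_equal(a.features, b.features)

    def test_activity_depends_only_on_informative_features(self):
        lib = generate_linear_library(1000, 10, 5, seed=5)
        coef = np.asarray(lib.metadata["coef"])
        assert np.count_nonzero(coef) == 5
        # independent recomputation from the informative columns alone
        informative = np.flatnonzero(coef)
        recomputed = lib.features[:, informative] @ coef[informative]
        np.testing.assert_allclose(recomputed, lib.true_activities, rtol=1e-10)
        # permuting the non-informative columns cannot change any activity
        permuted = lib.features.copy()
        noninf = np.flatnonzero(coef == 0)
        permuted[:, noninf] = permuted[:, noninf[::-1]]
        np.testing.assert_allclose(
            permuted[:, informative] @ coef[informative], lib.true_activities, rtol=1e-10
        )

    @pytest.mark.parametrize("bad", [(1, 4, 2), (10, 4, 0), (10, 4, 5)])
    def test_invalid_sizes_rejected(self, bad):
        n, d, k = bad
        with pytest.raises(ValueError):
            generate_linear_library(n, d, k, seed=0)


class TestFriedman3Generator:
    def test_pool_shape(self):
        lib = generate_friedman3_library(5000, seed=0)
        assert len(lib) == 5000
        assert lib.n_features == 4

    def test_response_matches_closed_form(self):
        lib = generate_friedman3_library(500, seed=9)
        x = lib.features
        expected = np.arctan((x[:, 1] * x[:, 2] - 1.0 / (x[:, 1] * x[:, 3])) / x[:, 0])
        np.testing.assert_allclose(lib.true_activities, expected, rtol=1e-12)

    def test_deterministic_under_fixed_seed(self):
        a = generate_friedman3_library(50, seed=4)
        b = generate_friedman3_library(50, seed=4)
        assert np.array_equal(a.true_activities, b.true_activities)


# ---------------------------------------------------------------------------
# hit threshold
# ---------------------------------------------------------------------------

def brute_force_threshold(activities, q):
    ranked = sorted(activities, reverse=True)
    return ranked[math.ceil(q * len(activities)) - 1]


class TestHitThreshold:
    def test_top_decile_of_1_to_10(self):
        acts = np.arange(1.0, 11.0)
        thr = compute_hit_threshold(acts, 0.1)
        assert thr == brute_force_threshold(acts, 0.1) == 10.0
        assert int(np.sum(acts >= thr)) == 1

    def test_quantile_one_makes_everything_active(self):
        acts = np.array([3.0, -1.0, 7.0])
        assert compute_hit_threshold(acts, 1.0) == -1.0

    def test_top_percent_of_1_to_100(self):
        acts = np.arange(1.0, 101.0)
        thr = compute_hit_threshold(acts, 0.01)
        assert thr == brute_force_threshold(acts, 0.01)
        assert int(np.sum(acts >= thr)) == 1

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("q", [0.01, 0.1, 0.37, 0.9])
    def test_matches_brute_force_on_random_pools(self, seed, q):
        acts = np.random.default_rng(seed).normal(size=200)
        assert compute_hit_threshold(acts, q) == brute_force_threshold(acts, q)

    def test_active_count_is_ceil_of_quantile(self):
        acts = np.random.default_rng(1).normal(size=333)  # distinct values, no ties
        for q in (0.05, 0.1, 0.5):
            thr = compute_hit_threshold(acts, q)
            assert int(np.sum(acts >= thr)) == math.ceil(q * len(acts))

    def test_out_of_range_quantile_rejected(self):
        with pytest.raises(ValueError):
            compute_hit_threshold(np.ones(5), 0.0)
        with pytest.raises(ValueError):
            compute_hit_threshold(np.ones(5), 1.5)

    def test_threshold_ignores_measurements(self, small_linear):
        # the threshold is a function of true activities only: adding noise to
        # a copy of the pool's measured values cannot change it
        thr = compute_hit_threshold(small_linear, 0.1)
        assert thr == compute_hit_threshold(small_linear.true_activities, 0.1)


# ---------------------------------------------------------------------------
# noise model
# ---------------------------------------------------------------------------

class TestNoiseVariance:
    def test_zero_alpha_means_zero_variance(self):
        assert noise_variance(0.0, 123.4) == 0.0
        assert noise_variance(0.0, 123.4, form="variance") == 0.0

    def test_range_proportional_variance_form(self):
        assert noise_variance(0.1, 6.0, form="variance") == pytest.approx(0.6)
        assert noise_variance(0.2, 6.0, form="variance") == pytest.approx(1.2)

    def test_range_proportional_sd_form(self):
        # default: sigma2 = alpha * range, so the variance is its square
        assert noise_variance(0.1, 6.0) == pytest.approx(0.36)
        assert noise_variance(0.2, 10.0, form="sd") == pytest.approx(4.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            noise_variance(-0.1, 1.0)
        with pytest.raises(ValueError):
            noise_variance(0.1, -1.0)
        with pytest.raises(ValueError):
            noise_variance(0.1, 1.0, form="cubic")


class TestMeasurementOracle:
    def test_noise_free_measurements_equal_true_activity(self, small_linear):
        oracle = MeasurementOracle(small_linear, NoiseModel(0.0, 0.0, base_seed=1))
        for mid in (0, 7, 599):
            m = oracle.measure(mid)
            assert m.measured_value == small_linear.true_activities[mid]

    def test_stream_is_independent_of_query_order(self, small_linear):
        noise = NoiseModel.for_library(small_linear, alpha=0.2, base_seed=5)
        a = MeasurementOracle(small_linear, noise)
        b = MeasurementOracle(small_linear, noise)
        queries = [(3, 0), (17, 1), (3, 1), (599, 0)]
        va = [a.measure(m, r).measured_value for m, r in queries]
        vb = [b.measure(m, r).measured_value for m, r in reversed(queries)]
        assert va == vb[::-1]

    def test_replicates_differ_but_are_reproducible(self, small_linear):
        noise = NoiseModel.for_library(small_linear, alpha=0.2, base_seed=5)
        oracle = MeasurementOracle(small_linear, noise)
        first = oracle.measure(10, replicate_index=0).measured_value
        retest = oracle.measure(10, replicate_index=1).measured_value
        assert first != retest
        assert oracle.measure(10, replicate_index=1).measured_value == retest

    def test_unknown_molecule_rejected(self, small_linear):
        oracle = MeasurementOracle(small_linear, NoiseModel(0.0, 0.0, base_seed=1))
        with pytest.raises(KeyError):
            oracle.measure(len(small_linear))

    def test_noise_is_gaussian_with_stated_variance(self, small_linear):
        noise = NoiseModel.for_library(small_linear, alpha=0.1, base_seed=77)
        oracle = MeasurementOracle(small_linear, noise)
        draws = np.array([oracle.noise_draw(42, k) for k in range(100_000)])
        assert abs(draws.var() / noise.sigma2_sq - 1) < 0.05
        assert abs(draws.mean()) < 3 * math.sqrt(noise.sigma2_sq / draws.size)
        # omnibus normality check on the injected noise
        assert stats.normaltest(draws).pvalue > 1e-3

    def test_noise_model_invariants(self):
        with pytest.raises(ValueError):
            NoiseModel(alpha=0.0, sigma2_sq=1.0, base_seed=0)
        with pytest.raises(ValueError):
            NoiseModel(alpha=0.1, sigma2_sq=0.0, base_seed=0)
        with pytest.raises(ValueError):
            NoiseModel(alpha=-0.1, sigma2_sq=1.0, base_seed=0)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def toy_csv(path, rows, header="f0,f1,f2,f3,activity"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


class TestCsvLoader:
    def test_three_row_toy_table(self, tmp_path):
        p = toy_csv(tmp_path / "lib.csv", ["0,1,0,1,5.0", "1,1,0,0,2.0", "0,0,1,1,9.0"])
        lib = load_library_csv(p)
        assert len(lib) == 3
        assert lib.n_features == 4
        assert lib.true_activities.tolist() == [5.0, 2.0, 9.0]

    def test_label_column_sets_threshold_to_min_active_activity(self, tmp_path):
        p = toy_csv(
            tmp_path / "lib.csv",
            ["0,1,0,1,5.0,0", "1,1,0,0,2.0,0", "0,0,1,1,9.0,1"],
            header="f0,f1,f2,f3,activity,active",
        )
        lib = load_library_csv(p, active_label_column="active")
        assert lib.label_based_hits
        assert lib.hit_threshold == 9.0
        assert lib.is_active.tolist() == [False, False, True]

    def test_round_trip(self, tmp_path, small_linear):
        p = write_library_csv(small_linear, tmp_path / "rt.csv")
        again = load_library_csv(p)
        assert again == small_linear

    def test_missing_column_names_offender(self, tmp_path):
        p = toy_csv(tmp_path / "lib.csv", ["0,1,0,1,5.0"])
        with pytest.raises(LibraryFormatError, match="pXC50"):
            load_library_csv(p, activity_column="pXC50")
        with pytest.raises(LibraryFormatError, match="f9"):
            load_library_csv(p, feature_columns=["f0", "f9"])

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        p = toy_csv(tmp_path / "lib.csv", ["0,1,0,1,5.0", "1,oops,0,0,2.0"])
        with pytest.raises(LibraryFormatError, match="'f1', row 1"):
            load_library_csv(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(LibraryFormatError):
            load_library_csv(p)


class TestScreeningLibraryInvariants:
    def test_feature_row_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ScreeningLibrary(np.ones((3, 2)), np.ones(4))

    def test_activity_range_and_active_mask(self):
        lib = ScreeningLibrary(np.zeros((4, 1)), np.array([0.0, 1.0, 2.0, 3.0]), hit_quantile=0.25)
        assert lib.activity_range == 3.0
        assert lib.hit_threshold == 3.0
        assert lib.is_active.sum() == 1

    def test_record_accessor(self):
        lib = ScreeningLibrary(np.arange(6.0).reshape(3, 2), np.array([1.0, 2.0, 3.0]))
        rec = lib.record(1)
        assert rec.molecule_id == 1
        assert rec.true_activity == 2.0
        with pytest.raises(KeyError):
            lib.record(3)
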