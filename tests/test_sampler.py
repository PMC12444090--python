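"""Subsampling primitives and the adaptive stabilization loop contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stabcurve as sc

from conftest import ConstantAccuracyAdapter, StreamAccuracyAdapter, UniformAccuracyAdapter


class TestSubsampleSize:
    @pytest.mark.parametrize(
        "pool_size, n_percent, expected",
        [
            (100, 10, 10),        # exact percentage
            (250, 100, 250),      # whole pool
            (442, 2.5, 11),       # 11.05 rounds half-up to 11
            (442, 2.6, 11),       # 11.492 -> 11
            (100, 10.5, 11),      # 10.5 rounds half up
            (100, 0.5, 2),        # floored at 2
        ],
    )
    def test_rounding_rule(self, pool_size, n_percent, expected):
        assert sc.subsample_size(pool_size, n_percent) == expected

    def test_out_of_range_percent_rejected(self):
        for bad in (0, -5, 100.1):
            with pytest.raises(ValueError):
                sc.subsample_size(100, bad)


class TestDrawSubsample:
    def test_full_draw_is_a_permutation(self, small_pool, rng):
        sub = sc.draw_subsample(small_pool, small_pool.sample_count, rng)
        np.testing.assert_array_equal(np.sort(sub.target), np.sort(small_pool.target))

    def test_same_stream_state_same_selection(self, small_pool):
        a = sc.draw_subsample(small_pool, 10, np.random.default_rng(5))
        b = sc.draw_subsample(small_pool, 10, np.random.default_rng(5))
        np.testing.assert_array_equal(a.features, b.features)

    def test_out_of_range_draw_rejected(self, small_pool):
        with pytest.raises(ValueError):
            sc.draw_subsample(small_pool, 1, np.random.default_rng(0))
        with pytest.raises(ValueError):
            sc.draw_subsample(small_pool, small_pool.sample_count + 1, np.random.default_rng(0))

    def test_rows_drawn_uniformly(self):
        # minimal draws from a 10-row pool: each row's inclusion frequency
        # should sit within 3 binomial standard errors of d_n/10
        pool = sc.DataPool(np.arange(20, dtype=float).reshape(10, 2), np.arange(10, dtype=float))
        rng = np.random.default_rng(123)
        n_draws, d_n = 10_000, 2
        counts = np.zeros(10)
        for _ in range(n_draws):
            counts[sc.draw_subsample(pool, d_n, rng).target.astype(int)] += 1
        p = d_n / 10
        se = np.sqrt(p * (1 - p) / n_draws)
        np.testing.assert_array_less(np.abs(counts / n_draws - p), 3 * se)


class TestSplitTrainTest:
    @pytest.mark.parametrize("d_n, c, n_train", [(100, 0.7, 70), (3, 0.7, 2), (10, 0.35, 3)])
    def test_split_sizes(self, rng, d_n, c, n_train):
        pool = sc.DataPool(rng.standard_normal((d_n, 2)), rng.standard_normal(d_n))
        train, test = sc.split_train_test(pool, c, rng)
        assert (train.sample_count, test.sample_count) == (n_train, d_n - n_train)

    @given(d_n=st.integers(2, 60), c=st.floats(0.05, 0.95), seed=st.integers(0, 2**20))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_split_is_a_disjoint_partition(self, d_n, c, seed):
        import math

        n_tr = math.floor(c * d_n)
        pool = sc.DataPool(
            np.arange(d_n, dtype=float).reshape(-1, 1), np.arange(d_n, dtype=float)
        )
        rng = np.random.default_rng(seed)
        if n_tr < 1 or d_n - n_tr < 1:
            with pytest.raises(sc.DegenerateSplitError):
                sc.split_train_test(pool, c, rng)
            return
        train, test = sc.split_train_test(pool, c, rng)
        merged = np.concatenate([train.target, test.target])
        np.testing.assert_array_equal(np.sort(merged), pool.target)


class TestSummarize:
    def test_constant_list(self):
        s = sc.summarize([1, 1, 1, 1])
        assert (s.mean, s.median, s.q25, s.q75) == (1, 1, 1, 1)

    def test_linear_interpolation_convention(self):
        s = sc.summarize([1, 2, 3, 4])
        assert (s.mean, s.median, s.q25, s.q75) == (2.5, 2.5, 1.75, 3.25)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_quartiles_are_ordered(self, values):
        s = sc.summarize(values)
        assert s.q25 <= s.median <= s.q75

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sc.summarize([])


class TestCharacteristicsSimilar:
    def _summary(self, **kw):
        base = dict(mean=0.5, median=0.5, q25=0.4, q75=0.6, count=10)
        base.update(kw)
        return sc.DistSummary(**base)

    def test_identical_summaries_pass(self):
        s = self._summary()
        assert sc.characteristics_similar([s, s], 1e-12)

    def test_single_characteristic_excess_fails(self):
        a, b = self._summary(), self._summary(q75=0.602)
        assert not sc.characteristics_similar([a, b], 0.001)
        # comparison is inclusive: a difference exactly at tolerance passes
        c, d = self._summary(), self._summary(q75=0.85)
        assert sc.characteristics_similar([c, d], 0.25)

    def test_any_exceeding_pair_fails(self):
        # only the (first, third) pair exceeds the tolerance
        trio = [self._summary(), self._summary(mean=0.5015), self._summary(mean=0.503)]
        assert not sc.characteristics_similar(trio, 0.002)
        assert sc.characteristics_similar(trio[:2], 0.002)

    def test_per_characteristic_tolerances(self):
        a, b = self._summary(), self._summary(mean=0.52, q75=0.61)
        tol = {"mean": 0.05, "median": 0.01, "q25": 0.01, "q75": 0.05}
        assert sc.characteristics_similar([a, b], tol)
        tol["q75"] = 0.001
        assert not sc.characteristics_similar([a, b], tol)


class TestStabilizeSize:
    def test_zero_variance_converges_in_one_round(self, small_pool, quick_config):
        res = sc.stabilize_size(small_pool, 100, ConstantAccuracyAdapter(0.5), quick_config)
        assert res.converged
        assert res.final_k_n == quick_config.k0_base_reps
        assert res.summaries[(1, "te")].mean == pytest.approx(0.5)

    def test_cap_reached_reports_not_converged(self, small_pool):
        config = sc.StudyConfig(
            size_ladder_S=(100.0,), k0_base_reps=5, tolerance=1e-6,
            max_reps_cap=20, master_seed=3,
        )
        with pytest.warns(sc.StabilizationCapWarning):
            res = sc.stabilize_size(small_pool, 100, UniformAccuracyAdapter(), config)
        assert not res.converged
        assert res.final_k_n == 20

    def test_monotone_effort_in_tolerance(self, small_pool):
        # the accuracy stream is a pure function of (n, j, i): shrinking the
        # tolerance can only postpone the exit
        adapter = StreamAccuracyAdapter(seed=5, scale=0.05)
        ks = {}
        for tol in (0.025, 0.001):
            config = sc.StudyConfig(
                size_ladder_S=(100.0,), k0_base_reps=10, tolerance=tol,
                max_reps_cap=5000, master_seed=9,
            )
            ks[tol] = sc.stabilize_size(small_pool, 100, adapter, config).final_k_n
        assert ks[0.001] >= ks[0.025]

    def test_store_is_append_only_across_tolerances(self, small_pool):
        # the tighter run's accuracy sequence must extend the looser run's
        adapter = StreamAccuracyAdapter(seed=5, scale=0.05)
        stores = {}
        for tol in (0.025, 0.001):
            config = sc.StudyConfig(
                size_ladder_S=(100.0,), k0_base_reps=10, tolerance=tol,
                max_reps_cap=5000, master_seed=9,
            )
            store = sc.AccuracyStore()
            sc.stabilize_size(small_pool, 100, adapter, config, store)
            stores[tol] = store
        short = stores[0.025].get(100, 1, "te")
        long = stores[0.001].get(100, 1, "te")
        np.testing.assert_array_equal(long[: short.size], short)

    def test_final_k_identical_across_instances(self, small_pool):
        config = sc.StudyConfig(
            size_ladder_S=(100.0,), m_instances=3, k0_base_reps=10,
            tolerance=0.05, max_reps_cap=5000, master_seed=2,
        )
        store = sc.AccuracyStore()
        res = sc.stabilize_size(small_pool, 100, StreamAccuracyAdapter(1), config, store)
        for j in (1, 2, 3):
            assert store.get(100, j, "tr").size == res.final_k_n


class TestRunStudy:
    def test_single_entry_whole_pool(self, small_pool, constant_adapter):
        config = sc.StudyConfig(
            size_ladder_S=(100.0,), k0_base_reps=5, tolerance=0.1, master_seed=1
        )
        results = sc.run_study(small_pool, constant_adapter, config)
        assert len(results) == 1
        assert results[0].converged
        assert results[0].d_n == small_pool.sample_count

    def test_bit_identical_reruns(self, small_pool):
        config = sc.StudyConfig(
            size_ladder_S=(50.0, 100.0), k0_base_reps=10, tolerance=0.1, master_seed=77
        )
        frames = []
        for _ in range(2):
            store = sc.AccuracyStore()
            sc.run_study(small_pool, sc.OLSAdapter(), config, store)
            frames.append(sc.store_to_frame(store))
        assert frames[0].equals(frames[1])

    def test_ladder_order_and_sizes(self, small_pool, constant_adapter):
        config = sc.StudyConfig(
            size_ladder_S=(50.0, 100.0), k0_base_reps=5, tolerance=0.1, master_seed=1
        )
        results = sc.run_study(small_pool, constant_adapter, config)
        assert [r.n_percent for r in results] == [50.0, 100.0]
        assert [r.d_n for r in results] == [
            sc.subsample_size(small_pool.sample_count, 50),
            sc.subsample_size(small_pool.sample_count, 100),
        ]
        for r in results:
            assert r.train_size + r.test_size == r.d_n


class TestFixedRepsStudy:
    def test_matches_adaptive_when_both_stop_at_k0(self, small_pool, constant_adapter):
        config = sc.StudyConfig(
            size_ladder_S=(100.0,), k0_base_reps=10, tolerance=0.1, master_seed=4
        )
        s_adaptive, s_fixed = sc.AccuracyStore(), sc.AccuracyStore()
        sc.run_study(small_pool, constant_adapter, config, s_adaptive)
        sc.fixed_reps_study(small_pool, constant_adapter, config, 10, s_fixed)
        assert sc.store_to_frame(s_adaptive).equals(sc.store_to_frame(s_fixed))

    def test_constant_repetition_count(self, small_pool):
        config = sc.StudyConfig(
            size_ladder_S=(50.0, 100.0), k0_base_reps=10, tolerance=0.1, master_seed=4
        )
        results = sc.fixed_reps_study(small_pool, sc.OLSAdapter(), config, 50)
        assert all(r.final_k_n == 50 for r in results)

    def test_single_repetition_rejected(self, small_pool, constant_adapter, quick_config):
        with pytest.raises(ValueError):
            sc.fixed_reps_study(small_pool, constant_adapter, quick_config, 1)


class TestStudyConfigValidation:
    def test_all_problems_reported_at_once(self):
        with pytest.raises(sc.ConfigError) as err:
            sc.StudyConfig(split_fraction_c=1.5, size_ladder_S=(30, 20), m_instances=1)
        msg = str(err.value)
        assert "split_fraction_c" in msg
        assert "ascending" in msg
        assert "m_instances" in msg

    def test_ladder_checked_against_pool(self, small_pool):
        # 3% of 60 rows -> 2 rows; a 0.2 split leaves the training side empty
        config = sc.StudyConfig(split_fraction_c=0.2, size_ladder_S=(3.0, 100.0))
        with pytest.raises(sc.ConfigError):
            config.validate_for_pool(small_pool.sample_count)
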