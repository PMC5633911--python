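"""Screening, gap filling, smoothing, trimming, normalization and selection."""

import numpy as np
import pytest

from conftest import make_cycle
from cyclespm.datatypes import NormalizedCycle
from cyclespm.preprocessing import (
    CyclePreprocessor,
    ProtocolViolationError,
    average_cycles,
    fill_gaps,
    loo_rmse,
    screen_occlusion,
    select_cycles_rmse,
    smooth_curve,
    time_normalize,
    trim_repetitions,
)


def _norm(values, cid, subject="s1"):
    values = np.atleast_2d(np.asarray(values, float))
    chans = tuple(("elbow", f"ch{i}") for i in range(values.shape[0]))
    return NormalizedCycle(subject, "RF", cid, chans, values)


class TestScreenOcclusion:
    @pytest.mark.parametrize("n_missing,keep", [(26, False), (20, True), (0, True)])
    def test_twenty_percent_rule_uses_strict_exceedance(self, n_missing, keep):
        missing = np.zeros((1, 100), dtype=bool)
        missing[0, :n_missing] = True
        cyc = make_cycle(np.zeros(100), missing=missing)
        decision, frac = screen_occlusion(cyc, 0.2)
        assert decision is keep
        assert frac == pytest.approx(n_missing / 100)

    def test_any_channel_missing_counts_the_sample(self):
        missing = np.zeros((2, 100), dtype=bool)
        missing[0, :15] = True
        missing[1, 10:25] = True  # union is 25 samples
        cyc = make_cycle(np.zeros((2, 100)), missing=missing)
        keep, frac = screen_occlusion(cyc, 0.2)
        assert not keep
        assert frac == pytest.approx(0.25)

    def test_invalid_limit_rejected(self):
        cyc = make_cycle(np.zeros(10))
        with pytest.raises(ValueError):
            screen_occlusion(cyc, 1.5)


class TestFillGaps:
    def test_no_gaps_is_identity(self):
        cyc = make_cycle(np.sin(np.linspace(0, 3, 50)))
        assert fill_gaps(cyc) is cyc

    def test_spline_reproduces_a_line_exactly(self):
        y = np.arange(10.0)
        missing = np.zeros((1, 10), dtype=bool)
        missing[0, 2] = True
        cyc = make_cycle(y, missing=missing)
        filled = fill_gaps(cyc)
        assert filled.samples[0, 2] == pytest.approx(2.0, abs=1e-10)
        # observed samples unchanged
        np.testing.assert_array_equal(filled.samples[0, ~missing[0]], y[~missing[0]])

    def test_interior_gap_on_sine_small_error(self):
        t = np.linspace(0, 2 * np.pi, 100)
        y = np.sin(t)
        missing = np.zeros((1, 100), dtype=bool)
        missing[0, 40:50] = True
        filled = fill_gaps(make_cycle(y, missing=missing))
        err = np.abs(filled.samples[0] - y).max()
        assert err < 0.05  # < 5% of unit amplitude

    def test_too_few_observed_samples_raise(self):
        missing = np.ones((1, 10), dtype=bool)
        missing[0, :3] = False
        with pytest.raises(ValueError, match="fewer than 4"):
            fill_gaps(make_cycle(np.zeros(10), missing=missing))


class TestSmoothCurve:
    def test_line_is_a_fixed_point_for_any_target(self):
        y = 3.0 * np.arange(50) - 7.0
        out = smooth_curve(y, predicted_mse=5.0)
        np.testing.assert_allclose(out, y, atol=1e-8)

    def test_zero_target_interpolates(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        out = smooth_curve(y, predicted_mse=0.0)
        np.testing.assert_allclose(out, y, atol=1e-8)

    def test_mean_squared_residual_matches_target(self, rng):
        t = np.linspace(0, 2 * np.pi, 200)
        y = 10 * np.sin(t) + rng.normal(scale=1.0, size=t.size)
        out = smooth_curve(y, predicted_mse=1.0)
        msr = np.mean((out - y) ** 2)
        assert 0.8 <= msr <= 1.2

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError):
            smooth_curve(np.zeros(20), predicted_mse=-1.0)


class TestTrimRepetitions:
    def _recording(self, indices):
        return [make_cycle(np.zeros(10), repetition=i) for i in indices]

    def test_middle_two_of_four_are_kept(self):
        kept = trim_repetitions(self._recording([1, 2, 3, 4]))
        assert [c.repetition_index for c in kept] == [2, 3]

    def test_two_recordings_give_four_cycles_per_task(self):
        # the protocol's bookkeeping: 2 recordings x 4 reps -> 4 retained
        total = sum(len(trim_repetitions(self._recording([1, 2, 3, 4]))) for _ in range(2))
        assert total == 4

    def test_wrong_repetition_count_raises(self):
        with pytest.raises(ProtocolViolationError):
            trim_repetitions(self._recording([1, 2, 3]))

    def test_lenient_mode_trims_first_and_last_present(self):
        with pytest.warns(UserWarning):
            kept = trim_repetitions(self._recording([1, 2, 3]), strict=False)
        assert [c.repetition_index for c in kept] == [2]


class TestTimeNormalize:
    def test_constant_channel_stays_constant(self):
        out = time_normalize(make_cycle(np.full(50, 7.0)), Q=101)
        np.testing.assert_allclose(out.values, 7.0)

    def test_linear_ramp_preserved_with_exact_endpoints(self):
        out = time_normalize(make_cycle(np.arange(50.0)), Q=101)
        assert out.values[0, 0] == 0.0
        assert out.values[0, -1] == 49.0
        np.testing.assert_allclose(out.values[0], np.linspace(0, 49, 101), atol=1e-12)

    def test_interpolation_error_bounded_by_curvature(self):
        T, Q = 120, 101
        t = np.linspace(0, 1, T)
        y = np.sin(2 * np.pi * t)
        out = time_normalize(make_cycle(y), Q=Q)
        exact = np.sin(2 * np.pi * np.linspace(0, 1, Q))
        max_dd = (2 * np.pi) ** 2  # max |second derivative| on the unit domain
        bound = max_dd * (1 / (T - 1)) ** 2 / 8
        assert np.abs(out.values[0] - exact).max() < bound * 1.01

    def test_idempotent_at_fixed_q(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=77).cumsum()
        once = time_normalize(make_cycle(y), Q=101)
        again = time_normalize(make_cycle(once.values[0]), Q=101)
        np.testing.assert_allclose(once.values, again.values, atol=1e-12)


class TestSelectCyclesRmse:
    def test_hand_computed_outlier_case(self):
        cycles = [
            _norm(np.zeros(10), "a"),
            _norm(np.zeros(10), "b"),
            _norm(np.zeros(10), "c"),
            _norm(np.full(10, 10.0), "d"),
        ]
        kept, report = select_cycles_rmse(cycles)
        np.testing.assert_allclose(
            np.sort(report.rmse.to_numpy()), [10 / 3, 10 / 3, 10 / 3, 10.0]
        )
        assert {c.cycle_id for c in kept} == {"a", "b", "c"}

    def test_tie_break_keeps_earlier_cycle_ids(self):
        cycles = [_norm(np.ones(5), cid) for cid in ("a", "b", "c", "d")]
        kept, _ = select_cycles_rmse(cycles)
        assert {c.cycle_id for c in kept} == {"a", "b", "c"}

    def test_selection_is_permutation_invariant_for_distinct_rmse(self, rng):
        base = [_norm(rng.normal(size=(2, 21)), cid) for cid in ("a", "b", "c", "d")]
        kept_ids = {c.cycle_id for c in select_cycles_rmse(base)[0]}
        for perm in ([3, 1, 0, 2], [2, 3, 1, 0], [1, 0, 3, 2]):
            shuffled = [base[i] for i in perm]
            assert {c.cycle_id for c in select_cycles_rmse(shuffled)[0]} == kept_ids

    def test_planted_outlier_always_discarded(self, rng):
        rep_sd = 1.0
        for _ in range(100):
            cycles = [_norm(rng.normal(scale=rep_sd, size=(1, 21)), cid)
                      for cid in ("a", "b", "c", "d")]
            k = rng.integers(4)
            cycles[k].values += 5 * rep_sd
            kept, _ = select_cycles_rmse(cycles)
            assert cycles[k].cycle_id not in {c.cycle_id for c in kept}

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            select_cycles_rmse([_norm(np.zeros(5), "a")] * 3)


class TestAverageCycles:
    def test_three_identical_cycles_average_to_themselves(self):
        c = _norm(np.arange(12.0).reshape(2, 6), "a")
        out = average_cycles([c, c, c])
        np.testing.assert_array_equal(out.values, c.values)
        assert out.n_cycles_used == 3

    def test_matches_independent_mean(self, rng):
        cycles = [_norm(rng.normal(size=(3, 11)), cid) for cid in "abc"]
        out = average_cycles(cycles)
        oracle = sum(c.values for c in cycles) / 3.0
        np.testing.assert_allclose(out.values, oracle, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            average_cycles([_norm(np.zeros(5), "a"), _norm(np.zeros(6), "b")])


class TestPipelineTransformer:
    def test_two_recordings_of_four_reps_yield_three_cycle_average(self):
        rng = np.random.default_rng(7)
        cycles = [
            make_cycle(rng.normal(size=(2, 60)), recording=f"r{rec}", repetition=rep)
            for rec in (1, 2)
            for rep in (1, 2, 3, 4)
        ]
        prep = CyclePreprocessor(Q=51)
        curves = prep.transform(cycles)
        assert len(curves) == 1
        assert curves[0].n_cycles_used == 3
        assert curves[0].Q == 51
        # one discard row logged by the selection stage
        assert (prep.qc_.stage == "select").sum() == 1

    def test_occluded_cycle_is_excluded_and_logged(self):
        rng = np.random.default_rng(8)
        cycles = []
        for rec in (1, 2):
            for rep in (1, 2, 3, 4):
                missing = np.zeros((1, 100), dtype=bool)
                if rec == 1 and rep == 2:
                    missing[0, :30] = True  # 30% occlusion -> excluded
                cyc = make_cycle(rng.normal(size=(1, 100)), missing=missing,
                                 recording=f"r{rec}", repetition=rep)
                cycles.append(cyc)
        prep = CyclePreprocessor(Q=21)
        curves = prep.transform(cycles)
        assert len(curves) == 1
        assert curves[0].n_cycles_used == 3  # 3 usable mid cycles remain
        assert (prep.qc_.action == "exclude").sum() == 1

    def test_loo_rmse_matches_direct_formula(self, rng):
        cycles = [_norm(rng.normal(size=(2, 9)), cid) for cid in "abcd"]
        rmse = loo_rmse(cycles)
        for i in range(4):
            others = [c.values for j, c in enumerate(cycles) if j != i]
            ref = np.mean(others, axis=0)
            expected = np.sqrt(np.mean((cycles[i].values - ref) ** 2))
            assert rmse[i] == pytest.approx(expected, abs=1e-12)
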