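"""Sampling plans, well summaries, subsampling stability and time courses."""

import dataclasses

import numpy as np
import pytest

from aslheight import (
    ASLMeasurement,
    PhantomConfig,
    measure_well,
    relaxation_height,
    render_well,
    serpentine_positions,
    subsample_stability,
    summarize_well,
    timecourse,
)
from aslheight.errors import InsufficientDataError


def meas(height, idx=0, flags=(), well="w", t=0.0):
    return ASLMeasurement(well_id=well, position_index=idx, time_min=t,
                          method="reflection", asl_height=height,
                          qc_flags=frozenset(flags))


class TestSerpentine:
    def test_3x5_grid_alternates_direction(self):
        plan = serpentine_positions(3, 5)
        assert plan.n_positions == 15
        assert plan.order[:5] == tuple((0, c) for c in range(5))
        assert plan.order[5:10] == tuple((1, c) for c in range(4, -1, -1))
        assert plan.order[10:] == tuple((2, c) for c in range(5))

    def test_single_row_is_plain_left_to_right(self):
        plan = serpentine_positions(1, 6)
        assert plan.order == tuple((0, c) for c in range(6))

    def test_positions_confined_to_central_area(self):
        plan = serpentine_positions(4, 4, central_fraction=0.6)
        xs = [x for x, _ in plan.coords]
        ys = [y for _, y in plan.coords]
        assert min(xs + ys) >= 0.2 and max(xs + ys) <= 0.8

    def test_zero_grid_rejected(self):
        with pytest.raises(ValueError):
            serpentine_positions(0, 5)


class TestSummarize:
    def test_hand_computed_summary(self):
        s = summarize_well([meas(4.0), meas(6.0, 1), meas(8.0, 2)])
        assert s.mean == pytest.approx(6.0)
        assert s.sd == pytest.approx(2.0)
        assert s.sem == pytest.approx(1.1547, abs=1e-4)
        assert s.cv == pytest.approx(33.33, abs=0.01)

    def test_equal_heights_have_zero_dispersion(self):
        s = summarize_well([meas(5.0, i) for i in range(4)])
        assert s.sd == 0.0 and s.cv == 0.0

    def test_flagged_positions_are_excluded_but_counted(self):
        s = summarize_well(
            [meas(4.0), meas(6.0, 1), meas(50.0, 2, flags=["fit_quality"])]
        )
        assert s.mean == pytest.approx(5.0)
        assert s.n_positions == 2 and s.n_flagged == 1

    def test_clamped_zero_positions_stay_in_the_mean(self):
        s = summarize_well([meas(0.0, 0, flags=["negative_clamped"]), meas(4.0, 1)])
        assert s.mean == pytest.approx(2.0)
        assert s.n_flagged == 0

    def test_permutation_invariance(self):
        ms = [meas(h, i) for i, h in enumerate((3.0, 9.0, 5.5, 7.2))]
        a = summarize_well(ms)
        b = summarize_well(ms[::-1])
        assert (a.mean, a.sd, a.cv) == (b.mean, b.sd, b.cv)

    def test_insufficient_usable_positions(self):
        with pytest.raises(InsufficientDataError):
            summarize_well([meas(4.0), meas(6.0, 1, flags=["boundary_failure"])])

    def test_phantom_well_mean_matches_truth(self, noisy_well):
        s = summarize_well(measure_well(noisy_well))
        assert s.mean == pytest.approx(8.8, abs=0.3)


class TestSubsampling:
    @pytest.fixture()
    def measurements(self):
        rng = np.random.default_rng(0)
        return [meas(h, i) for i, h in enumerate(rng.normal(8.0, 0.8, 20))]

    def test_full_size_reproduces_the_well_summary_every_rep(self, measurements):
        full = summarize_well(measurements)
        tab = subsample_stability(measurements, [20], n_reps=5, seed=1)
        assert tab.loc[0, "mean_of_means"] == pytest.approx(full.mean)
        assert tab.loc[0, "mean_sd"] == pytest.approx(full.sd)
        assert tab.loc[0, "mean_cv"] == pytest.approx(full.cv)

    def test_same_seed_gives_identical_tables(self, measurements):
        t1 = subsample_stability(measurements, [10, 15], n_reps=50, seed=7)
        t2 = subsample_stability(measurements, [10, 15], n_reps=50, seed=7)
        assert t1.equals(t2)

    def test_oversized_subsample_rejected(self, measurements):
        with pytest.raises(ValueError):
            subsample_stability(measurements, [21], n_reps=5, seed=0)


class TestTimecourse:
    @staticmethod
    def summary_at(t, mean):
        ms = [meas(mean - 0.1, 0, t=t), meas(mean + 0.1, 1, t=t)]
        return summarize_well(ms)

    def test_single_time_point(self):
        df = timecourse([self.summary_at(0.0, 8.0)])
        assert len(df) == 1 and df.loc[0, "mean"] == pytest.approx(8.0)

    def test_unordered_input_is_sorted_by_time(self):
        df = timecourse([self.summary_at(120.0, 6.0), self.summary_at(0.0, 9.0)])
        assert list(df["time_min"]) == [0.0, 120.0]

    def test_duplicate_time_points_rejected(self):
        with pytest.raises(ValueError):
            timecourse([self.summary_at(0.0, 8.0), self.summary_at(0.0, 7.0)])

    def test_volume_challenge_wells_follow_the_exponential(self):
        # initial 20 µm relaxing to 6 µm with tau 60 min, checked at 0/2/6/24 h
        base = PhantomConfig(n_z=400, n_positions=5, tilt=1.0)
        times = [0.0, 120.0, 360.0, 1440.0]
        summaries = []
        for k, t in enumerate(times):
            h = relaxation_height(20.0, 6.0, 60.0, t)
            cfg = dataclasses.replace(base, asl_height=h)
            ms = measure_well(render_well(cfg, seed=50 + k), time_min=t)
            summaries.append(summarize_well(ms))
        df = timecourse(summaries)
        for t, m in zip(df["time_min"], df["mean"]):
            assert m == pytest.approx(relaxation_height(20.0, 6.0, 60.0, t), abs=0.3)
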