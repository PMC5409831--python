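import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prc2mem import ModelParams, SimulationConfig, engine, metrics
from conftest import make_trajectory

HOUR = 3600.0


class TestTimeAverage:
    def test_weighted_mean(self):
        assert metrics.time_average([0.0, 2.0], [1.0, 0.0], t1=10.0) == pytest.approx(0.2)

    def test_constant(self):
        assert metrics.time_average([0.0, 5.0, 7.0], [3.3, 3.3, 3.3], t1=9.0) == pytest.approx(3.3)

    def test_concatenation_consistency(self):
        t = np.array([0.0, 1.0, 4.0, 6.0])
        x = np.array([2.0, 5.0, 1.0, 7.0])
        whole = metrics.time_average(t, x, t1=10.0)
        left = metrics.time_average(t, x, t0=0.0, t1=4.0)
        right = metrics.time_average(t, x, t0=4.0, t1=10.0)
        assert whole == pytest.approx((4 * left + 6 * right) / 10)

    def test_zero_window_rejected(self):
        with pytest.raises(ValueError):
            metrics.time_average([0.0], [1.0], t0=1.0, t1=1.0)


class TestPOnOff:
    def test_pinned_repressed(self):
        traj = make_trajectory([0.0], [60], n=60, t_cc=10 * HOUR,
                               t_final=20 * HOUR, p_t=1 / 3)
        p_on, p_off = metrics.p_on_off(traj)
        assert (p_on, p_off) == (0.0, 1.0)

    def test_pinned_active(self):
        traj = make_trajectory([0.0], [0], n=60, t_cc=10 * HOUR,
                               t_final=20 * HOUR, p_t=1 / 3)
        p_on, p_off = metrics.p_on_off(traj)
        assert (p_on, p_off) == (1.0, 0.0)

    def test_constructed_forty_forty(self):
        """A trajectory spending 40% of each last-hour window above the OFF
        threshold, 40% below the ON threshold and 20% in between gives
        (P_ON, P_OFF) = (0.4, 0.4)."""
        t_cc = 10 * HOUR
        t, n23 = [], []
        for c in range(3):
            start = (c + 1) * t_cc - HOUR
            t += [c * t_cc, start, start + 0.4 * HOUR, start + 0.8 * HOUR]
            n23 += [10, 20, 4, 10]  # OFF needs >15, ON needs <5
        traj = make_trajectory(t, n23, n=60, t_cc=t_cc, t_final=3 * t_cc,
                               p_t=1 / 3)
        p_on, p_off = metrics.p_on_off(traj)
        assert p_off == pytest.approx(0.4)
        assert p_on == pytest.approx(0.4)

    def test_threshold_ties_count_as_neither(self):
        # exactly at the OFF threshold (15) and ON threshold (5)
        t_cc = 10 * HOUR
        traj = make_trajectory([0.0, t_cc - HOUR / 2], [15, 5], n=60,
                               t_cc=t_cc, t_final=t_cc, p_t=1 / 3)
        p_on, p_off = metrics.p_on_off(traj)
        assert (p_on, p_off) == (0.0, 0.0)

    def test_p_t_one_reduces_to_quartile_of_n(self):
        """With P_T = 1 the thresholds are the classical 3N/4 and N/4."""
        t_cc = 10 * HOUR
        traj = make_trajectory([0.0, t_cc - HOUR / 2], [46, 14], n=60,
                               t_cc=t_cc, t_final=t_cc, p_t=1.0)
        p_on, p_off = metrics.p_on_off(traj)
        assert p_off == pytest.approx(0.5)
        assert p_on == pytest.approx(0.5)

    def test_windowing_matters_only_with_transients(self):
        """Last-hour windowing differs from whole-cycle averaging exactly
        when the trajectory has within-cycle transients."""
        t_cc = 10 * HOUR
        # dips below the OFF threshold early in the cycle, recovers later
        traj = make_trajectory([0.0, 5 * HOUR], [10, 20], n=60, t_cc=t_cc,
                               t_final=t_cc, p_t=1 / 3)
        _, off_last = metrics.p_on_off(traj, window="last_hour")
        _, off_all = metrics.p_on_off(traj, window="all")
        assert off_last == pytest.approx(1.0)
        assert off_all == pytest.approx(0.5)
        # without transients the two windows agree
        flat = make_trajectory([0.0], [20], n=60, t_cc=t_cc, t_final=t_cc,
                               p_t=1 / 3)
        assert metrics.p_on_off(flat, window="last_hour") == metrics.p_on_off(
            flat, window="all"
        )

    def test_agrees_with_kernel_accumulators(self, fitted):
        cfg = SimulationConfig(initial_state="uniform_me3",
                               equilibration_cycles=0, total_cycles=3, seed=5)
        traj = engine.run(cfg, fitted)
        p_on, p_off = metrics.p_on_off(traj)
        assert p_on == pytest.approx(traj.summary.p_on, abs=1e-12)
        assert p_off == pytest.approx(traj.summary.p_off, abs=1e-12)


class TestBistability:
    @pytest.mark.parametrize(
        "p_on,p_off,expected", [(0.5, 0.5, 1.0), (0.0, 1.0, 0.0), (0.4, 0.4, 0.64)]
    )
    def test_examples(self, p_on, p_off, expected):
        assert metrics.bistability(p_on, p_off) == pytest.approx(expected)

    @given(p_on=st.floats(0, 1), p_off=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_symmetry(self, p_on, p_off):
        b = metrics.bistability(p_on, p_off)
        assert b >= 0.0
        if p_on + p_off <= 1.0:  # the occupancies are mutually exclusive
            assert b <= 1.0 + 1e-12
        assert b == pytest.approx(metrics.bistability(p_off, p_on))

    def test_maximized_at_balanced_occupancy(self):
        grid = np.linspace(0, 0.5, 51)
        values = [metrics.bistability(p, 0.5) for p in grid]
        assert np.argmax(values) == 50

    def test_invalid_probabilities(self):
        with pytest.raises(ValueError):
            metrics.bistability(-0.1, 0.5)


class TestFirstPassage:
    def test_never_switching_gives_fp_one(self):
        res = metrics.first_passage([100.0] * 5, [100.0] * 5, 100.0)
        assert res.fp == pytest.approx(1.0)
        assert res.t_fp_me0_s == pytest.approx(100.0)

    def test_half_and_full(self):
        res = metrics.first_passage([50.0], [100.0], 100.0)
        assert res.fp == pytest.approx(0.5)

    def test_censoring_clips_at_horizon(self):
        res = metrics.first_passage([250.0], [40.0], 100.0)
        assert res.t_fp_me0_s == pytest.approx(100.0)
        assert 0.0 < res.fp <= 1.0

    def test_deterministic_crossing_detection(self):
        t_cc = 10 * HOUR
        traj = make_trajectory([0.0, 3 * HOUR, 4 * HOUR], [0, 10, 20], n=60,
                               t_cc=t_cc, t_final=t_cc, p_t=1 / 3)
        assert metrics.crossing_time(traj, "uniform_me0") == pytest.approx(4 * HOUR)
        # from the repressed side the same trajectory crosses at t = 0
        traj3 = make_trajectory([0.0, 3 * HOUR], [60, 4], n=60, t_cc=t_cc,
                                t_final=t_cc, p_t=1 / 3)
        assert metrics.crossing_time(traj3, "uniform_me3") == pytest.approx(3 * HOUR)

    def test_trajectory_detection_matches_kernel_early_stop(self, fitted):
        """Threshold detection on a recorded trajectory reproduces the
        kernel's own first-passage stop time for the same seed."""
        p = fitted.replace(k_me=4e-5, p_dem=0.2)  # fast-switching regime
        times = engine.first_passage_ensemble(p, "uniform_me3", 4, 30, 900)
        for r in range(4):
            cfg = SimulationConfig(initial_state="uniform_me3",
                                   equilibration_cycles=0, total_cycles=30,
                                   seed=900 + r)
            traj = engine.run(cfg, p)
            assert metrics.crossing_time(traj, "uniform_me3") == pytest.approx(
                times[r]
            )

    def test_mismatched_horizons_rejected(self, fitted):
        t_cc = 10 * HOUR
        a = make_trajectory([0.0], [0], n=60, t_cc=t_cc, t_final=t_cc)
        b = make_trajectory([0.0], [60], n=60, t_cc=t_cc, t_final=2 * t_cc)
        with pytest.raises(ValueError):
            metrics.first_passage_from_trajectories([a], [b])


class TestTranscriptionalOutput:
    def test_zero_events(self):
        traj = make_trajectory([0.0], [60], n=60, t_cc=22 * HOUR,
                               t_final=22 * HOUR)
        assert metrics.transcriptional_output(traj, 1) == 0.0

    def test_one_per_hour(self, fitted):
        from prc2mem import _kernels as K

        t_cc = 22 * HOUR
        t = np.linspace(0.1, t_cc, 22, endpoint=False)
        traj = make_trajectory(t, [0] * 22, n=60, t_cc=t_cc, t_final=t_cc)
        traj.event[:] = K.EV_TX
        assert metrics.transcriptional_output(traj, 1) == pytest.approx(1.0)

    def test_requested_cycle_must_exist(self):
        traj = make_trajectory([0.0], [0], n=60, t_cc=22 * HOUR,
                               t_final=22 * HOUR)
        with pytest.raises(ValueError):
            metrics.transcriptional_output(traj, 2)

    def test_fully_active_rate_matches_poisson_oracle(self, fitted):
        """A frozen fully-active locus transcribes at f_max; over pooled
        replicates the measured events per cycle match rate x time within
        the Poisson error."""
        p = fitted.replace(beta=0.0, p_dem=0.0, p_ex=0.0,
                           replication_survival=1.0)
        outputs = []
        for r in range(60):
            cfg = SimulationConfig(initial_state="uniform_me0",
                                   equilibration_cycles=0, total_cycles=1,
                                   seed=100 + r)
            traj = engine.run(cfg, p)
            outputs.append(metrics.transcriptional_output(traj, 1))
        mean_per_cycle = np.mean(outputs) * 22.0
        expected = p.f_max * p.t_cc  # 316.8 events per cycle
        se = np.sqrt(expected / 60)
        assert abs(mean_per_cycle - expected) < 3 * se


class TestH33Asymmetry:
    def test_no_exchange_anywhere(self, fitted):
        p = fitted.replace(p_ex=0.0)
        trajs = []
        for initial in ("uniform_me0", "uniform_me3"):
            cfg = SimulationConfig(initial_state=initial,
                                   equilibration_cycles=0, total_cycles=1,
                                   seed=3)
            trajs.append(engine.run(cfg, p))
        assert metrics.h33_asymmetry([trajs[0]], [trajs[1]]) == 0.0

    def test_identical_pools(self, short_run):
        assert metrics.h33_asymmetry([short_run], [short_run]) == 0.0

    def test_active_state_accumulates_h33(self, fitted):
        """At the fitted parameters the active state accumulates
        exchange-deposited (H3.3-like) histones while the repressed state
        does not, giving a clearly positive asymmetry H."""
        on, off = [], []
        for r in range(6):
            for initial, pool in (("uniform_me0", on), ("uniform_me3", off)):
                cfg = SimulationConfig(initial_state=initial,
                                       equilibration_cycles=0,
                                       total_cycles=20, seed=700 + r)
                pool.append(engine.run(cfg, fitted))
        h = metrics.h33_asymmetry(on, off)
        assert h > 0.2


class TestCV:
    def test_constant_signal(self):
        assert metrics.coefficient_of_variation([0.0, 1.0], [2.0, 2.0], t1=2.0) == 0.0

    def test_two_level_signal(self):
        # x = 0 half the time, 2 half the time: mean 1, var 1, CV 1
        cv = metrics.coefficient_of_variation([0.0, 1.0], [0.0, 2.0], t1=2.0)
        assert cv == pytest.approx(1.0)
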