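import numpy as np
import pytest
import scipy.stats

from prc2mem import (
    BurstParams,
    ModelParams,
    RegulatorParams,
    SimulationConfig,
    StepProtocol,
    engine,
)
from prc2mem import chromatin as C
from prc2mem import _kernels as K


def total_methyl(traj):
    return traj.counts @ np.arange(4)


class TestDeterminism:
    def test_same_seed_same_trajectory(self, fitted):
        cfg = SimulationConfig(initial_state="uniform_me3",
                               equilibration_cycles=0, total_cycles=2, seed=3)
        a = engine.run(cfg, fitted)
        b = engine.run(cfg, fitted)
        assert np.array_equal(a.t, b.t)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.event, b.event)

    def test_different_seeds_differ(self, fitted):
        cfg1 = SimulationConfig(equilibration_cycles=0, total_cycles=1, seed=3)
        cfg2 = SimulationConfig(equilibration_cycles=0, total_cycles=1, seed=4)
        a = engine.run(cfg1, fitted)
        b = engine.run(cfg2, fitted)
        assert not np.array_equal(a.t, b.t)


class TestBackendEquivalence:
    """The compiled kernel and the pure-Python loop over the reference
    operations share only the RNG stream; identical trajectories mean the
    kernel's propensities and updates match the reference definitions."""

    @pytest.mark.parametrize(
        "variant",
        ["main", "processive_methylation", "processive_demethylation",
         "two_state"],
    )
    @pytest.mark.parametrize("initial", ["uniform_me0", "uniform_me3"])
    def test_bit_identical(self, fitted, variant, initial):
        cfg = SimulationConfig(variant=variant, initial_state=initial,
                               equilibration_cycles=0, total_cycles=2,
                               seed=11)
        a = engine.run(cfg, fitted, record_levels=True)
        b = engine.run(cfg, fitted, backend="python", record_levels=True)
        assert np.array_equal(a.t, b.t)
        assert np.array_equal(a.event, b.event)
        assert np.array_equal(a.levels, b.levels)
        assert np.array_equal(a.tx_cum, b.tx_cum)

    def test_bit_identical_promoter_switching(self, fitted):
        cfg = SimulationConfig(variant="promoter_switching",
                               initial_state="uniform_me3",
                               equilibration_cycles=0, total_cycles=2,
                               seed=13)
        burst = BurstParams(5e-4, 5e-3)
        a = engine.run(cfg, fitted, burst=burst, record_levels=True)
        b = engine.run(cfg, fitted, burst=burst, backend="python",
                       record_levels=True)
        assert np.array_equal(a.t, b.t)
        assert np.array_equal(a.event, b.event)
        assert np.array_equal(a.levels, b.levels)
        assert np.array_equal(a.promoter, b.promoter)

    def test_bit_identical_coupled_regulator(self, fitted):
        cfg = SimulationConfig(initial_state="uniform_me0",
                               equilibration_cycles=0, total_cycles=1,
                               seed=17)
        reg = RegulatorParams(b=50.0)
        a = engine.run_coupled(cfg, fitted, reg, record_levels=True)
        b = engine.run(cfg, fitted, trans_input=reg, backend="python",
                       record_levels=True)
        assert np.array_equal(a.t, b.t)
        assert np.array_equal(a.event, b.event)
        assert np.array_equal(a.protein, b.protein)
        assert np.array_equal(a.alpha, b.alpha)


class TestReplicationInterrupts:
    def test_absorbed_state_advances_through_replications(self, fitted):
        """With every reaction switched off the trajectory contains exactly
        the replication events, one per cell-cycle boundary."""
        p = fitted.replace(beta=0.0, p_dem=0.0, p_ex=0.0, alpha=0.0)
        cfg = SimulationConfig(initial_state="uniform_me3",
                               equilibration_cycles=0, total_cycles=2, seed=1)
        traj = engine.run(cfg, p)
        reps = traj.event == K.EV_REPLICATION
        assert reps.sum() == 2
        assert np.allclose(traj.t[reps], [p.t_cc, 2 * p.t_cc])
        assert traj.event[0] == K.EV_INIT

    def test_replication_once_per_cycle_any_regime(self, fitted):
        cfg = SimulationConfig(initial_state="uniform_me0",
                               equilibration_cycles=0, total_cycles=5, seed=2)
        traj = engine.run(cfg, fitted)
        rep_times = traj.t[traj.event == K.EV_REPLICATION]
        assert np.allclose(rep_times, fitted.t_cc * np.arange(1, 6))

    def test_counts_conserved_through_everything(self, fitted):
        p = fitted.replace(p_ex=0.05, p_dem=0.05)
        cfg = SimulationConfig(initial_state="uniform_me3",
                               equilibration_cycles=0, total_cycles=3, seed=9)
        traj = engine.run(cfg, p)
        assert (traj.counts.sum(axis=1) == 60).all()
        assert (traj.t[1:] >= traj.t[:-1]).all()


class TestWaitingTimes:
    def test_rescaled_intervals_are_unit_exponential(self, oracle_params):
        """Inter-event waiting times multiplied by the total propensity of
        the originating state follow Exp(1) (direct-method correctness);
        segments truncated by replication boundaries are excluded."""
        cfg = SimulationConfig(initial_state="uniform_me0",
                               equilibration_cycles=0, total_cycles=1,
                               seed=23)
        traj = engine.run(cfg, oracle_params, record_levels=True)
        totals = np.empty(len(traj))
        st = C.ChromatinState.uniform(oracle_params.n_histones, 0)
        for k in range(len(traj)):
            st.levels[:] = traj.levels[k]
            r = sum(
                C.methylation_propensity(st, i, oracle_params)
                + C.noisy_demethylation_propensity(st, i, oracle_params)
                for i in range(1, oracle_params.n_histones + 1)
            )
            totals[k] = r + C.transcription_propensity(st, oracle_params)
        dt = np.diff(traj.t)
        keep = traj.event[1:] != K.EV_REPLICATION
        scaled = dt[keep] * totals[:-1][keep]
        assert scaled.size > 1000
        p_value = scipy.stats.kstest(scaled, "expon").pvalue
        assert p_value > 0.01


class TestMonotonicityOracles:
    def test_methyl_count_nondecreasing_without_removal(self, fitted):
        p = fitted.replace(p_dem=0.0, p_ex=0.0, replication_survival=1.0)
        cfg = SimulationConfig(initial_state="uniform_me0",
                               equilibration_cycles=0, total_cycles=2, seed=4)
        traj = engine.run(cfg, p)
        assert (np.diff(total_methyl(traj)) >= 0).all()

    def test_methyl_count_nonincreasing_without_addition(self, fitted):
        # k_me = 0 zeroes both the stimulated rates and their noise floors
        p = fitted.replace(k_me=0.0, replication_survival=1.0)
        cfg = SimulationConfig(initial_state="uniform_me3",
                               equilibration_cycles=0, total_cycles=2, seed=4)
        traj = engine.run(cfg, p)
        assert (np.diff(total_methyl(traj)) <= 0).all()


class TestPropensityCrossCheck:
    @pytest.mark.parametrize("variant", ["main", "two_state", "promoter_switching"])
    def test_kernel_matches_reference_on_random_states(self, fitted, variant):
        """Element-by-element agreement of the compiled propensity vector
        with the reference operations, including the regulator block (which
        also verifies the union propensity is the plain sum of parts)."""
        rng = np.random.default_rng(8)
        n = fitted.n_histones
        burst = (BurstParams(5e-4, 5e-3).derive(fitted)
                 if variant == "promoter_switching" else None)
        reg = RegulatorParams(b=10.0)
        vcode = engine.VARIANT_CODES[variant]
        pvec = engine.pack_params(fitted, burst)
        rvec = engine.pack_regulator(reg)
        for _ in range(25):
            if variant == "two_state":
                levels = rng.choice([0, 3], size=n).astype(np.int8)
            else:
                levels = rng.integers(0, 4, size=n).astype(np.int8)
            state = C.ChromatinState(
                levels=levels.copy(),
                origin=np.zeros(n, dtype=np.int8),
                age=np.zeros(n, dtype=np.int8),
                promoter=int(rng.integers(0, 2)),
            )
            cnt = state.counts()
            mrna, protein = int(rng.integers(0, 5)), int(rng.integers(0, 2000))
            kernel_props = np.zeros(2 * n + 6)
            total = K.fill_propensities(
                state.levels, state.promoter, cnt, mrna, protein, pvec, rvec,
                vcode, 1, 1.0, kernel_props,
            )
            scal_i = np.zeros(K.N_SCAL_I, dtype=np.int64)
            scal_i[K.SI_PROMOTER] = state.promoter
            scal_i[K.SI_MRNA] = mrna
            scal_i[K.SI_PROTEIN] = protein
            ref_props = np.zeros(2 * n + 6)
            ref_total = engine._reference_propensities(
                state, cnt, scal_i, rvec, fitted, vcode, 1, 1.0, burst,
                ref_props,
            )
            np.testing.assert_allclose(kernel_props, ref_props, rtol=1e-12)
            assert total == pytest.approx(ref_total, rel=1e-12)


class TestBurstMeanRateIdentity:
    def test_repressed_mean_initiation_rate_is_f_min(self, fitted):
        """With the chromatin pinned fully repressed, the promoter cycles
        between open and closed states and the long-run initiation rate
        f_0 * k_on_min/(k_on_min + k_off) equals f_min by construction."""
        p = fitted.replace(beta=0.0, p_dem=0.0, p_ex=0.0,
                           replication_survival=1.0)
        # bursty counts are super-Poissonian, so use the empirical spread
        # of per-replicate rates rather than a Poisson error bar
        rates = []
        for r in range(20):
            pinned = C.ChromatinState.uniform(60, C.ME2)  # P = 1 >= P_T
            pinned.promoter = C.CLOSED
            cfg = SimulationConfig(variant="promoter_switching",
                                   initial_state="custom",
                                   equilibration_cycles=0, total_cycles=60,
                                   seed=31 + r, record_mode="none")
            traj = engine.run(cfg, p, burst=BurstParams(5e-4, 5e-3),
                              custom_state=pinned)
            rates.append(traj.final_state.tx_count / traj.t_final)
        rates = np.asarray(rates)
        se = rates.std(ddof=1) / np.sqrt(rates.size)
        assert abs(rates.mean() - p.f_min) < 3 * se


class TestConfigValidation:
    def test_burst_variant_requires_burst_params(self, fitted):
        cfg = SimulationConfig(variant="promoter_switching",
                               equilibration_cycles=0, total_cycles=1)
        with pytest.raises(ValueError):
            engine.run(cfg, fitted)

    def test_burst_params_rejected_elsewhere(self, fitted):
        cfg = SimulationConfig(variant="two_state", equilibration_cycles=0,
                               total_cycles=1)
        with pytest.raises(ValueError):
            engine.run(cfg, fitted, burst=BurstParams(5e-4, 5e-3))

    def test_two_state_rejects_step_protocol(self, fitted):
        cfg = SimulationConfig(variant="two_state", equilibration_cycles=0,
                               total_cycles=1)
        with pytest.raises(ValueError):
            engine.run(cfg, fitted, trans_input=StepProtocol(1.0, 5.0))

    def test_unknown_names_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(variant="nope")
        with pytest.raises(ValueError):
            SimulationConfig(initial_state="nope")


class TestTrajectoryIO:
    def test_tsv_roundtrip(self, short_run, tmp_path):
        path = tmp_path / "traj.tsv"
        short_run.to_tsv(str(path))
        back = engine.Trajectory.from_tsv(str(path))
        assert np.allclose(back.t, short_run.t)
        assert np.array_equal(back.counts, short_run.counts)
        assert np.array_equal(back.event, short_run.event)
        assert back.n == short_run.n
        assert back.t_final == short_run.t_final
        assert back.meta["seed"] == short_run.meta["seed"]


class TestStepProtocol:
    def test_strong_activation_erases_repression(self, fitted):
        """A persistent jump to alpha = 100 after equilibration drives the
        repressed state to the active one within a few cycles."""
        cfg = SimulationConfig(initial_state="uniform_me3",
                               equilibration_cycles=2, total_cycles=8,
                               seed=19)
        traj = engine.run(cfg, fitted, trans_input=StepProtocol(1.0, 100.0))
        final_me23 = traj.n_me23[-1] / traj.n
        assert final_me23 < fitted.p_t / 4
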