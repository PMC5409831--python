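"""Direct Gillespie simulation engine with replication interrupts.

`run` drives any model variant and returns a `Trajectory` (ordered event
record) plus a `SimSummary` of time-weighted accumulators.  The default
backend is a compiled numba kernel; `backend="python"` runs a readable loop
over the reference operations in `chromatin` using the identical random
stream, so the two backends produce bit-identical trajectories — this is the
engine's primary correctness contract.

Fast ensemble helpers (`first_passage_ensemble`, `bistability_ensemble`)
skip event recording and let the kernel stop at threshold crossings, which
is what makes full-scale protocols (hundreds of cell cycles, many
replicates) tractable on a desktop.

Seed discipline: every simulation owns one xoshiro256++ stream; ensembles
derive replicate seeds as base_seed + replicate_index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import _kernels as K
from . import chromatin as C
from .params import BurstParams, DerivedBurstParams, ModelParams
from .trans_input import RegulatorParams, StepProtocol

VARIANT_CODES = {
    "main": K.V_MAIN,
    "two_state": K.V_TWO_STATE,
    "processive_methylation": K.V_PROC_METH,
    "processive_demethylation": K.V_PROC_DEMETH,
    "promoter_switching": K.V_BURST,
}

EVENT_NAMES = {
    K.EV_INIT: "init",
    K.EV_METH: "methylation",
    K.EV_DEMETH: "demethylation",
    K.EV_TX: "transcription",
    K.EV_REPLICATION: "replication",
    K.EV_PROMOTER: "promoter",
    K.EV_MRNA_BIRTH: "mrna_birth",
    K.EV_MRNA_DEATH: "mrna_death",
    K.EV_PROT_BIRTH: "protein_birth",
    K.EV_PROT_DEATH: "protein_death",
}


@dataclass
class SimulationConfig:
    """What to simulate: variant, initial condition, duration, seed."""

    variant: str = "main"
    initial_state: str = "uniform_me3"  # uniform_me0 | uniform_me3 | custom
    equilibration_cycles: int = 5
    total_cycles: int = 20  # measurement cycles after equilibration
    seed: int = 0
    record_mode: str = "events"  # events | none

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_CODES:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.initial_state not in ("uniform_me0", "uniform_me3", "custom"):
            raise ValueError(f"unknown initial_state {self.initial_state!r}")
        if self.total_cycles < 1:
            raise ValueError("total_cycles must be >= 1")
        if self.equilibration_cycles < 0:
            raise ValueError("equilibration_cycles must be >= 0")
        if self.record_mode not in ("events", "none"):
            raise ValueError(f"unknown record_mode {self.record_mode!r}")


@dataclass
class SimSummary:
    """Time-weighted accumulators over the measurement phase.

    P_OFF/P_ON use the strict thresholds n_me2+n_me3 > 3*N*P_T/4 (OFF) and
    < N*P_T/4 (ON), time-averaged over the last hour of each cell cycle.
    """

    window_time: float
    off_time: float
    on_time: float
    total_time: float
    exch_fraction_mean: float
    me3_fraction_mean: float
    me23_fraction_mean: float
    tx_per_cycle: np.ndarray
    stopped: bool = False
    stop_time: float = float("nan")

    @property
    def p_off(self) -> float:
        return self.off_time / self.window_time if self.window_time > 0 else 0.0

    @property
    def p_on(self) -> float:
        return self.on_time / self.window_time if self.window_time > 0 else 0.0


@dataclass
class Trajectory:
    """Ordered event record of one simulation.

    Records are the state *after* each event; a synthetic "init" record at
    the start time carries the initial state.  `t_final` closes the last
    piecewise-constant segment.  Counts always sum to N.
    """

    t: np.ndarray
    event: np.ndarray
    counts: np.ndarray  # (K, 4) histones at me0..me3
    tx_cum: np.ndarray
    promoter: np.ndarray
    alpha: np.ndarray
    exch: np.ndarray  # exchange-deposited histone count
    protein: np.ndarray
    n: int
    t_cc: float
    t_final: float
    levels: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)
    summary: SimSummary | None = None
    final_state: C.ChromatinState | None = None

    def __len__(self) -> int:
        return self.t.size

    @property
    def n_me23(self) -> np.ndarray:
        return self.counts[:, 2] + self.counts[:, 3]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.t,
                "event": [EVENT_NAMES[int(e)] for e in self.event],
                "n_me0": self.counts[:, 0],
                "n_me1": self.counts[:, 1],
                "n_me2": self.counts[:, 2],
                "n_me3": self.counts[:, 3],
                "tx_cum": self.tx_cum,
                "promoter": self.promoter,
                "alpha": self.alpha,
                "n_exchange_origin": self.exch,
                "protein": self.protein,
            }
        )

    def to_tsv(self, path: str) -> None:
        """Write the event table as TSV with a JSON metadata sidecar."""
        self.to_frame().to_csv(path, sep="\t", index=False)
        side = dict(self.meta)
        side.update(n=self.n, t_cc=self.t_cc, t_final=self.t_final)
        with open(str(path) + ".json", "w") as fh:
            json.dump(side, fh, indent=2, sort_keys=True, default=str)

    @classmethod
    def from_tsv(cls, path: str) -> "Trajectory":
        df = pd.read_csv(path, sep="\t")
        with open(str(path) + ".json") as fh:
            side = json.load(fh)
        rev = {v: k for k, v in EVENT_NAMES.items()}
        return cls(
            t=df["time_s"].to_numpy(float),
            event=np.array([rev[e] for e in df["event"]], dtype=np.int8),
            counts=df[["n_me0", "n_me1", "n_me2", "n_me3"]].to_numpy(np.int64),
            tx_cum=df["tx_cum"].to_numpy(np.int64),
            promoter=df["promoter"].to_numpy(np.int8),
            alpha=df["alpha"].to_numpy(np.float32),
            exch=df["n_exchange_origin"].to_numpy(np.int64),
            protein=df["protein"].to_numpy(np.int64),
            n=int(side.pop("n")),
            t_cc=float(side.pop("t_cc")),
            t_final=float(side.pop("t_final")),
            meta=side,
        )


# -- parameter packing -------------------------------------------------------


def pack_params(
    params: ModelParams, burst: DerivedBurstParams | None = None
) -> np.ndarray:
    pvec = np.zeros(K.N_PVEC)
    pvec[K.P_BETA] = params.beta
    pvec[K.P_KME] = params.k_me
    pvec[K.P_RHO] = params.rho_me2
    pvec[K.P_FMIN] = params.f_min
    pvec[K.P_FMAX] = params.f_max
    pvec[K.P_PT] = params.p_t
    pvec[K.P_PDEM] = params.p_dem
    pvec[K.P_PEX] = params.p_ex
    pvec[K.P_FCAP] = params.f_cap
    pvec[K.P_GDEM] = params.gamma_dem
    pvec[K.P_TCC] = params.t_cc
    pvec[K.P_KME01] = params.k_me0_1
    pvec[K.P_KME12] = params.k_me1_2
    pvec[K.P_G01] = params.gamma_me0_1
    pvec[K.P_G12] = params.gamma_me1_2
    pvec[K.P_G23] = params.gamma_me2_3
    pvec[K.P_PREPLACE] = 1.0 - params.replication_survival
    pvec[K.P_GME_2S] = params.k_me / 20.0
    if burst is not None:
        pvec[K.P_KONMAX] = burst.k_on_max
        pvec[K.P_KOFF] = burst.k_off
        pvec[K.P_KONMIN] = burst.k_on_min
        pvec[K.P_F0] = burst.f_0
        pvec[K.P_KONCAP] = burst.k_on_cap
    return pvec


def pack_regulator(reg: RegulatorParams | None) -> np.ndarray:
    rvec = np.zeros(K.N_RVEC)
    if reg is not None:
        rvec[K.R_SR] = reg.s_r_per_s
        rvec[K.R_DR] = reg.d_r_per_s
        rvec[K.R_SP] = reg.s_p_per_s
        rvec[K.R_DP] = reg.d_p_per_s
        rvec[K.R_MEAN] = reg.mean_protein
    return rvec


def _initial_state(
    config: SimulationConfig, params: ModelParams, custom: C.ChromatinState | None
) -> C.ChromatinState:
    if config.initial_state == "custom":
        if custom is None:
            raise ValueError("initial_state='custom' requires a ChromatinState")
        state = custom.copy()
    else:
        level = C.ME0 if config.initial_state == "uniform_me0" else C.ME3
        state = C.ChromatinState.uniform(params.n_histones, level)
        # bursty variant: active start opens the promoter, repressed closes it
        state.promoter = C.OPEN if level == C.ME0 else C.CLOSED
    state.validate()
    return state


class _Recorder:
    """Growable record buffers shared by both backends."""

    def __init__(self, enabled: bool, cap: int = 1 << 14, n: int = 0,
                 levels: bool = False) -> None:
        self.enabled = enabled
        self.n = n if (enabled and levels) else 0
        self.cap = cap if enabled else 1
        self._alloc(self.cap)

    def _alloc(self, cap: int) -> None:
        self.t = np.zeros(cap)
        self.event = np.zeros(cap, dtype=np.int8)
        self.counts = np.zeros((cap, 4), dtype=np.int16)
        self.tx = np.zeros(cap, dtype=np.int64)
        self.prom = np.zeros(cap, dtype=np.int8)
        self.alpha = np.zeros(cap, dtype=np.float32)
        self.exch = np.zeros(cap, dtype=np.int16)
        self.prot = np.zeros(cap, dtype=np.int32)
        self.levels = np.zeros((cap if self.n else 0, max(self.n, 1)),
                               dtype=np.int8)

    def grow(self) -> None:
        old = (self.t, self.event, self.counts, self.tx, self.prom,
               self.alpha, self.exch, self.prot, self.levels)
        self.cap *= 2
        self._alloc(self.cap)
        for new, prev in zip(
            (self.t, self.event, self.counts, self.tx, self.prom,
             self.alpha, self.exch, self.prot, self.levels),
            old,
        ):
            new[: prev.shape[0]] = prev


def _make_scal(state: C.ChromatinState, next_rep_index: int,
               mrna: int, protein: int) -> tuple[np.ndarray, np.ndarray]:
    scal_i = np.zeros(K.N_SCAL_I, dtype=np.int64)
    scal_i[K.SI_PROMOTER] = state.promoter
    scal_i[K.SI_TX] = state.tx_count
    scal_i[K.SI_NEXT_REP] = next_rep_index
    scal_i[K.SI_MRNA] = mrna
    scal_i[K.SI_PROTEIN] = protein
    scal_i[K.SI_NEXCH] = int(np.count_nonzero(state.origin == C.EXCHANGE_DEPOSITED))
    scal_f = np.array([state.t])
    return scal_i, scal_f


def run(
    config: SimulationConfig,
    params: ModelParams,
    trans_input: float | StepProtocol | RegulatorParams | None = None,
    burst: BurstParams | DerivedBurstParams | None = None,
    custom_state: C.ChromatinState | None = None,
    backend: str = "numba",
    sample_times: np.ndarray | None = None,
    record_levels: bool = False,
) -> Trajectory:
    """Simulate one trajectory; returns the Trajectory with its summary.

    `trans_input` sets the trans-activation signal alpha: a constant (None
    means params.alpha), a StepProtocol (switching at the end of
    equilibration), or RegulatorParams for a concurrently simulated noisy
    regulator.  The summary accumulators cover only the measurement phase
    (after equilibration); the event record covers the whole run.
    """
    if config.variant == "promoter_switching":
        if burst is None:
            raise ValueError("promoter_switching variant requires BurstParams")
        if isinstance(burst, BurstParams):
            burst = burst.derive(params)
    elif burst is not None:
        raise ValueError(f"variant {config.variant!r} does not take BurstParams")
    if config.variant == "two_state" and isinstance(
        trans_input, (StepProtocol, RegulatorParams)
    ):
        raise ValueError("two_state variant supports only constant alpha")

    state = _initial_state(config, params, custom_state)
    vcode = VARIANT_CODES[config.variant]
    pvec = pack_params(params, burst)

    reg: RegulatorParams | None = None
    alpha_mode = 0
    mrna = protein = 0
    if isinstance(trans_input, RegulatorParams):
        reg = trans_input
        alpha_mode = 1
        mrna, protein = reg.stationary_counts()
    rvec = pack_regulator(reg)

    t_cc = params.t_cc
    n_equil = config.equilibration_cycles
    n_total = n_equil + config.total_cycles
    t_switch = n_equil * t_cc
    t_end = n_total * t_cc

    # phases: (t_stop, alpha0); alpha is constant within a phase
    if isinstance(trans_input, StepProtocol):
        phases = [(t_switch, trans_input.alpha_before),
                  (t_end, trans_input.alpha_after)]
    else:
        a0 = params.alpha if trans_input is None or reg is not None else float(trans_input)
        if t_switch > 0:
            phases = [(t_switch, a0), (t_end, a0)]
        else:
            phases = [(t_end, a0)]

    rng = K.seed_state(config.seed)
    scal_i, scal_f = _make_scal(state, next_rep_index=1, mrna=mrna, protein=protein)
    cnt = state.counts()
    rec = _Recorder(config.record_mode == "events", n=params.n_histones,
                    levels=record_levels)
    record_flag = 1 if rec.enabled else 0
    acc = np.zeros(K.N_ACC)
    tx_per_cycle = np.zeros(n_total + 1, dtype=np.int64)
    if sample_times is None:
        sample_times = np.empty(0)
    sample_out = np.full((sample_times.size, 4), np.nan)
    props = np.zeros(2 * params.n_histones + 6)

    step = _python_step_runner(params, vcode, burst) if backend == "python" else None
    if backend not in ("numba", "python"):
        raise ValueError(f"unknown backend {backend!r}")

    # initial record
    if rec.enabled:
        alpha0_init = protein / reg.mean_protein if reg is not None else phases[0][1]
        K._record.py_func(
            rec.t, rec.event, rec.counts, rec.tx, rec.prom, rec.alpha,
            rec.exch, rec.prot, rec.levels, state.levels, scal_i, cnt,
            state.t, K.EV_INIT, alpha0_init,
        )

    for phase_idx, (t_stop, alpha0) in enumerate(phases):
        measuring = t_stop > t_switch or n_equil == 0
        if measuring and phase_idx == len(phases) - 1 and n_equil > 0:
            acc[:] = 0.0  # summary covers the measurement phase only
        while True:
            args = (
                state.levels, state.origin, state.age, cnt, scal_i, scal_f,
                rng, pvec, rvec, vcode, alpha_mode, float(alpha0),
                float(t_stop), 1, 0, 0.0, record_flag,
                rec.t, rec.event, rec.counts, rec.tx, rec.prom, rec.alpha,
                rec.exch, rec.prot, rec.levels, acc, tx_per_cycle,
                sample_times, sample_out, props,
            )
            code = (K.run_kernel(*args) if backend == "numba" else step(*args))
            if code == 1:
                rec.grow()
                continue
            break

    state.promoter = int(scal_i[K.SI_PROMOTER])
    state.tx_count = int(scal_i[K.SI_TX])
    state.t = float(scal_f[0])

    summary = SimSummary(
        window_time=acc[K.A_WINDOW],
        off_time=acc[K.A_OFF],
        on_time=acc[K.A_ON],
        total_time=acc[K.A_TIME],
        exch_fraction_mean=acc[K.A_EXCH] / acc[K.A_TIME] if acc[K.A_TIME] else 0.0,
        me3_fraction_mean=acc[K.A_ME3] / acc[K.A_TIME] if acc[K.A_TIME] else 0.0,
        me23_fraction_mean=acc[K.A_ME23] / acc[K.A_TIME] if acc[K.A_TIME] else 0.0,
        tx_per_cycle=tx_per_cycle[:n_total].copy(),
    )
    k = scal_i[K.SI_RECLEN]
    traj = Trajectory(
        t=rec.t[:k].copy(),
        event=rec.event[:k].copy(),
        counts=rec.counts[:k].astype(np.int64),
        tx_cum=rec.tx[:k].copy(),
        promoter=rec.prom[:k].copy(),
        alpha=rec.alpha[:k].copy(),
        exch=rec.exch[:k].astype(np.int64),
        protein=rec.prot[:k].astype(np.int64),
        levels=rec.levels[:k].copy() if rec.n else None,
        n=params.n_histones,
        t_cc=t_cc,
        t_final=t_end,
        meta={
            "seed": config.seed,
            "variant": config.variant,
            "initial_state": config.initial_state,
            "equilibration_cycles": n_equil,
            "total_cycles": config.total_cycles,
            "backend": backend,
            "params": params.to_dict(),
        },
        summary=summary,
        final_state=state,
    )
    traj.sample_times = sample_times  # type: ignore[attr-defined]
    traj.samples = sample_out  # type: ignore[attr-defined]
    if rec.enabled:
        _check_counts(traj)
    return traj


def _check_counts(traj: Trajectory) -> None:
    if traj.t.size and not np.all(traj.counts.sum(axis=1) == traj.n):
        raise AssertionError("histone count conservation violated")


def run_coupled(
    config: SimulationConfig,
    params: ModelParams,
    regulator_params: RegulatorParams,
    burst: BurstParams | DerivedBurstParams | None = None,
    **kwargs: Any,
) -> Trajectory:
    """Simulate chromatin and the noisy trans-regulator as one reaction
    union; the transcription propensity uses alpha(t) = r(t)/<r>."""
    return run(config, params, trans_input=regulator_params, burst=burst, **kwargs)


# -- pure-Python reference backend ------------------------------------------


class _XoshiroAdapter:
    """numpy-Generator-like facade over the shared xoshiro stream, so the
    reference operations in `chromatin` consume the same draws as the
    compiled kernel."""

    def __init__(self, rng_state: np.ndarray) -> None:
        self._state = rng_state

    def random(self, size: int | None = None):
        if size is None:
            return K.rand_u01(self._state)
        return np.array([K.rand_u01(self._state) for _ in range(size)])


def _python_step_runner(params: ModelParams, vcode: int,
                        burst: DerivedBurstParams | None):
    """Build a drop-in replacement for run_kernel executing the readable
    reference operations (chromatin module) with identical draw order."""

    def step(
        S, origin, age, cnt, scal_i, scal_f, rng, pvec, rvec, variant,
        alpha_mode, alpha0, t_end, final_rep, stop_mode, stop_level, record,
        rec_t, rec_event, rec_n, rec_tx, rec_prom, rec_alpha, rec_exch,
        rec_prot, rec_levels, acc, tx_per_cycle, sample_times, sample_out,
        props,
    ) -> int:
        n = S.size
        t_cc = pvec[K.P_TCC]
        state = C.ChromatinState(levels=S, origin=origin, age=age)
        adapter = _XoshiroAdapter(rng)
        t = scal_f[0]
        while True:
            K._flush_samples.py_func(S, age, scal_i, sample_times, sample_out, t)
            if record and scal_i[K.SI_RECLEN] >= rec_t.size:
                scal_f[0] = t
                return 1
            state.promoter = int(scal_i[K.SI_PROMOTER])
            total = _reference_propensities(
                state, cnt, scal_i, rvec, params, vcode, alpha_mode, alpha0,
                burst, props,
            )
            alpha = (scal_i[K.SI_PROTEIN] / rvec[K.R_MEAN]
                     if alpha_mode == 1 else alpha0)
            next_rep = scal_i[K.SI_NEXT_REP] * t_cc
            t_next = t + K.rand_exp(rng) / total if total > 0 else np.inf
            off_thr = 3.0 * n * pvec[K.P_PT] / 4.0
            on_thr = n * pvec[K.P_PT] / 4.0
            if next_rep <= t_end and next_rep < t_next:
                if next_rep == t_end and final_rep == 0:
                    K._flush_samples.py_func(S, age, scal_i, sample_times,
                                             sample_out, t_end)
                    K._accumulate.py_func(acc, cnt, n, scal_i[K.SI_NEXCH], t,
                                          t_end, t_cc, off_thr, on_thr)
                    scal_f[0] = t_end
                    return 0
                K._flush_samples.py_func(S, age, scal_i, sample_times,
                                         sample_out, next_rep)
                K._accumulate.py_func(acc, cnt, n, scal_i[K.SI_NEXCH], t,
                                      next_rep, t_cc, off_thr, on_thr)
                t = next_rep
                before_exch = int(np.count_nonzero(origin == C.EXCHANGE_DEPOSITED))
                C.apply_replication(state, params, adapter)
                cnt[:] = state.counts()
                scal_i[K.SI_NEXCH] += (
                    int(np.count_nonzero(origin == C.EXCHANGE_DEPOSITED))
                    - before_exch
                )
                scal_i[K.SI_NEXT_REP] += 1
                if record:
                    K._record.py_func(rec_t, rec_event, rec_n, rec_tx,
                                      rec_prom, rec_alpha, rec_exch, rec_prot,
                                      rec_levels, S, scal_i, cnt, t,
                                      K.EV_REPLICATION, alpha)
                if _crossed(cnt, stop_mode, stop_level):
                    scal_f[0] = t
                    return 3
                if t >= t_end:
                    scal_f[0] = t
                    return 0
                continue
            if t_next >= t_end:
                K._flush_samples.py_func(S, age, scal_i, sample_times,
                                         sample_out, t_end)
                K._accumulate.py_func(acc, cnt, n, scal_i[K.SI_NEXCH], t,
                                      t_end, t_cc, off_thr, on_thr)
                scal_f[0] = t_end
                return 0
            K._flush_samples.py_func(S, age, scal_i, sample_times, sample_out,
                                     t_next)
            K._accumulate.py_func(acc, cnt, n, scal_i[K.SI_NEXCH], t, t_next,
                                  t_cc, off_thr, on_thr)
            t = t_next
            u = K.rand_u01(rng) * total
            idx = int(np.searchsorted(np.cumsum(props[: 2 * n + 6]), u,
                                      side="right"))
            code = _apply_reference_reaction(
                state, cnt, scal_i, idx, params, vcode, adapter, t, t_cc,
                tx_per_cycle,
            )
            if record:
                if alpha_mode == 1:
                    alpha = scal_i[K.SI_PROTEIN] / rvec[K.R_MEAN]
                K._record.py_func(rec_t, rec_event, rec_n, rec_tx, rec_prom,
                                  rec_alpha, rec_exch, rec_prot, rec_levels,
                                  S, scal_i, cnt, t, code, alpha)
            if code in (K.EV_METH, K.EV_DEMETH, K.EV_TX) and _crossed(
                cnt, stop_mode, stop_level
            ):
                scal_f[0] = t
                return 3

    return step


def _crossed(cnt: np.ndarray, stop_mode: int, stop_level: float) -> bool:
    n23 = cnt[2] + cnt[3]
    if stop_mode == 1:
        return n23 > stop_level
    if stop_mode == 2:
        return n23 < stop_level
    return False


def _reference_propensities(
    state: C.ChromatinState, cnt, scal_i, rvec, params: ModelParams,
    vcode: int, alpha_mode: int, alpha0: float,
    burst: DerivedBurstParams | None, props: np.ndarray,
) -> float:
    n = state.n
    props[:] = 0.0
    alpha = (scal_i[K.SI_PROTEIN] / rvec[K.R_MEAN] if alpha_mode == 1
             else alpha0)
    if vcode == K.V_TWO_STATE:
        props[: 2 * n + 1] = C.two_state_propensities(state, params)
    else:
        for i in range(1, n + 1):
            props[i - 1] = C.methylation_propensity(state, i, params)
            props[n + i - 1] = C.noisy_demethylation_propensity(state, i, params)
        if vcode == K.V_BURST:
            assert burst is not None
            if state.promoter == C.OPEN:
                props[2 * n] = burst.f_0
                props[2 * n + 1] = burst.k_off
            else:
                props[2 * n + 1] = C.burst_k_on(state, params, burst, alpha)
        else:
            props[2 * n] = C.transcription_propensity(state, params, alpha)
    if alpha_mode == 1:
        m = scal_i[K.SI_MRNA]
        p = scal_i[K.SI_PROTEIN]
        props[2 * n + 2] = rvec[K.R_SR]
        props[2 * n + 3] = rvec[K.R_DR] * m
        props[2 * n + 4] = rvec[K.R_SP] * m
        props[2 * n + 5] = rvec[K.R_DP] * p
    # sequential sum, matching the compiled kernel's accumulation order
    total = 0.0
    for k in range(2 * n + 6):
        total += props[k]
    return total


def _apply_reference_reaction(
    state: C.ChromatinState, cnt, scal_i, idx: int, params: ModelParams,
    vcode: int, adapter: "_XoshiroAdapter", t: float, t_cc: float,
    tx_per_cycle: np.ndarray,
) -> int:
    n = state.n
    if idx < n:
        if vcode in (K.V_PROC_METH, K.V_TWO_STATE):
            state.levels[idx] = C.ME3
        else:
            state.levels[idx] += 1
        cnt[:] = state.counts()
        return K.EV_METH
    if idx < 2 * n:
        k = idx - n
        if vcode == K.V_PROC_DEMETH:
            C.processive_demethylation_update(state, k + 1)
        else:
            state.levels[k] -= 1
        cnt[:] = state.counts()
        return K.EV_DEMETH
    if idx == 2 * n:
        if vcode == K.V_TWO_STATE:
            C.two_state_apply_transcription(state, params, adapter)
        else:
            before = int(np.count_nonzero(state.origin == C.EXCHANGE_DEPOSITED))
            C.apply_transcription_event(
                state, params, adapter,
                processive_demethylation=(vcode == K.V_PROC_DEMETH),
            )
            scal_i[K.SI_NEXCH] += (
                int(np.count_nonzero(state.origin == C.EXCHANGE_DEPOSITED))
                - before
            )
        cnt[:] = state.counts()
        scal_i[K.SI_TX] += 1
        ci = int(t / t_cc)
        if ci < tx_per_cycle.size:
            tx_per_cycle[ci] += 1
        return K.EV_TX
    if idx == 2 * n + 1:
        scal_i[K.SI_PROMOTER] = 1 - scal_i[K.SI_PROMOTER]
        return K.EV_PROMOTER
    if idx == 2 * n + 2:
        scal_i[K.SI_MRNA] += 1
        return K.EV_MRNA_BIRTH
    if idx == 2 * n + 3:
        scal_i[K.SI_MRNA] -= 1
        return K.EV_MRNA_DEATH
    if idx == 2 * n + 4:
        scal_i[K.SI_PROTEIN] += 1
        return K.EV_PROT_BIRTH
    scal_i[K.SI_PROTEIN] -= 1
    return K.EV_PROT_DEATH


# -- fast ensemble protocols -------------------------------------------------


def first_passage_ensemble(
    params: ModelParams,
    initial_state: str,
    n_replicates: int,
    censor_cycles: int,
    seed: int,
    variant: str = "main",
    burst: BurstParams | DerivedBurstParams | None = None,
    regulator: RegulatorParams | None = None,
    alpha: float | None = None,
) -> np.ndarray:
    """First-passage times (seconds) to the opposite chromatin state.

    Each replicate starts in the given uniform state and runs until
    n_me2+n_me3 first crosses the opposite-state threshold (strictly above
    3*N*P_T/4 from a me0 start; strictly below N*P_T/4 from a me3 start) or
    until the censoring horizon, whichever comes first; censored replicates
    report the horizon itself.
    """
    if initial_state not in ("uniform_me0", "uniform_me3"):
        raise ValueError("initial_state must be uniform_me0 or uniform_me3")
    if isinstance(burst, BurstParams):
        burst = burst.derive(params)
    vcode = VARIANT_CODES[variant]
    pvec = pack_params(params, burst)
    rvec = pack_regulator(regulator)
    alpha_mode = 1 if regulator is not None else 0
    alpha0 = params.alpha if alpha is None else float(alpha)
    n = params.n_histones
    t_end = censor_cycles * params.t_cc
    if initial_state == "uniform_me0":
        stop_mode, stop_level, level = 1, params.off_threshold, C.ME0
    else:
        stop_mode, stop_level, level = 2, params.on_threshold, C.ME3
    empty = np.empty(0)
    empty_out = np.empty((0, 4))
    dummy = _Recorder(False)
    times = np.empty(n_replicates)
    props = np.zeros(2 * n + 6)
    for r in range(n_replicates):
        state = C.ChromatinState.uniform(n, level)
        state.promoter = C.OPEN if level == C.ME0 else C.CLOSED
        rng = K.seed_state(seed + r)
        mrna, protein = regulator.stationary_counts() if regulator else (0, 0)
        scal_i, scal_f = _make_scal(state, 1, mrna, protein)
        cnt = state.counts()
        acc = np.zeros(K.N_ACC)
        tx_pc = np.zeros(censor_cycles + 1, dtype=np.int64)
        code = K.run_kernel(
            state.levels, state.origin, state.age, cnt, scal_i, scal_f, rng,
            pvec, rvec, vcode, alpha_mode, alpha0, t_end, 1, stop_mode,
            stop_level, 0, dummy.t, dummy.event, dummy.counts, dummy.tx,
            dummy.prom, dummy.alpha, dummy.exch, dummy.prot, dummy.levels,
            acc, tx_pc, empty, empty_out, props,
        )
        times[r] = scal_f[0] if code == 3 else t_end
    return times


def bistability_ensemble(
    params: ModelParams,
    n_replicates_per_state: int,
    n_cycles: int,
    seed: int,
    variant: str = "main",
    burst: BurstParams | DerivedBurstParams | None = None,
    regulator: RegulatorParams | None = None,
    alpha: float | None = None,
    equilibration_cycles: int = 0,
) -> dict[str, float]:
    """Pooled P_ON/P_OFF/B over replicates from both uniform initial states.

    Occupancies are time-averaged over the last hour of every cell cycle
    (after any equilibration cycles), pooled over all replicates, matching
    the bistability-scan protocol.
    """
    if isinstance(burst, BurstParams):
        burst = burst.derive(params)
    vcode = VARIANT_CODES[variant]
    pvec = pack_params(params, burst)
    rvec = pack_regulator(regulator)
    alpha_mode = 1 if regulator is not None else 0
    alpha0 = params.alpha if alpha is None else float(alpha)
    n = params.n_histones
    n_total = equilibration_cycles + n_cycles
    empty = np.empty(0)
    empty_out = np.empty((0, 4))
    dummy = _Recorder(False)
    props = np.zeros(2 * n + 6)
    pooled = np.zeros(3)  # off, on, window
    r_idx = 0
    for level in (C.ME0, C.ME3):
        for _ in range(n_replicates_per_state):
            state = C.ChromatinState.uniform(n, level)
            state.promoter = C.OPEN if level == C.ME0 else C.CLOSED
            rng = K.seed_state(seed + r_idx)
            r_idx += 1
            mrna, protein = regulator.stationary_counts() if regulator else (0, 0)
            scal_i, scal_f = _make_scal(state, 1, mrna, protein)
            cnt = state.counts()
            acc = np.zeros(K.N_ACC)
            tx_pc = np.zeros(n_total + 1, dtype=np.int64)
            if equilibration_cycles > 0:
                K.run_kernel(
                    state.levels, state.origin, state.age, cnt, scal_i,
                    scal_f, rng, pvec, rvec, vcode, alpha_mode, alpha0,
                    equilibration_cycles * params.t_cc, 1, 0, 0.0, 0,
                    dummy.t, dummy.event, dummy.counts, dummy.tx, dummy.prom,
                    dummy.alpha, dummy.exch, dummy.prot, dummy.levels, acc,
                    tx_pc, empty, empty_out, props,
                )
                acc[:] = 0.0
            K.run_kernel(
                state.levels, state.origin, state.age, cnt, scal_i, scal_f,
                rng, pvec, rvec, vcode, alpha_mode, alpha0,
                n_total * params.t_cc, 1, 0, 0.0, 0,
                dummy.t, dummy.event, dummy.counts, dummy.tx, dummy.prom,
                dummy.alpha, dummy.exch, dummy.prot, dummy.levels, acc,
                tx_pc, empty, empty_out, props,
            )
            pooled[0] += acc[K.A_OFF]
            pooled[1] += acc[K.A_ON]
            pooled[2] += acc[K.A_WINDOW]
    p_off = pooled[0] / pooled[2] if pooled[2] > 0 else 0.0
    p_on = pooled[1] / pooled[2] if pooled[2] > 0 else 0.0
    return {"p_off": p_off, "p_on": p_on, "b": 4.0 * p_off * p_on}
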