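"""Summary statistics over simulated trajectories.

All quantities follow the piecewise-constant convention: the state recorded
at t_i holds on [t_i, t_{i+1}), and time averages weight each value by its
segment length.  Occupancy-based quantities (P_ON, P_OFF, B) are by default
evaluated only over the last hour of each cell cycle, so that the transient
dilution at DNA replication does not penalize states that are stable in the
long run.

Thresholds are strict inequalities: the gene is OFF when the repressive
mark count n_me2+n_me3 exceeds 3*N*P_T/4 (the lower quartile of the
chromatin-controlled transcription rate) and ON when it is below N*P_T/4;
exact ties count as neither.  With P_T = 1 these reduce to the classical
three-quarters / one-quarter definitions of the bistability literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .engine import Trajectory

LAST_HOUR = 3600.0


@dataclass
class MetricsResult:
    """Bundle of the summary statistics for one parameter set."""

    p_on: float = float("nan")
    p_off: float = float("nan")
    b: float = float("nan")
    t_fp_me0_s: float = float("nan")
    t_fp_me3_s: float = float("nan")
    t_fp_me0_cycles: float = float("nan")
    t_fp_me3_cycles: float = float("nan")
    fp: float = float("nan")
    tx_output_per_hr: float = float("nan")
    h: float = float("nan")
    cv: float = float("nan")

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def _segments(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Segment start and end times; the final segment closes at t_final."""
    starts = traj.t
    ends = np.empty_like(starts)
    ends[:-1] = starts[1:]
    if starts.size:
        ends[-1] = max(traj.t_final, starts[-1])
    return starts, ends


def time_average(
    t: np.ndarray, x: np.ndarray, t0: float | None = None,
    t1: float | None = None,
) -> float:
    """Time-weighted mean of a piecewise-constant quantity.

    `x[i]` holds on [t[i], t[i+1]); the last value extends to t1.  The
    average over [t0, t1] is sum(x_i * overlap_i) / (t1 - t0).
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size == 0 or t.size != x.size:
        raise ValueError("need equal-length, nonempty time/value arrays")
    if t0 is None:
        t0 = t[0]
    if t1 is None:
        t1 = t[-1]
    if not t1 > t0:
        raise ValueError("zero-length averaging window")
    ends = np.empty_like(t)
    ends[:-1] = t[1:]
    ends[-1] = max(t1, t[-1])
    lo = np.clip(t, t0, t1)
    hi = np.clip(ends, t0, t1)
    w = np.maximum(hi - lo, 0.0)
    return float(np.sum(x * w) / (t1 - t0))


def _window_overlap(starts: np.ndarray, ends: np.ndarray, t_cc: float) -> np.ndarray:
    """Overlap of each segment with the last hour of its own cell cycle.
    Segments never span replication boundaries, so one window suffices."""
    cyc_end = (np.floor(starts / t_cc) + 1.0) * t_cc
    return np.maximum(np.minimum(ends, cyc_end) - np.maximum(starts, cyc_end - LAST_HOUR), 0.0)


def p_on_off(
    traj: Trajectory,
    p_t: float | None = None,
    window: str = "last_hour",
    t_start: float = 0.0,
) -> tuple[float, float]:
    """Time-averaged (P_ON, P_OFF) of the chromatin expression state.

    OFF: n_me2+n_me3 > 3*N*P_T/4; ON: n_me2+n_me3 < N*P_T/4 (strict).
    `window="last_hour"` restricts to the final hour of each cell cycle;
    `window="all"` uses the whole of [t_start, t_final].
    """
    if p_t is None:
        p_t = float(traj.meta.get("params", {}).get("p_t", 1.0))
    n = traj.n
    off_thr = 3.0 * n * p_t / 4.0
    on_thr = n * p_t / 4.0
    starts, ends = _segments(traj)
    keep = ends > t_start
    starts = np.maximum(starts[keep], t_start)
    ends = ends[keep]
    n23 = traj.n_me23[keep]
    if window == "last_hour":
        w = _window_overlap(starts, ends, traj.t_cc)
    elif window == "all":
        w = ends - starts
    else:
        raise ValueError(f"unknown window {window!r}")
    total = w.sum()
    if total <= 0:
        return 0.0, 0.0
    p_off_v = float(w[n23 > off_thr].sum() / total)
    p_on_v = float(w[n23 < on_thr].sum() / total)
    return p_on_v, p_off_v


def bistability(p_on: float, p_off: float) -> float:
    """Balanced bistability measure B = 4 * P_OFF * P_ON, in [0, 1] and
    maximal when both states are occupied half the time."""
    if not (0 <= p_on <= 1 and 0 <= p_off <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return 4.0 * p_off * p_on


def crossing_time(
    traj: Trajectory, initial_state: str, p_t: float | None = None
) -> float:
    """First time the trajectory reaches the opposite chromatin state;
    censored at t_final.  From a me0 start the crossing is n_me2+n_me3 >
    3*N*P_T/4, from a me3 start n_me2+n_me3 < N*P_T/4 (strict), evaluated
    at event resolution."""
    if p_t is None:
        p_t = float(traj.meta.get("params", {}).get("p_t", 1.0))
    n = traj.n
    n23 = traj.n_me23
    if initial_state == "uniform_me0":
        hit = n23 > 3.0 * n * p_t / 4.0
    elif initial_state == "uniform_me3":
        hit = n23 < n * p_t / 4.0
    else:
        raise ValueError("initial_state must be uniform_me0 or uniform_me3")
    idx = np.flatnonzero(hit)
    return float(traj.t[idx[0]]) if idx.size else float(traj.t_final)


def first_passage(
    me0_times: np.ndarray | list,
    me3_times: np.ndarray | list,
    total_time: float,
) -> MetricsResult:
    """Censored-mean first-passage times and the combined measure FP.

    Inputs are per-replicate crossing times (seconds), censored at
    `total_time` (replicates that never switch contribute the full horizon).
    FP = t_FP(me0) * t_FP(me3) / T^2 lies in (0, 1]; values near 1 mean
    both states survive the whole simulation.
    """
    me0 = np.minimum(np.asarray(me0_times, dtype=float), total_time)
    me3 = np.minimum(np.asarray(me3_times, dtype=float), total_time)
    if me0.size == 0 or me3.size == 0:
        raise ValueError("need at least one replicate per initial state")
    t0 = float(me0.mean())
    t3 = float(me3.mean())
    res = MetricsResult()
    res.t_fp_me0_s = t0
    res.t_fp_me3_s = t3
    res.fp = t0 * t3 / total_time**2
    return res


def first_passage_from_trajectories(
    me0_trajs: list[Trajectory],
    me3_trajs: list[Trajectory],
    p_t: float | None = None,
) -> MetricsResult:
    """`first_passage` computed by threshold detection on recorded
    trajectories (all replicates must share the same horizon)."""
    horizons = {t.t_final for t in me0_trajs} | {t.t_final for t in me3_trajs}
    if len(horizons) != 1:
        raise ValueError("replicates must share one total simulation time")
    total = horizons.pop()
    me0 = [crossing_time(t, "uniform_me0", p_t) for t in me0_trajs]
    me3 = [crossing_time(t, "uniform_me3", p_t) for t in me3_trajs]
    return first_passage(me0, me3, total)


def transcriptional_output(
    traj: Trajectory, cycle_index: int, offset_cycles: int = 0
) -> float:
    """Transcription events per hour in the given cell cycle (1-based,
    counted after `offset_cycles` equilibration cycles)."""
    if cycle_index < 1:
        raise ValueError("cycle_index is 1-based")
    c0 = (offset_cycles + cycle_index - 1) * traj.t_cc
    c1 = c0 + traj.t_cc
    if c1 > traj.t_final + 1e-9:
        raise ValueError("trajectory does not span the requested cycle")
    is_tx = traj.event == K.EV_TX
    in_cycle = (traj.t > c0) & (traj.t <= c1)
    return float(np.count_nonzero(is_tx & in_cycle) / (traj.t_cc / 3600.0))


def exchange_fraction_mean(traj: Trajectory, t_start: float = 0.0) -> float:
    """Time-averaged fraction of exchange-deposited ("H3.3") histones."""
    starts, ends = _segments(traj)
    keep = ends > t_start
    lo = np.maximum(starts[keep], t_start)
    w = ends[keep] - lo
    frac = traj.exch[keep] / traj.n
    return float(np.sum(frac * w) / np.sum(w))


def h33_asymmetry(
    on_replicates: list[Trajectory],
    off_replicates: list[Trajectory],
    t_start: float = 0.0,
) -> float:
    """Transcription-dependent H3.3 accumulation H = |<H3.3>_ON -
    <H3.3>_OFF|: the absolute difference in time-averaged
    exchange-deposited histone fraction between simulations started in the
    active versus repressed state."""
    if not on_replicates or not off_replicates:
        raise ValueError("need replicates for both pools")
    on = np.mean([exchange_fraction_mean(t, t_start) for t in on_replicates])
    off = np.mean([exchange_fraction_mean(t, t_start) for t in off_replicates])
    return float(abs(on - off))


def coefficient_of_variation(t: np.ndarray, x: np.ndarray,
                             t1: float | None = None) -> float:
    """Time-weighted CV of a piecewise-constant signal."""
    mean = time_average(t, x, t1=t1)
    second = time_average(t, np.asarray(x, dtype=float) ** 2, t1=t1)
    var = max(second - mean**2, 0.0)
    return float(np.sqrt(var) / mean) if mean else float("nan")
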