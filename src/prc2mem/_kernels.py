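"""Compiled (numba) direct-Gillespie kernels and the shared RNG.

The RNG is xoshiro256++ seeded through splitmix64, with one stream per
simulation.  The same compiled primitives back both the fast kernel and the
pure-Python reference engine, so the two can be compared bit-for-bit.

Propensity vector layout for a system of N histones (recomputed after every
system update):

  [0, N)        methylation of histone i
  [N, 2N)       noisy demethylation of histone i
  2N            transcription initiation
  2N+1          promoter toggle (bursty variant: k_on if closed, k_off if open)
  2N+2 .. 2N+5  regulator reactions (mRNA birth/death, protein birth/death)

Scalar-state array layouts (mutated in place so a run can be resumed, e.g.
after growing a record buffer):

  scal_i = [promoter, tx_count, next_rep_index, mRNA, protein,
            sample_idx, rec_len, n_exchange_origin]
  scal_f = [t]

Exit codes: 0 reached t_end; 1 record buffer full (call again to resume);
3 first-passage threshold crossed (time left in scal_f[0]).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# -- parameter vector indices ------------------------------------------------
P_BETA = 0
P_KME = 1
P_RHO = 2
P_FMIN = 3
P_FMAX = 4
P_PT = 5
P_PDEM = 6
P_PEX = 7
P_FCAP = 8
P_GDEM = 9
P_TCC = 10
P_KME01 = 11
P_KME12 = 12
P_G01 = 13
P_G12 = 14
P_G23 = 15
P_PREPLACE = 16
P_GME_2S = 17
P_KONMAX = 18
P_KOFF = 19
P_KONMIN = 20
P_F0 = 21
P_KONCAP = 22
N_PVEC = 23

# -- regulator rate vector indices (all rates in s^-1) -----------------------
R_SR = 0
R_DR = 1
R_SP = 2
R_DP = 3
R_MEAN = 4
N_RVEC = 5

# -- variant codes -----------------------------------------------------------
V_MAIN = 0
V_TWO_STATE = 1
V_PROC_METH = 2
V_PROC_DEMETH = 3
V_BURST = 4

# -- scal_i indices ----------------------------------------------------------
SI_PROMOTER = 0
SI_TX = 1
SI_NEXT_REP = 2
SI_MRNA = 3
SI_PROTEIN = 4
SI_SAMPLE = 5
SI_RECLEN = 6
SI_NEXCH = 7
N_SCAL_I = 8

# -- accumulator indices -----------------------------------------------------
A_OFF = 0  # time in OFF within last-hour windows
A_ON = 1  # time in ON within last-hour windows
A_WINDOW = 2  # total time within last-hour windows
A_EXCH = 3  # integral of exchange-origin fraction dt
A_TIME = 4  # total elapsed time
A_ME3 = 5  # integral of me3 fraction dt
A_ME23 = 6  # integral of me2/me3 fraction dt
N_ACC = 7

# -- event codes -------------------------------------------------------------
EV_INIT = 0
EV_METH = 1
EV_DEMETH = 2
EV_TX = 3
EV_REPLICATION = 4
EV_PROMOTER = 5
EV_MRNA_BIRTH = 6
EV_MRNA_DEATH = 7
EV_PROT_BIRTH = 8
EV_PROT_DEATH = 9

LAST_HOUR = 3600.0


# -- RNG: splitmix64 seeding, xoshiro256++ stream ----------------------------


_MASK64 = 0xFFFFFFFFFFFFFFFF


def seed_state(seed: int) -> np.ndarray:
    """Initialize a xoshiro256++ state from an integer seed (splitmix64)."""
    state = np.empty(4, dtype=np.uint64)
    x = int(seed) & _MASK64
    for k in range(4):
        x = (x + 0x9E3779B97F4A7C15) & _MASK64
        z = x
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
        state[k] = np.uint64(z ^ (z >> 31))
    if not state.any():  # all-zero state is invalid for xoshiro
        state[0] = np.uint64(1)
    return state


@njit(cache=True, inline="always")
def _rotl(x, k):
    return (x << np.uint64(k)) | (x >> np.uint64(64 - k))


@njit(cache=True)
def next_u64(rng):
    result = _rotl(rng[0] + rng[3], 23) + rng[0]
    t = rng[1] << np.uint64(17)
    rng[2] ^= rng[0]
    rng[3] ^= rng[1]
    rng[1] ^= rng[2]
    rng[0] ^= rng[3]
    rng[2] ^= t
    rng[3] = _rotl(rng[3], 45)
    return result


@njit(cache=True)
def rand_u01(rng):
    """Uniform double in [0, 1) with 53-bit resolution."""
    return float(next_u64(rng) >> np.uint64(11)) * (2.0 ** -53)


@njit(cache=True)
def rand_exp(rng):
    """Unit-mean exponential deviate (strictly positive)."""
    return -np.log(1.0 - rand_u01(rng))


# -- propensities ------------------------------------------------------------


@njit(cache=True)
def fill_propensities(
    S, promoter, cnt, mrna, protein, pvec, rvec, variant, alpha_mode, alpha0, props
):
    """Recompute all reaction propensities in place; returns their sum."""
    n = S.size
    if variant == V_TWO_STATE:
        n3 = cnt[3]
        meth = pvec[P_GME_2S] + pvec[P_KME] * n3 / n
        for k in range(n):
            props[k] = meth if S[k] == 0 else 0.0
            props[n + k] = 0.0
        props[2 * n] = pvec[P_FMAX] - (pvec[P_FMAX] - pvec[P_FMIN]) * n3 / n
        props[2 * n + 1] = 0.0
    else:
        beta = pvec[P_BETA]
        rho = pvec[P_RHO]
        gdem = pvec[P_GDEM]
        for k in range(n):
            s = S[k]
            if s == 3:
                props[k] = 0.0
            else:
                # neighbor set: partner histone + the two flanking nucleosomes
                e = 0.0
                if k % 2 == 1:
                    lo, hi = k - 3, k + 2
                else:
                    lo, hi = k - 2, k + 3
                for j in range(max(lo, 0), min(hi, n - 1) + 1):
                    if j == k:
                        continue
                    sj = S[j]
                    if sj == 2:
                        e += rho
                    elif sj == 3:
                        e += 1.0
                if s == 0:
                    props[k] = beta * (pvec[P_G01] + pvec[P_KME01] * e)
                elif s == 1:
                    props[k] = beta * (pvec[P_G12] + pvec[P_KME12] * e)
                else:
                    props[k] = beta * (pvec[P_G23] + pvec[P_KME] * e)
            props[n + k] = gdem if S[k] > 0 else 0.0
        if alpha_mode == 1:
            alpha = protein / rvec[R_MEAN]
        else:
            alpha = alpha0
        p_rep = (cnt[2] + cnt[3]) / n
        if variant == V_BURST:
            k_on = pvec[P_KONMAX] - (p_rep / pvec[P_PT]) * (
                pvec[P_KONMAX] - pvec[P_KONMIN]
            )
            k_on = alpha * max(k_on, pvec[P_KONMIN])
            k_on = min(k_on, pvec[P_KONCAP])
            if promoter == 1:
                props[2 * n] = pvec[P_F0]
                props[2 * n + 1] = pvec[P_KOFF]
            else:
                props[2 * n] = 0.0
                props[2 * n + 1] = k_on
        else:
            f = pvec[P_FMAX] - (p_rep / pvec[P_PT]) * (pvec[P_FMAX] - pvec[P_FMIN])
            f = alpha * max(f, pvec[P_FMIN])
            props[2 * n] = min(f, pvec[P_FCAP])
            props[2 * n + 1] = 0.0
    if alpha_mode == 1:
        props[2 * n + 2] = rvec[R_SR]
        props[2 * n + 3] = rvec[R_DR] * mrna
        props[2 * n + 4] = rvec[R_SP] * mrna
        props[2 * n + 5] = rvec[R_DP] * protein
    else:
        props[2 * n + 2] = 0.0
        props[2 * n + 3] = 0.0
        props[2 * n + 4] = 0.0
        props[2 * n + 5] = 0.0
    total = 0.0
    for k in range(2 * n + 6):
        total += props[k]
    return total


# -- event updates -----------------------------------------------------------


@njit(cache=True)
def apply_transcription(S, origin, age, cnt, rng, pvec, variant):
    """Transcription event: exchange draws first, then demethylation draws
    on non-exchanged histones.  Updates counts; returns (n_ex, n_dem,
    d_exchange_origin)."""
    n = S.size
    n_ex = 0
    n_dem = 0
    d_exch = 0
    if variant == V_TWO_STATE:
        p_dem = pvec[P_PDEM]
        if p_dem > 0.0:
            for k in range(n):
                if S[k] == 3 and rand_u01(rng) < p_dem:
                    S[k] = 0
                    cnt[3] -= 1
                    cnt[0] += 1
                    n_dem += 1
        return n_ex, n_dem, d_exch
    p_ex = pvec[P_PEX]
    p_dem = pvec[P_PDEM]
    exchanged = np.zeros(n, dtype=np.uint8)
    if p_ex > 0.0:
        for k in range(n):
            if rand_u01(rng) < p_ex:
                exchanged[k] = 1
        for k in range(0, n, 2):
            if exchanged[k] == 1 or exchanged[k + 1] == 1:
                for j in range(k, k + 2):
                    exchanged[j] = 1
                    cnt[S[j]] -= 1
                    cnt[0] += 1
                    S[j] = 0
                    if origin[j] == 0:
                        d_exch += 1
                    origin[j] = 1
                    age[j] = 1
                    n_ex += 1
            else:
                exchanged[k] = 0
                exchanged[k + 1] = 0
    if p_dem > 0.0:
        for k in range(n):
            if exchanged[k] == 1 or S[k] == 0:
                continue
            if rand_u01(rng) < p_dem:
                cnt[S[k]] -= 1
                if variant == V_PROC_DEMETH:
                    S[k] = 0
                else:
                    S[k] = S[k] - 1
                cnt[S[k]] += 1
                n_dem += 1
    return n_ex, n_dem, d_exch


@njit(cache=True)
def apply_replication(S, origin, age, cnt, rng, p_replace):
    """Replication: each nucleosome replaced by me0/me0 with probability
    p_replace.  Returns (n_replaced, d_exchange_origin)."""
    n = S.size
    n_rep = 0
    d_exch = 0
    for k in range(0, n, 2):
        if rand_u01(rng) < p_replace:
            for j in range(k, k + 2):
                cnt[S[j]] -= 1
                cnt[0] += 1
                S[j] = 0
                if origin[j] == 1:
                    d_exch -= 1
                origin[j] = 0
                age[j] = 1
                n_rep += 1
    return n_rep, d_exch


@njit(cache=True)
def _flush_samples(S, age, scal_i, sample_times, sample_out, up_to):
    """Record pooled me3 fractions for every pending sample time <= up_to
    (state is piecewise constant, so the current state applies)."""
    n = S.size
    si = scal_i[SI_SAMPLE]
    while si < sample_times.size and sample_times[si] <= up_to:
        n_old = 0
        n_new = 0
        old3 = 0
        new3 = 0
        tot3 = 0
        for k in range(n):
            if S[k] == 3:
                tot3 += 1
            if age[k] == 0:
                n_old += 1
                if S[k] == 3:
                    old3 += 1
            else:
                n_new += 1
                if S[k] == 3:
                    new3 += 1
        sample_out[si, 0] = old3 / n_old if n_old > 0 else 0.0
        sample_out[si, 1] = new3 / n_new if n_new > 0 else 0.0
        sample_out[si, 2] = tot3 / n
        sample_out[si, 3] = n_new / n
        si += 1
    scal_i[SI_SAMPLE] = si


@njit(cache=True)
def _accumulate(acc, cnt, n, n_exch, t0, t1, t_cc, off_thr, on_thr):
    """Time-weighted accumulators over [t0, t1); the interval never spans a
    replication boundary, so a single cycle's last-hour window applies."""
    dt = t1 - t0
    if dt <= 0.0:
        return
    acc[A_TIME] += dt
    acc[A_EXCH] += dt * n_exch / n
    acc[A_ME3] += dt * cnt[3] / n
    n23 = cnt[2] + cnt[3]
    acc[A_ME23] += dt * n23 / n
    cyc_end = (np.floor(t0 / t_cc) + 1.0) * t_cc
    win_lo = cyc_end - LAST_HOUR
    ov = min(t1, cyc_end) - max(t0, win_lo)
    if ov > 0.0:
        acc[A_WINDOW] += ov
        if n23 > off_thr:
            acc[A_OFF] += ov
        elif n23 < on_thr:
            acc[A_ON] += ov


@njit(cache=True)
def _record(
    rec_t, rec_event, rec_n, rec_tx, rec_prom, rec_alpha, rec_exch, rec_prot,
    rec_levels, S,
    scal_i, cnt, t, code, alpha,
):
    r = scal_i[SI_RECLEN]
    if rec_levels.shape[0] > 0:
        for k in range(S.size):
            rec_levels[r, k] = S[k]
    rec_t[r] = t
    rec_event[r] = code
    rec_n[r, 0] = cnt[0]
    rec_n[r, 1] = cnt[1]
    rec_n[r, 2] = cnt[2]
    rec_n[r, 3] = cnt[3]
    rec_tx[r] = scal_i[SI_TX]
    rec_prom[r] = scal_i[SI_PROMOTER]
    rec_alpha[r] = alpha
    rec_exch[r] = scal_i[SI_NEXCH]
    rec_prot[r] = scal_i[SI_PROTEIN]
    scal_i[SI_RECLEN] = r + 1


@njit(cache=True)
def run_kernel(
    S, origin, age, cnt, scal_i, scal_f, rng,
    pvec, rvec, variant, alpha_mode, alpha0,
    t_end, final_rep, stop_mode, stop_level,
    record,
    rec_t, rec_event, rec_n, rec_tx, rec_prom, rec_alpha, rec_exch, rec_prot,
    rec_levels,
    acc, tx_per_cycle, sample_times, sample_out, props,
):
    """Direct Gillespie loop with deterministic replication interrupts.

    Advances the mutable state to t_end (exclusive of the final-boundary
    replication unless final_rep), or until the record buffer fills, or the
    n_me2+n_me3 first-passage threshold is crossed (stop_mode 1: strictly
    above stop_level; 2: strictly below).
    """
    n = S.size
    t_cc = pvec[P_TCC]
    off_thr = 3.0 * n * pvec[P_PT] / 4.0
    on_thr = n * pvec[P_PT] / 4.0
    t = scal_f[0]
    cap = rec_t.size
    while True:
        _flush_samples(S, age, scal_i, sample_times, sample_out, t)
        if record == 1 and scal_i[SI_RECLEN] >= cap:
            scal_f[0] = t
            return 1
        total = fill_propensities(
            S, scal_i[SI_PROMOTER], cnt, scal_i[SI_MRNA], scal_i[SI_PROTEIN],
            pvec, rvec, variant, alpha_mode, alpha0, props,
        )
        if alpha_mode == 1:
            alpha = scal_i[SI_PROTEIN] / rvec[R_MEAN]
        else:
            alpha = alpha0
        next_rep = scal_i[SI_NEXT_REP] * t_cc
        if total > 0.0:
            t_next = t + rand_exp(rng) / total
        else:
            t_next = np.inf
        # replication interrupt: projected reaction time would overshoot
        if next_rep <= t_end and next_rep < t_next:
            if next_rep == t_end and final_rep == 0:
                _flush_samples(S, age, scal_i, sample_times, sample_out, t_end)
                _accumulate(acc, cnt, n, scal_i[SI_NEXCH], t, t_end, t_cc,
                            off_thr, on_thr)
                scal_f[0] = t_end
                return 0
            _flush_samples(S, age, scal_i, sample_times, sample_out, next_rep)
            _accumulate(acc, cnt, n, scal_i[SI_NEXCH], t, next_rep, t_cc,
                        off_thr, on_thr)
            t = next_rep
            _, d_exch = apply_replication(S, origin, age, cnt, rng,
                                          pvec[P_PREPLACE])
            scal_i[SI_NEXCH] += d_exch
            scal_i[SI_NEXT_REP] += 1
            if record == 1:
                _record(rec_t, rec_event, rec_n, rec_tx, rec_prom, rec_alpha,
                        rec_exch, rec_prot, rec_levels, S, scal_i, cnt, t,
                        EV_REPLICATION, alpha)
            n23 = cnt[2] + cnt[3]
            if stop_mode == 1 and n23 > stop_level:
                scal_f[0] = t
                return 3
            if stop_mode == 2 and n23 < stop_level:
                scal_f[0] = t
                return 3
            if t >= t_end:
                scal_f[0] = t
                return 0
            continue
        if t_next >= t_end:
            _flush_samples(S, age, scal_i, sample_times, sample_out, t_end)
            _accumulate(acc, cnt, n, scal_i[SI_NEXCH], t, t_end, t_cc,
                        off_thr, on_thr)
            scal_f[0] = t_end
            return 0
        # ordinary reaction at t_next
        _flush_samples(S, age, scal_i, sample_times, sample_out, t_next)
        _accumulate(acc, cnt, n, scal_i[SI_NEXCH], t, t_next, t_cc,
                    off_thr, on_thr)
        t = t_next
        u = rand_u01(rng) * total
        idx = 0
        csum = props[0]
        while csum <= u and idx < 2 * n + 5:
            idx += 1
            csum += props[idx]
        code = EV_METH
        if idx < n:
            # methylation of histone idx
            cnt[S[idx]] -= 1
            if variant == V_PROC_METH or variant == V_TWO_STATE:
                S[idx] = 3
            else:
                S[idx] = S[idx] + 1
            cnt[S[idx]] += 1
            code = EV_METH
        elif idx < 2 * n:
            k = idx - n
            cnt[S[k]] -= 1
            if variant == V_PROC_DEMETH:
                S[k] = 0
            else:
                S[k] = S[k] - 1
            cnt[S[k]] += 1
            code = EV_DEMETH
        elif idx == 2 * n:
            _, _, d_exch = apply_transcription(S, origin, age, cnt, rng, pvec,
                                               variant)
            scal_i[SI_NEXCH] += d_exch
            scal_i[SI_TX] += 1
            ci = np.int64(t / t_cc)
            if ci < tx_per_cycle.size:
                tx_per_cycle[ci] += 1
            code = EV_TX
        elif idx == 2 * n + 1:
            scal_i[SI_PROMOTER] = 1 - scal_i[SI_PROMOTER]
            code = EV_PROMOTER
        elif idx == 2 * n + 2:
            scal_i[SI_MRNA] += 1
            code = EV_MRNA_BIRTH
        elif idx == 2 * n + 3:
            scal_i[SI_MRNA] -= 1
            code = EV_MRNA_DEATH
        elif idx == 2 * n + 4:
            scal_i[SI_PROTEIN] += 1
            code = EV_PROT_BIRTH
        else:
            scal_i[SI_PROTEIN] -= 1
            code = EV_PROT_DEATH
        if record == 1:
            if alpha_mode == 1:
                alpha = scal_i[SI_PROTEIN] / rvec[R_MEAN]
            _record(rec_t, rec_event, rec_n, rec_tx, rec_prom, rec_alpha,
                    rec_exch, rec_prot, rec_levels, S, scal_i, cnt, t, code,
                    alpha)
        if code == EV_METH or code == EV_DEMETH or code == EV_TX:
            n23 = cnt[2] + cnt[3]
            if stop_mode == 1 and n23 > stop_level:
                scal_f[0] = t
                return 3
            if stop_mode == 2 and n23 < stop_level:
                scal_f[0] = t
                return 3


@njit(cache=True)
def regulator_kernel(state, rng, rvec, t_end, record, rec_t, rec_m, rec_p, acc):
    """SSA for the two-stage (mRNA -> protein) birth-death regulator alone.

    state = [t, mRNA, protein] (floats; counts are integers in value).
    acc accumulates [total time, integral alpha dt, integral alpha^2 dt,
    integral protein dt, integral protein^2 dt].  Returns 0 at t_end or 1
    when the record buffer fills.
    """
    t = state[0]
    m = state[1]
    p = state[2]
    mean = rvec[R_MEAN]
    cap = rec_t.size
    r = 0
    if record == 1:
        # resume position encoded by first NaN slot
        while r < cap and not np.isnan(rec_t[r]):
            r += 1
    while t < t_end:
        a0 = rvec[R_SR]
        a1 = rvec[R_DR] * m
        a2 = rvec[R_SP] * m
        a3 = rvec[R_DP] * p
        total = a0 + a1 + a2 + a3
        if total <= 0.0:
            break
        t_next = t + rand_exp(rng) / total
        if t_next > t_end:
            t_next = t_end
            dt = t_next - t
            alpha = p / mean
            acc[0] += dt
            acc[1] += dt * alpha
            acc[2] += dt * alpha * alpha
            acc[3] += dt * p
            acc[4] += dt * p * p
            t = t_next
            break
        dt = t_next - t
        alpha = p / mean
        acc[0] += dt
        acc[1] += dt * alpha
        acc[2] += dt * alpha * alpha
        acc[3] += dt * p
        acc[4] += dt * p * p
        t = t_next
        u = rand_u01(rng) * total
        if u < a0:
            m += 1.0
        elif u < a0 + a1:
            m -= 1.0
        elif u < a0 + a1 + a2:
            p += 1.0
        else:
            p -= 1.0
        if record == 1:
            if r >= cap:
                state[0] = t
                state[1] = m
                state[2] = p
                return 1
            rec_t[r] = t
            rec_m[r] = m
            rec_p[r] = p
            r += 1
    state[0] = t
    state[1] = m
    state[2] = p
    return 0
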