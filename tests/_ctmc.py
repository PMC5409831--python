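"""Exact continuous-time Markov chain oracle for tiny systems.

Enumerates all 4^N methylation configurations, assembles the generator
matrix from the reference propensity functions (transcription is a compound
event: every methylated histone independently loses one methyl group with
probability p_dem), and solves for the stationary distribution by
null-space.  Deliberately independent of the Gillespie engine: the only
shared code is the propensity definitions themselves, which is what the
engine is being checked against.
"""

import itertools

import numpy as np
from scipy.linalg import null_space

from prc2mem import chromatin as C


def state_id(levels, n):
    return int(sum(int(l) * 4**i for i, l in enumerate(levels)))


def build_generator(params):
    n = params.n_histones
    n_states = 4**n
    Q = np.zeros((n_states, n_states))
    for s in itertools.product(range(4), repeat=n):
        sid = state_id(s, n)
        st = C.ChromatinState.uniform(n, 0)
        st.levels[:] = s
        for i in range(1, n + 1):
            r = C.methylation_propensity(st, i, params)
            if r > 0:
                s2 = list(s)
                s2[i - 1] += 1
                Q[sid, state_id(s2, n)] += r
            r = C.noisy_demethylation_propensity(st, i, params)
            if r > 0:
                s2 = list(s)
                s2[i - 1] -= 1
                Q[sid, state_id(s2, n)] += r
        f = C.transcription_propensity(st, params)
        eligible = [i for i in range(n) if s[i] > 0]
        for hits in itertools.product((0, 1), repeat=len(eligible)):
            if not any(hits):
                continue
            prob = 1.0
            for h in hits:
                prob *= params.p_dem if h else 1.0 - params.p_dem
            s2 = list(s)
            for i, h in zip(eligible, hits):
                if h:
                    s2[i] -= 1
            Q[sid, state_id(s2, n)] += f * prob
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(Q):
    ns = null_space(Q.T)
    assert ns.shape[1] == 1, "generator must have a unique stationary law"
    pi = ns[:, 0]
    pi = pi / pi.sum()
    assert (pi > -1e-12).all()
    return np.clip(pi, 0.0, None)


def occupancy_from_trajectory(traj, n, t_burn):
    """Time-weighted occupancy of each configuration, discarding t < t_burn."""
    sids = (traj.levels.astype(np.int64) * (4 ** np.arange(n))).sum(axis=1)
    starts = np.maximum(traj.t, t_burn)
    ends = np.empty_like(traj.t)
    ends[:-1] = traj.t[1:]
    ends[-1] = traj.t_final
    ends = np.maximum(ends, t_burn)
    w = ends - starts
    return np.bincount(sids, weights=w, minlength=4**n) / (traj.t_final - t_burn)
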