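"""Chromatin state and reaction rules of the H3K27 methylation model.

The locus is a row of N histones (N even); nucleosomes are the adjacent pairs
(1,2), (3,4), ... in 1-based numbering.  Each histone carries a methylation
level in {me0, me1, me2, me3}.  PRC2 adds methyl groups one at a time, with
rates stimulated by me2/me3 marks on the five histones of the neighboring
nucleosomes (including the partner histone); transcription removes methyl
groups and exchanges whole nucleosomes; DNA replication randomly replaces
half the nucleosomes with unmethylated ones.

These are the readable reference implementations; the Gillespie engine has a
numerically identical compiled path (see `_kernels`), which the test suite
holds bit-identical to this module.

Internally histones are 0-based numpy arrays; the public `neighbor_indices`
follows the 1-based convention of the model definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams

# methylation levels
ME0, ME1, ME2, ME3 = 0, 1, 2, 3
# histone origin labels (H3.1-like vs H3.3-like bookkeeping)
REPLICATION_DEPOSITED, EXCHANGE_DEPOSITED = 0, 1
# histone age labels (SILAC bookkeeping)
OLD, NEW = 0, 1
# promoter flags (promoter-switching variant)
CLOSED, OPEN = 0, 1


@dataclass
class ChromatinState:
    """Mutable per-histone state of the simulated locus.

    Attributes
    ----------
    levels : (N,) int8 array of methylation levels 0..3.
    origin : (N,) int8 array; 0 replication-deposited, 1 exchange-deposited.
    age : (N,) int8 array; 0 old, 1 new (SILAC labeling).
    promoter : 0 closed / 1 open (meaningful in the bursty variant only).
    t : simulation clock, seconds.
    tx_count : cumulative number of transcription events.
    """

    levels: np.ndarray
    origin: np.ndarray
    age: np.ndarray
    promoter: int = OPEN
    t: float = 0.0
    tx_count: int = 0

    @classmethod
    def uniform(cls, n_histones: int, level: int) -> "ChromatinState":
        if n_histones < 2 or n_histones % 2:
            raise ValueError("n_histones must be a positive even integer")
        if level not in (ME0, ME1, ME2, ME3):
            raise ValueError("level must be in 0..3")
        return cls(
            levels=np.full(n_histones, level, dtype=np.int8),
            origin=np.zeros(n_histones, dtype=np.int8),
            age=np.zeros(n_histones, dtype=np.int8),
        )

    @property
    def n(self) -> int:
        return self.levels.size

    def counts(self) -> np.ndarray:
        """Histone counts by methylation level, length-4 int array."""
        return np.bincount(self.levels, minlength=4).astype(np.int64)

    def repressive_fraction(self) -> float:
        """Proportion of me2/me3-marked histones, P_me2/me3."""
        return float(np.count_nonzero(self.levels >= ME2)) / self.n

    def copy(self) -> "ChromatinState":
        return ChromatinState(
            levels=self.levels.copy(),
            origin=self.origin.copy(),
            age=self.age.copy(),
            promoter=self.promoter,
            t=self.t,
            tx_count=self.tx_count,
        )

    def validate(self) -> None:
        n = self.n
        if n % 2 or any(a.shape != (n,) for a in (self.origin, self.age)):
            raise ValueError("inconsistent state arrays")
        if self.levels.min() < ME0 or self.levels.max() > ME3:
            raise ValueError("methylation level out of range")


def neighbor_indices(i: int, n_histones: int) -> tuple[int, ...]:
    """Neighboring-histone set M_i (1-based, as in the model definition).

    For even i: {i-3, i-2, i-1, i+1, i+2}; for odd i: {i-2, i-1, i+1, i+2,
    i+3}; truncated to [1, N] — histones outside the simulated region are not
    considered, so boundary nucleosomes have one-sided recruitment.  The set
    always contains the partner histone on the same nucleosome and the four
    histones of the two flanking nucleosomes.
    """
    if not 1 <= i <= n_histones:
        raise ValueError(f"histone index {i} out of range 1..{n_histones}")
    if i % 2 == 0:
        raw = (i - 3, i - 2, i - 1, i + 1, i + 2)
    else:
        raw = (i - 2, i - 1, i + 1, i + 2, i + 3)
    return tuple(j for j in raw if 1 <= j <= n_histones)


def feedback_sum(state: ChromatinState, i: int, rho_me2: float) -> float:
    """Allosteric activation E_i from me2/me3 marks on neighboring histones.

    E_i = sum over j in M_i of (rho_me2 * [S_j == me2] + [S_j == me3]).
    """
    e = 0.0
    for j in neighbor_indices(i, state.n):
        s = state.levels[j - 1]
        if s == ME2:
            e += rho_me2
        elif s == ME3:
            e += 1.0
    return e


def methylation_propensity(
    state: ChromatinState, i: int, params: ModelParams
) -> float:
    """Propensity of adding one methyl group at histone i (1-based).

    beta * (gamma_level + k_level * E_i) for the histone's current level;
    zero for fully methylated (me3) histones.
    """
    s = state.levels[i - 1]
    if s == ME3:
        return 0.0
    e = feedback_sum(state, i, params.rho_me2)
    if s == ME0:
        return params.beta * (params.gamma_me0_1 + params.k_me0_1 * e)
    if s == ME1:
        return params.beta * (params.gamma_me1_2 + params.k_me1_2 * e)
    return params.beta * (params.gamma_me2_3 + params.k_me * e)


def noisy_demethylation_propensity(
    state: ChromatinState, i: int, params: ModelParams
) -> float:
    """Propensity of noisy (transcription-independent) loss of one methyl
    group at histone i; gamma_dem for me1/me2/me3, zero for me0."""
    return params.gamma_dem if state.levels[i - 1] > ME0 else 0.0


def transcription_propensity(
    state: ChromatinState, params: ModelParams, alpha: float | None = None
) -> float:
    """Transcription initiation rate f given the current chromatin state.

    f falls linearly with the me2/me3 proportion P, saturating at f_min once
    P reaches the threshold P_T; the trans-activation multiplier alpha scales
    the whole rate, subject to the absolute cap f <= f_cap.
    """
    if alpha is None:
        alpha = params.alpha
    p = state.repressive_fraction()
    f = params.f_max - (p / params.p_t) * (params.f_max - params.f_min)
    return min(alpha * max(f, params.f_min), params.f_cap)


def apply_transcription_event(
    state: ChromatinState,
    params: ModelParams,
    rng: np.random.Generator,
    processive_demethylation: bool = False,
) -> dict[str, int]:
    """One passage of Pol II: histone exchange then demethylation, in place.

    Each histone draws exchange with probability p_ex; a hit replaces BOTH
    histones of its nucleosome with me0 (origin exchange-deposited, age new).
    Each remaining methylated histone then loses one methyl group with
    probability p_dem (or all of them, in the processive-demethylation
    variant).  Exchange is resolved first so that a replaced histone is not
    also counted as demethylated, keeping the mean per-histone loss rate
    through exchange at ~2*f*p_ex.
    """
    n = state.n
    exchanged = np.zeros(n, dtype=bool)
    if params.p_ex > 0:
        hits = rng.random(n) < params.p_ex
        for k in range(0, n, 2):
            if hits[k] or hits[k + 1]:
                exchanged[k] = exchanged[k + 1] = True
        state.levels[exchanged] = ME0
        state.origin[exchanged] = EXCHANGE_DEPOSITED
        state.age[exchanged] = NEW
    n_dem = 0
    if params.p_dem > 0:
        for k in range(n):
            if exchanged[k] or state.levels[k] == ME0:
                continue
            if rng.random() < params.p_dem:
                state.levels[k] = (
                    ME0 if processive_demethylation else state.levels[k] - 1
                )
                n_dem += 1
    state.tx_count += 1
    return {"n_exchanged": int(exchanged.sum()), "n_demethylated": n_dem}


def apply_replication(
    state: ChromatinState, params: ModelParams, rng: np.random.Generator
) -> int:
    """DNA replication: random histone dilution, in place.

    Each nucleosome is independently replaced with a new me0/me0 nucleosome
    (origin replication-deposited, age new) with probability
    1 - replication_survival; surviving nucleosomes keep their methylation.
    Returns the number of histones replaced.
    """
    n_replaced = 0
    p_replace = 1.0 - params.replication_survival
    for k in range(0, state.n, 2):
        if rng.random() < p_replace:
            state.levels[k : k + 2] = ME0
            state.origin[k : k + 2] = REPLICATION_DEPOSITED
            state.age[k : k + 2] = NEW
            n_replaced += 2
    return n_replaced


def processive_methylation_update(state: ChromatinState, i: int) -> None:
    """Processive-methylation variant: a selected methylation reaction
    converts histone i (1-based) directly to me3."""
    state.levels[i - 1] = ME3


def processive_demethylation_update(state: ChromatinState, i: int) -> None:
    """Processive-demethylation variant: a selected (noisy) demethylation
    converts histone i (1-based) directly to me0."""
    state.levels[i - 1] = ME0


# -- two-state variant (me0/me3 only, long-range mean-field feedback) -------


def two_state_methylation_propensity(
    state: ChromatinState, i: int, params: ModelParams
) -> float:
    """Per-histone me0->me3 propensity of the two-state model:
    gamma_me + (k_me/N) * n_me3 for me0 histones, zero otherwise."""
    if state.levels[i - 1] != ME0:
        return 0.0
    n_me3 = int(np.count_nonzero(state.levels == ME3))
    gamma_me = params.k_me / 20.0
    return gamma_me + params.k_me * n_me3 / state.n


def two_state_transcription_propensity(
    state: ChromatinState, params: ModelParams
) -> float:
    """Transcription propensity of the two-state model: linear in the me3
    count, from f_max (all me0) down to f_min (all me3); no threshold, cap
    or trans-activation applies to this variant."""
    n_me3 = int(np.count_nonzero(state.levels == ME3))
    return params.f_max - (params.f_max - params.f_min) * n_me3 / state.n


def two_state_propensities(
    state: ChromatinState, params: ModelParams
) -> np.ndarray:
    """All 2N+1 propensities of the two-state variant in engine order:
    N methylations, N (zero) demethylation slots, transcription."""
    if np.any((state.levels != ME0) & (state.levels != ME3)):
        raise ValueError("two-state variant requires levels in {me0, me3}")
    n = state.n
    props = np.zeros(2 * n + 1)
    for i in range(1, n + 1):
        props[i - 1] = two_state_methylation_propensity(state, i, params)
    props[2 * n] = two_state_transcription_propensity(state, params)
    return props


def two_state_apply_transcription(
    state: ChromatinState, params: ModelParams, rng: np.random.Generator
) -> int:
    """Two-state transcription event: each me3 histone reverts to me0 with
    probability p_dem.  Returns the number demethylated."""
    n_dem = 0
    for k in range(state.n):
        if state.levels[k] == ME3 and rng.random() < params.p_dem:
            state.levels[k] = ME0
            n_dem += 1
    state.tx_count += 1
    return n_dem


def burst_k_on(
    state: ChromatinState,
    params: ModelParams,
    burst: "DerivedBurstParams",
    alpha: float | None = None,
) -> float:
    """Promoter opening rate k_on(alpha, P) of the bursty variant.

    Mirrors the main model's f: linear decrease with P/P_T from k_on_max to
    k_on_min, scaled by alpha and capped at k_on_cap so that the mean
    initiation rate f_0 * P_open never exceeds 1/60 s^-1.
    """
    if alpha is None:
        alpha = params.alpha
    p = state.repressive_fraction()
    k = burst.k_on_max - (p / params.p_t) * (burst.k_on_max - burst.k_on_min)
    return min(alpha * max(k, burst.k_on_min), burst.k_on_cap)


# re-export for type hints
from .params import DerivedBurstParams  # noqa: E402  (cycle-free tail import)
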