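"""Trans-activation inputs alpha(t).

The trans-regulatory environment of the gene enters the model as a
multiplicative factor alpha on the transcription initiation rate: alpha = 1
is neutral, alpha > 1 activating, alpha < 1 repressive.  Three forms are
supported:

* a constant (just pass a float to the engine);
* a `StepProtocol` — equilibrate at one value, then switch permanently;
* a `RegulatorParams` two-stage birth-death gene-expression model
  (DNA -> mRNA -> protein, both species decaying linearly), giving a
  fluctuating alpha(t) = r(t)/<r> where r(t) is the protein copy number.

For the stochastic regulator the burst size b = s_P/d_R (mean proteins made
per mRNA lifetime) is the single noise dial: synthesis rates are derived
from (b, mean_protein), so the stationary protein mean is independent of b
while the coefficient of variation grows with it — approximately
CV^2 = (1 + b/(1 + d_P/d_R)) / <r>.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels as K

HOUR = 3600.0

#: Burst sizes used for the noise-filtering scans (CV from ~0 up to ~1).
B_GRID = (1, 2, 9, 23, 43, 71, 106, 149, 200, 259, 327, 404, 489, 583,
          687, 799, 922, 1053, 1195)


@dataclass(frozen=True)
class StepProtocol:
    """Permanent step change in alpha after equilibration.

    The engine equilibrates for `SimulationConfig.equilibration_cycles`
    (default 5) at `alpha_before`, then switches to `alpha_after` for the
    measurement phase.
    """

    alpha_before: float = 1.0
    alpha_after: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_before < 0 or self.alpha_after < 0:
            raise ValueError("alpha values must be nonnegative")


@dataclass(frozen=True)
class RegulatorParams:
    """Two-stage stochastic regulator of protein copy number r(t).

    Rates are given per hour (the conventional units for these processes)
    and converted to s^-1 internally.  Synthesis rates are derived:
    s_R = d_P * mean_protein / b and s_P = d_R * b, which fixes the
    stationary means <mRNA> = s_R/d_R and <protein> = mean_protein.
    """

    d_r: float = 0.5  # mRNA decay, hr^-1
    d_p: float = 1.0 / 12.0  # protein decay, hr^-1
    b: float = 1.0  # burst size s_P/d_R, dimensionless
    mean_protein: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("d_r", "d_p", "b", "mean_protein"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def s_r(self) -> float:
        """mRNA synthesis rate, hr^-1."""
        return self.d_p * self.mean_protein / self.b

    @property
    def s_p(self) -> float:
        """Protein synthesis rate per mRNA, hr^-1."""
        return self.d_r * self.b

    # internal engine units (s^-1)
    @property
    def s_r_per_s(self) -> float:
        return self.s_r / HOUR

    @property
    def d_r_per_s(self) -> float:
        return self.d_r / HOUR

    @property
    def s_p_per_s(self) -> float:
        return self.s_p / HOUR

    @property
    def d_p_per_s(self) -> float:
        return self.d_p / HOUR

    @property
    def mean_mrna(self) -> float:
        return self.s_r / self.d_r

    def stationary_counts(self) -> tuple[int, int]:
        """Integer initial copy numbers at the deterministic stationary
        means (initialization convention; avoids startup transients)."""
        return round(self.mean_mrna), round(self.mean_protein)

    def cv_analytic(self) -> float:
        """Closed-form stationary CV of the protein count (two-stage
        birth-death noise formula)."""
        cv2 = (1.0 + self.b / (1.0 + self.d_p / self.d_r)) / self.mean_protein
        return math.sqrt(cv2)

    def to_rvec(self) -> np.ndarray:
        rvec = np.zeros(K.N_RVEC)
        rvec[K.R_SR] = self.s_r_per_s
        rvec[K.R_DR] = self.d_r_per_s
        rvec[K.R_SP] = self.s_p_per_s
        rvec[K.R_DP] = self.d_p_per_s
        rvec[K.R_MEAN] = self.mean_protein
        return rvec


def regulator_propensities(
    reg: RegulatorParams, mrna: int, protein: int
) -> np.ndarray:
    """The four reaction propensities (s^-1) at copy numbers (mrna, protein):
    mRNA birth, mRNA death, protein birth, protein death."""
    if mrna < 0 or protein < 0:
        raise ValueError("copy numbers must be nonnegative")
    return np.array(
        [
            reg.s_r_per_s,
            reg.d_r_per_s * mrna,
            reg.s_p_per_s * mrna,
            reg.d_p_per_s * protein,
        ]
    )


def alpha_of(r: float, mean_protein: float) -> float:
    """alpha = r / <r>; zero is allowed transiently when r = 0."""
    if mean_protein <= 0:
        raise ValueError("mean_protein must be positive")
    return r / mean_protein


@dataclass
class AlphaTrace:
    """Recorded alpha(t) trajectory with time-weighted summary statistics."""

    t: np.ndarray
    mrna: np.ndarray
    protein: np.ndarray
    mean_alpha: float
    cv: float
    mean_protein: float
    duration_s: float
    warning: str | None = None

    @property
    def alpha(self) -> np.ndarray:
        return self.protein / self.mean_protein

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.t,
                "mRNA": self.mrna,
                "protein": self.protein,
                "alpha": self.alpha,
            }
        )

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def simulate_regulator(
    reg: RegulatorParams,
    duration_hr: float,
    seed: int,
    record: bool = False,
    burn_in_hr: float = 0.0,
) -> AlphaTrace:
    """Simulate the regulator alone and return alpha(t) statistics.

    The chain starts at the stationary means; an optional burn-in is
    discarded before statistics accumulate.  The CV is time-weighted.
    """
    rvec = reg.to_rvec()
    m0, p0 = reg.stationary_counts()
    state = np.array([0.0, float(m0), float(p0)])
    rng = K.seed_state(seed)
    acc = np.zeros(5)
    nan = np.full(0, np.nan)
    if burn_in_hr > 0:
        K.regulator_kernel(state, rng, rvec, burn_in_hr * HOUR, 0,
                           nan, nan, nan, np.zeros(5))
    t_end = state[0] + duration_hr * HOUR
    if record:
        chunks: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        cap = 1 << 16
        while True:
            rec_t = np.full(cap, np.nan)
            rec_m = np.full(cap, np.nan)
            rec_p = np.full(cap, np.nan)
            code = K.regulator_kernel(state, rng, rvec, t_end, 1,
                                      rec_t, rec_m, rec_p, acc)
            k = np.count_nonzero(~np.isnan(rec_t))
            chunks.append((rec_t[:k], rec_m[:k], rec_p[:k]))
            if code == 0:
                break
        t = np.concatenate([c[0] for c in chunks])
        m = np.concatenate([c[1] for c in chunks])
        p = np.concatenate([c[2] for c in chunks])
    else:
        K.regulator_kernel(state, rng, rvec, t_end, 0, nan, nan, nan, acc)
        t = m = p = np.empty(0)
    total = acc[0]
    mean_a = acc[1] / total if total > 0 else float("nan")
    var_a = acc[2] / total - mean_a**2 if total > 0 else float("nan")
    cv = math.sqrt(max(var_a, 0.0)) / mean_a if mean_a else float("nan")
    warning = None
    # a stable CV estimate needs many protein lifetimes
    if duration_hr < 50.0 / reg.d_p:
        warning = (
            f"duration {duration_hr:g} hr is short relative to the protein "
            f"lifetime {1.0 / reg.d_p:g} hr; CV estimate may be unstable"
        )
    return AlphaTrace(
        t=t, mrna=m, protein=p, mean_alpha=mean_a, cv=cv,
        mean_protein=reg.mean_protein, duration_s=duration_hr * HOUR,
        warning=warning,
    )


def noise_series(
    b: float,
    duration_hr: float = 5000.0,
    seed: int = 0,
    d_r: float = 0.5,
    d_p: float = 1.0 / 12.0,
    mean_protein: float = 1000.0,
    record: bool = False,
) -> AlphaTrace:
    """alpha(t) trace and its time-weighted CV for a given burst size b."""
    reg = RegulatorParams(d_r=d_r, d_p=d_p, b=b, mean_protein=mean_protein)
    return simulate_regulator(reg, duration_hr, seed, record=record)
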