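"""Model parameters for the PRC2 target-gene chromatin model.

All rates are stored in s^-1 (per histone where applicable); probabilities are
dimensionless per-histone, per-transcription-event quantities.  Derived
quantities (the 9:6:1 substrate preference of PRC2, the 5% noise floors, the
noisy demethylation rate gamma_dem, the transcriptional fold change F) are
always recomputed from the primitive fields and never serialized.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Any

import yaml

#: Absolute cap on the transcription initiation rate (s^-1): at most one
#: initiation per minute even under strong trans-activation.
F_CAP = 1.0 / 60.0

#: Ratio of PRC2 catalytic activity on me0 : me1 : me2 substrates.
SUBSTRATE_RATIO = (9.0, 6.0, 1.0)

#: Noise floors (background PRC2 activity) are 5% of the stimulated rates.
NOISE_FRACTION = 1.0 / 20.0

VARIANTS = (
    "main",
    "two_state",
    "processive_methylation",
    "processive_demethylation",
    "promoter_switching",
)


@dataclass(frozen=True)
class ModelParams:
    """Rate constants and system constants of the chromatin model.

    Defaults are the fitted parameter set: a 60-histone locus (~5-6 kb),
    22 hr cell cycle, k_me = 8e-6 histone^-1 s^-1 (~0.6 per histone per cell
    cycle), p_dem = 4e-3 and p_ex = 1e-3 per histone per transcription event,
    f in [1e-4, 4e-3] s^-1 (fold change F = 40) and repression saturating at
    a me2/me3 proportion of P_T = 1/3.
    """

    n_histones: int = 60
    t_cc: float = 22.0 * 3600.0  # cell-cycle duration, seconds
    beta: float = 1.0  # relative local PRC2 activity
    k_me: float = 8e-6  # me2->me3 stimulated rate, histone^-1 s^-1
    rho_me2: float = 0.1  # me2 feedback efficiency relative to me3
    f_min: float = 1e-4  # minimum transcription initiation rate, s^-1
    f_max: float = 4e-3  # maximum transcription initiation rate, s^-1
    p_t: float = 1.0 / 3.0  # me2/me3 proportion at which repression saturates
    p_dem: float = 4e-3  # P(demethylation) per histone per transcription
    p_ex: float = 1e-3  # P(exchange) per histone per transcription
    alpha: float = 1.0  # trans-activation multiplier
    f_cap: float = F_CAP
    replication_survival: float = 0.5  # P(nucleosome retained) at replication

    def __post_init__(self) -> None:
        if self.n_histones < 2 or self.n_histones % 2:
            raise ValueError("n_histones must be a positive even integer")
        for name in ("t_cc", "beta", "k_me", "rho_me2", "alpha", "f_cap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 < self.f_min <= self.f_max:
            raise ValueError("require 0 < f_min <= f_max")
        if not 0 < self.p_t <= 1:
            raise ValueError("require 0 < p_t <= 1")
        for name in ("p_dem", "p_ex", "replication_survival"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability in [0, 1]")

    # -- derived rates -----------------------------------------------------

    @property
    def k_me0_1(self) -> float:
        """Stimulated me0->me1 rate (9x the me2->me3 rate)."""
        return SUBSTRATE_RATIO[0] * self.k_me

    @property
    def k_me1_2(self) -> float:
        """Stimulated me1->me2 rate (6x the me2->me3 rate)."""
        return SUBSTRATE_RATIO[1] * self.k_me

    @property
    def gamma_me0_1(self) -> float:
        return NOISE_FRACTION * self.k_me0_1

    @property
    def gamma_me1_2(self) -> float:
        return NOISE_FRACTION * self.k_me1_2

    @property
    def gamma_me2_3(self) -> float:
        return NOISE_FRACTION * self.k_me

    @property
    def gamma_dem(self) -> float:
        """Transcription-independent noisy demethylation rate, f_min * p_dem.

        Chosen so that in the maximally repressed state demethylation occurs
        through transcription-dependent and -independent routes with equal
        probability; total repressed-state noisy demethylation is then 5% of
        the maximal transcription-coupled rate.
        """
        return self.f_min * self.p_dem

    @property
    def fold_change(self) -> float:
        """F = f_max / f_min, transcriptional fold change."""
        return self.f_max / self.f_min

    @property
    def off_threshold(self) -> float:
        """OFF state requires n_me2 + n_me3 strictly above 3*N*P_T/4."""
        return 3.0 * self.n_histones * self.p_t / 4.0

    @property
    def on_threshold(self) -> float:
        """ON state requires n_me2 + n_me3 strictly below N*P_T/4."""
        return self.n_histones * self.p_t / 4.0

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **kwargs: Any) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        return cls.from_dict(json.loads(text))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelParams":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class BurstParams:
    """Promoter-switching (bursty transcription) parameters.

    The promoter toggles between closed and open states with rates k_on and
    k_off; transcription initiates at rate f_0 only while open.  Given
    (k_on_max, k_off) the remaining rates are derived so that the
    promoter-switching model matches the main model's transcriptional fold
    change F = f_max/f_min = 40 and its mean repressed-state rate f_min:

      k_on_min = k_on_max * k_off / ((F-1)*k_on_max + F*k_off)
      f_0      = f_min * (k_on_min + k_off) / k_on_min
      k_on_cap = k_off / (60 s * f_0 - 1)  (only when f_0 > 1/60 s^-1)
    """

    k_on_max: float = 5e-4  # s^-1, promoter opening rate when fully active
    k_off: float = 5e-3  # s^-1, promoter closing rate

    def __post_init__(self) -> None:
        if self.k_on_max <= 0 or self.k_off <= 0:
            raise ValueError("k_on_max and k_off must be positive")
        if self.k_on_max > self.k_off:
            # Otherwise the promoter is effectively always open in the
            # repressed state and k_on cannot up-regulate transcription.
            raise ValueError("analysis restricted to k_on_max <= k_off")

    def derive(self, params: ModelParams) -> "DerivedBurstParams":
        F = params.fold_change
        k_on_min = self.k_on_max * self.k_off / (
            (F - 1.0) * self.k_on_max + F * self.k_off
        )
        f_0 = params.f_min * (k_on_min + self.k_off) / k_on_min
        if f_0 > params.f_cap:
            k_on_cap = self.k_off / (f_0 / params.f_cap - 1.0)
        else:
            k_on_cap = float("inf")
        return DerivedBurstParams(
            k_on_max=self.k_on_max,
            k_off=self.k_off,
            k_on_min=k_on_min,
            f_0=f_0,
            k_on_cap=k_on_cap,
        )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "BurstParams":
        return cls(**d)


@dataclass(frozen=True)
class DerivedBurstParams:
    """BurstParams plus the derived rates (never serialized)."""

    k_on_max: float
    k_off: float
    k_on_min: float
    f_0: float
    k_on_cap: float

    def fold_change(self) -> float:
        """Maximal fold change in mean transcription rate, open-state
        occupancy at k_on_max versus k_on_min."""
        return (
            self.k_on_max
            * (self.k_on_min + self.k_off)
            / (self.k_on_min * (self.k_on_max + self.k_off))
        )


def burst_derived_params(
    k_on_max: float, k_off: float, f_min: float = 1e-4
) -> DerivedBurstParams:
    """Derive (k_on_min, f_0, k_on_cap) from (k_on_max, k_off, f_min)."""
    params = ModelParams(f_min=f_min)
    return BurstParams(k_on_max=k_on_max, k_off=k_off).derive(params)


#: The fitted parameter set used throughout the analysis protocols.
FITTED = ModelParams()

#: A demethylation-biased parameter set (monostable active state).
DEMETHYLATION_BIASED = ModelParams(k_me=1e-4, p_dem=0.1)
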