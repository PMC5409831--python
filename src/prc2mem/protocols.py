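"""Desk-scale versions of the headline simulation protocols.

Each function reproduces one of the quantitative experiments at reduced
replicate counts (the full-scale protocols run thousands of replicates):

* `censored_first_passage_cycles` — chromatin-state lifetimes at fixed
  trans-activation, censored means from both uniform starts.
* `fmax_bistability_threshold` — the doubling-series scan locating the
  smallest transcriptional dynamic range that supports bistability.
* `noise_filtering_contrast` — combined first passage FP under low- vs
  high-noise regulator input for slow and fast chromatin dynamics.
* `regulator_stationary_mean` — time-weighted mean protein count of the
  two-stage regulator.

The bistability scan runs under the untruncated (linear) transcription law
(P_T = 1), matching the stage of the analysis at which the dynamic-range
requirement was established; all other protocols use the fitted threshold
P_T = 1/3.
"""

from __future__ import annotations

import numpy as np

from . import engine, metrics
from .params import BurstParams, ModelParams
from .trans_input import RegulatorParams

#: log grids bracketing the fitted point and the balanced fast pairs
SCAN_K_ME = (2e-6, 8e-6, 3.2e-5, 1.28e-4)
SCAN_P_DEM = (1e-3, 4e-3, 1.6e-2, 6.4e-2, 0.256)
#: doubling series of the maximal initiation rate, in multiples of f_min
SCAN_F_MAX_FOLD = (2, 4, 8, 16, 32, 64)

#: fast-dynamics pair used for the noise-filtering contrast
FAST_K_ME = 4e-5
FAST_P_DEM = 0.2


def censored_first_passage_cycles(
    seed: int,
    params: ModelParams | None = None,
    n_replicates: int = 50,
    censor_cycles: int = 400,
    variant: str = "main",
    burst: BurstParams | None = None,
    alpha: float = 1.0,
) -> dict[str, float]:
    """Censored-mean first-passage times (cell cycles) from both uniform
    starts at constant alpha."""
    if params is None:
        params = ModelParams()
    me0 = engine.first_passage_ensemble(
        params, "uniform_me0", n_replicates, censor_cycles, seed,
        variant=variant, burst=burst, alpha=alpha,
    )
    me3 = engine.first_passage_ensemble(
        params, "uniform_me3", n_replicates, censor_cycles,
        seed + n_replicates, variant=variant, burst=burst, alpha=alpha,
    )
    return {
        "t_fp_me0_cycles": float(me0.mean() / params.t_cc),
        "t_fp_me3_cycles": float(me3.mean() / params.t_cc),
        "n_replicates": n_replicates,
        "censor_cycles": censor_cycles,
    }


def fmax_bistability_threshold(
    seed: int,
    replicates_per_state: int = 40,
    n_cycles: int = 20,
    f_min: float = 1e-4,
    k_me_grid=SCAN_K_ME,
    p_dem_grid=SCAN_P_DEM,
    f_max_folds=SCAN_F_MAX_FOLD,
    b_threshold: float = 0.5,
) -> dict:
    """Smallest f_max in a doubling series at which any (k_me, p_dem) grid
    point achieves B above `b_threshold`.

    Runs the 50-cycle-style scan at reduced scale: both uniform starts,
    last-hour-of-cycle occupancies pooled across replicates, untruncated
    transcription law (P_T = 1).
    """
    max_b = []
    threshold = None
    for fi, fold in enumerate(f_max_folds):
        f_max = fold * f_min
        best = 0.0
        for ki, k_me in enumerate(k_me_grid):
            for pi, p_dem in enumerate(p_dem_grid):
                params = ModelParams(
                    k_me=k_me, p_dem=p_dem, f_min=f_min, f_max=f_max,
                    p_t=1.0,
                )
                res = engine.bistability_ensemble(
                    params, replicates_per_state, n_cycles,
                    seed + 10_000 * fi + 1_000 * ki + 100 * pi,
                )
                best = max(best, res["b"])
        max_b.append(best)
        if threshold is None and best > b_threshold:
            threshold = f_max
    return {
        "f_max_threshold": threshold,
        "f_max_grid": [fold * f_min for fold in f_max_folds],
        "max_b": max_b,
        "n_simulations": 2 * replicates_per_state * len(k_me_grid)
        * len(p_dem_grid) * len(f_max_folds),
    }


def _fp_under_regulator(
    params: ModelParams, b: float, n_replicates: int, n_cycles: int,
    seed: int,
) -> float:
    reg = RegulatorParams(b=b)
    me0 = engine.first_passage_ensemble(
        params, "uniform_me0", n_replicates, n_cycles, seed, regulator=reg,
    )
    me3 = engine.first_passage_ensemble(
        params, "uniform_me3", n_replicates, n_cycles, seed + n_replicates,
        regulator=reg,
    )
    return metrics.first_passage(me0, me3, n_cycles * params.t_cc).fp


def noise_filtering_contrast(
    seed: int,
    n_replicates: int = 30,
    n_cycles: int = 20,
    b_low: float = 1.0,
    b_high: float = 1000.0,
) -> dict[str, float]:
    """Combined first passage FP for slow (fitted) versus fast chromatin
    dynamics, under low-noise and high-noise regulator input.

    Slow dynamics filter the fluctuations (FP stays high under both);
    fast dynamics lose state stability when the input is noisy.
    """
    slow = ModelParams()
    fast = ModelParams(k_me=FAST_K_ME, p_dem=FAST_P_DEM)
    return {
        "fp_slow_low": _fp_under_regulator(slow, b_low, n_replicates,
                                           n_cycles, seed),
        "fp_slow_high": _fp_under_regulator(slow, b_high, n_replicates,
                                            n_cycles, seed + 10_000),
        "fp_fast_low": _fp_under_regulator(fast, b_low, n_replicates,
                                           n_cycles, seed + 20_000),
        "fp_fast_high": _fp_under_regulator(fast, b_high, n_replicates,
                                            n_cycles, seed + 30_000),
    }


def regulator_stationary_mean(
    seed: int, b: float = 10.0, duration_hr: float = 2500.0
) -> dict[str, float]:
    """Time-weighted stationary protein mean (and CV) of the regulator."""
    from .trans_input import simulate_regulator

    reg = RegulatorParams(b=b)
    trace = simulate_regulator(reg, duration_hr, seed)
    return {
        "mean_protein": trace.mean_alpha * reg.mean_protein,
        "cv": trace.cv,
        "duration_hr": duration_hr,
    }
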