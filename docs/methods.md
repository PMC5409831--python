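# Methods

## Model

The simulated object is a single gene locus of N histones (default 60,
even; nucleosomes are the adjacent pairs). Each histone carries an H3K27
methylation level in {me0, me1, me2, me3}; me2/me3 are the repressive
marks. The main model has 2N + 1 reactions — N single-step methylations, N
single-step noisy demethylations, and transcription initiation — whose
propensities are recomputed after every state update and simulated exactly
with the direct Gillespie algorithm.

Assumptions worth keeping in mind:

* PRC2 recruitment is strictly local (the partner histone and the two
  flanking nucleosomes, truncated at the domain boundary, so boundary
  histones have one-sided recruitment); the long-range coupling needed for
  bistability comes from transcription, whose rate responds to the
  me2/me3 content of the whole locus.
* Methylation is non-processive; the relative PRC2 activity on
  me0/me1/me2 substrates is 9:6:1 and background ("noisy") methylation is
  5% of the corresponding stimulated rate.
* Transcription is a single discrete event per initiation (no explicit
  elongation); it demethylates each histone with probability p_dem and
  replaces each nucleosome with per-histone probability p_ex. Exchange is
  resolved before demethylation within an event, so a replaced histone is
  not double-counted; the mean per-histone loss rate through exchange is
  ≈ 2 f p_ex.
* Noisy (transcription-independent) demethylation runs at
  γ_dem = f_min·p_dem, making repressed-state demethylation 2.5%
  transcription-coupled + 2.5% independent of the active-state maximum.
* DNA replication fires deterministically every T_cc = 22 hr; each
  nucleosome is replaced by me0/me0 with probability 0.5 and one daughter
  locus is followed. Mitosis is treated as a pause and not modeled.
* No activating histone marks, no 3D chromatin, no Pol II elongation
  dynamics.

### Transcription law and the repression threshold

The transcription initiation rate is
f = min(α·max(f_max − (P/P_T)(f_max − f_min), f_min), 1/60 s⁻¹), linear in
the me2/me3 fraction P until it saturates at the threshold P_T, scaled by
the trans-activation multiplier α and capped at one initiation per minute.
The fitted threshold is P_T = 1/3. The bistability-window scan
(`protocols.fmax_bistability_threshold`) runs with P_T = 1, i.e. the
untruncated linear law: the dynamic-range requirement for bistability was
established at that stage of the analysis, before the threshold was
introduced, and with P_T = 1/3 the repressed state is shielded so strongly
(f pinned at f_min for all P ≥ 1/3) that even a two-fold dynamic range
yields metastable repression and the scan loses its meaning.

ON/OFF state calls always use the thresholded quartile definitions: OFF
when n_me2 + n_me3 > 3NP_T/4, ON when < NP_T/4, strict inequalities, ties
counting as neither; with P_T = 1 these reduce to the classical 3N/4 and
N/4 counts. Occupancies are time-averaged over the last hour of each cell
cycle so that slow recovery from replication dilution is not scored as
instability. B = 4·P_OFF·P_ON.

### Variants

* **two_state**: levels {me0, me3} only, mean-field (all-to-all) feedback
  `γ_me + (k_me/N)·n_me3`, transcription linear in n_me3 with no
  threshold, cap or α; transcription resets each me3 histone with
  probability p_dem. Demonstrates that intermediate methylation states are
  required for bistability.
* **processive_methylation / processive_demethylation**: propensities
  unchanged, but the selected reaction jumps directly to me3 (or me0;
  including noisy demethylation).
* **promoter_switching**: the promoter toggles closed↔open with rates
  k_on/k_off; transcription initiates at f₀ only while open. Chromatin and
  α regulate k_on, mirroring the main model's f (with k_on_max, k_on_min
  in place of f_max, f_min) and capped so that f₀·P_open ≤ 1/60 s⁻¹. Given
  (k_on_max, k_off), k_on_min is derived to reproduce the main model's
  fold change F = 40 and f₀ to reproduce its repressed-state mean rate
  f_min. The k_on(α, P) mirror form is a reconstruction — the defining
  expression lives in supplementary material not available here — but it
  is constrained at both ends by the derived identities, which are tested.
  Analysis is restricted to k_on_max ≤ k_off. Simulations start with the
  promoter open in the uniform-me0 state and closed in the uniform-me3
  state.

### Trans inputs

α enters multiplicatively in f (or k_on). Three forms: a constant, a step
protocol (equilibrate at one value, switch permanently), and a stochastic
two-stage regulator DNA → mRNA → protein with linear decay, simulated as
four extra reactions in the same SSA so that α(t) = r(t)/⟨r⟩ updates with
every birth/death event. Decay rates d_R = 1/2 hr⁻¹, d_P = 1/12 hr⁻¹;
synthesis rates are derived from the burst size b = s_P/d_R and the target
mean ⟨r⟩ = 1000, so b is the single noise dial and the stationary mean is
b-independent: CV² = (1 + b/(1 + d_P/d_R))/⟨r⟩, ≈ 0.043 at b = 1 and
≈ 0.93 at b = 1000. The regulator is initialized at its deterministic
stationary means (an explicit burn-in flag exists); CV estimates are
time-weighted. Single 4000-hr traces carry ~5% relative CV error, so
closed-form comparisons average several traces.

## Engine numerics

* Direct method: one exponential waiting time from the total propensity,
  one categorical draw by cumulative sum, full propensity recomputation
  after every update. If the projected event time crosses a replication
  boundary, time advances to the boundary, replication fires, and
  propensities are rebuilt; the pre-draw is discarded (memorylessness).
  Absorbing states (all propensities zero) jump directly to the next
  boundary or the end time.
* RNG: xoshiro256++ seeded via splitmix64, one stream per simulation;
  ensemble replicate r uses base_seed + r. Identical seed and
  configuration give bit-identical trajectories.
* Two backends share those RNG primitives: the compiled (numba) kernel
  and a pure-Python loop over the readable reference operations in
  `chromatin`. The test suite asserts bit-identical trajectories across
  backends for every variant — the kernel is never the only
  implementation of a rule. Engine correctness is additionally checked
  against the exact stationary distribution of the 256-state
  continuous-time Markov chain of an N = 4 system (generator assembled
  from the reference propensities, transcription expanded as a compound
  event; null-space solve), and by a Kolmogorov–Smirnov test of
  propensity-rescaled waiting times against Exp(1).
* Trajectories record the post-event state (time, event kind, level
  counts, cumulative transcription count, promoter flag, α, protein and
  exchange-origin counts; optionally per-histone levels); counts sum to N
  at every record. Between records the state is piecewise constant, and
  all time averages use exact segment weighting. For large ensembles the
  kernel instead accumulates last-hour occupancies, per-cycle
  transcription counts and first-crossing times in-stream without
  recording; the metrics module reproduces the same numbers from recorded
  trajectories, and tests pin the two routes together.

## First passage and censoring

t_FP is the first event time at which the opposite state's threshold is
crossed (strictly above 3NP_T/4 from a me0 start, strictly below NP_T/4
from a me3 start), evaluated at event resolution. Replicates that never
cross contribute the censoring horizon itself, so the censored mean is
bounded by the horizon and the combined measure
FP = t_FP(me0)·t_FP(me3)/T² lies in (0, 1]. The horizon matters: a
~230-cycle exponential lifetime censored at 400 cycles reports a mean of
~190, censored at 1500 cycles ~229. The lifetime protocols therefore
censor at 1500 cycles (50 replicates per state); the noise-filtering
contrast uses 20-cycle horizons where FP itself is the object of
interest.

## SILAC-style fitting

The labeling protocol: equilibrate the uniform-me3 state for 5 cell
cycles at α = 1, label every histone "old" at the next replication
boundary (t = 0, sampled pre-replication), then track me3 as a fraction
of the old and new pools at t = 0, 10, 24, 48 hr. Simulated series are
rescaled by 0.301/P_me3_end so that the cell-cycle-end me3 level on total
histones maps onto the measured t = 0 old-pool fraction. P_me3_end is
estimated as the labeling-boundary (pre-replication) total-me3 fraction
averaged over replicates — with all histones old at t = 0 this is exactly
the quantity the anchor represents; the uniform-me3 start has not fully
relaxed by cycle 5, so averaging earlier cycle ends would overestimate
the level and bias the fit. Parameter sets whose repressed state
collapses during equilibration (P_me3_end < 0.05) are flagged as
normalization failures and excluded from scoring. Scoring is the plain
sum of squared errors of the normalized simulation against every
individual replicate over all (time, pool) combinations.

The measured dataset this pipeline is designed around is not
redistributable, so `synthetic_silac` generates stand-in tables: labeled
simulations averaged over many replicates, rescaled so the t = 0 old-pool
mean equals 0.301 exactly, plus independent Gaussian replicate noise
(default σ = 0.02, three replicates per point, clipped to [0, 1]). The
generator emulates the means, replicate structure and anchoring of a
pulse-labeling experiment at a single locus; it does not emulate
genome-wide averaging over heterogeneous loci, cell-cycle asynchrony
(the simulated time courses carry replication sawtooth the real
genome-average smooths out), or correlated measurement error — so
recovery results demonstrate that the fitting machinery is correct, not
that the model is identified by any real dataset.

### Identifiability and the fitting grids

Empirically (high-precision replicate-averaged curves), the normalized
48-hr time courses are informative about k_me in both directions — it
sets the me3 accumulation rate on new histones — but about p_dem and P_T
only upward of the fitted values: the anchor normalization divides out
the steady-state level those parameters control, and the post-replication
me2/me3 fraction never falls below ~0.4, so thresholds at or below 1/3
never engage the transcription law during the repressed-state protocol.
Curves at (p_dem, P_T) below the fitted point coincide to within ~0.005,
far below the replicate noise; no fitting procedure could separate them.
The default grids are therefore spaced at the procedure's measured
resolution: k_me ∈ 8×10⁻⁶·{¼, ½, 1, 2, 4}, p_dem ∈ {4×10⁻³, 1.6×10⁻²,
6.4×10⁻², 0.256, 1} and P_T ∈ {⅓, ⅔, 1}. All grid points share one
replicate seed set (common random numbers), which cancels much of the
simulation noise in SSE differences between neighbors. With 80 labeled
replicates per grid point the recovery experiment
(`silac.recovery_experiment`) returns the generating point in ≳ 80% of
repetitions at σ = 0.02; ties are broken toward slower k_me, then smaller
p_dem, then smaller P_T.

## Desk-scale protocol sizes

The shipped protocols reproduce results whose original versions used up
to thousands of replicates; the reduced sizes below were chosen so each
quantity's Monte-Carlo error is small against the effect being measured:

* state lifetimes: 50 replicates per initial state, censored at 1500
  cycles;
* bistability-window scan: 4×5 (k_me, p_dem) log grid, f_max over
  {2, 4, 8, 16, 32, 64}·f_min, 40 replicates per initial state, 20
  cycles, P_T = 1 — the smallest f_max with any-point B > 0.5 is stable
  across seeds at 1.6×10⁻³ s⁻¹;
* noise filtering: slow (fitted) vs fast (k_me = 4×10⁻⁵, p_dem = 0.2)
  dynamics, b = 1 vs b = 1000, 30 replicates per state, 20-cycle
  horizon;
* regulator statistics: single 2500-hr traces for means, several 4000-hr
  traces for CVs;
* N = 4 oracle: 50 replicates of 3.2×10⁵ s with a 2×10⁴ s burn-in;
  per-state tolerance is 3σ with σ the larger of the empirical replicate
  SE and the asymptotic dwell-time SE √(2π_s τ_s/T) (the empirical SE is
  unreliable for states visited only a handful of times).

## Known limitations

* The promoter-switching k_on(α, P) functional form is a constrained
  reconstruction (see above).
* The "demethylation-biased" regime (k_me = 10⁻⁴,
  p_dem = 0.1, P_T = 1) is monostable-active in this implementation only
  in the attractor sense: the repressed start decays over tens of cycles,
  so short unequilibrated ensembles still show appreciable OFF occupancy.
* The two-state variant ignores α, p_ex and the rate cap by design.
* SILAC fitting constrains k_me well; p_dem and P_T only via upper
  bounds (see identifiability above). This mirrors the information
  actually present in the labeling protocol rather than a software
  limitation.
* Censored first-passage means depend on the censoring horizon; always
  report the horizon alongside the estimate.
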