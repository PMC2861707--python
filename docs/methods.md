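# Methods

This note documents the estimators, simulators and oracles implemented in
`spikeprc`: the quantities they compute, the assumptions behind them, the
numerical choices, and what the validation experiments do and do not show.

## Phase response curves from pulse-perturbed sweeps

A sweep (trial) is a spike train with one rectangular current pulse.  All
times are milliseconds; phases are dimensionless.  The oscillation period is
identified with the unperturbed mean ISI, T̄, estimated by pooling all ISIs
that end at or before the pulse across the ensemble (per-trial estimation is
available via `baseline_isi_stats(..., scope="per_trial")` but is noisy for
short baselines).  The CV uses the population (n) standard deviation, a
convention fixed so that exact tests are possible.  A pulse coincident with
a spike belongs to the ISI beginning at that spike (half-open intervals).
Sweeps with fewer than two spikes at or before the pulse or none after are
skipped with a logged count rather than raising — mirroring the practical
discard of unusable sweeps.

**Traditional estimator.**  One point per sweep, referenced to the spike s₀
immediately preceding the pulse: φ = (t_p − s₀)/T̄ and
F = (T̄ − (s₁ − s₀))/T̄.  Causality forces F ≤ 1 − φ (the next spike cannot
precede the pulse), and `causality_violations` returns any point violating
the bound to 1e−12 — a non-empty result signals corrupted input, never
physics.  Points with φ > 1 arise under jitter and are retained by default;
`drop_phase_gt_1` reproduces the deletion variant, which demonstrably does
not remove the late-phase bias.

**Corrected estimator.**  Every spike is used as the reference, one at a
time.  For band 1, each pre-pulse spike s with raw phase
r = (t_p − s)/T̄ < m_pre + 1 contributes a point at the *folded* phase
r − ⌊r⌋, with the cumulative value ((m+1)·T̄ − (s₁ − s))/T̄, where m is the
realized number of spikes strictly between s and the pulse.  Two details
matter and were settled by direct experiment on the surrogate (10,000
trials, 5% jitter):

* *Selection by raw phase, not by spike index.*  Each spike in the
  (m_pre+1)-period window then enters exactly once, so the pooled raw-phase
  density is uniform with a crisp cutoff; truncating by spike index instead
  leaves a jitter-wide half-ramp at the window boundary that folds
  asymmetrically (pooled histogram χ² p ≈ 1e−13 versus p ≈ 0.3 with the
  phase cutoff).
* *Folding by the integer part of the raw phase, not by the index.*  When
  jitter reassigns the pulse to a neighboring cycle, the reference indices
  shift; folding by ⌊r⌋ places each point at the phase where its value
  belongs.  This is what homogenizes the sampling and cancels the
  late-phase depletion: with index-shifting the corrected late-decile
  recovery error was ≈ 0.046, with folding it is ≈ 0.007 (amplitude 0.1).

For m = 1 both coordinates are independent of s₀'s jitter, the mechanism
that breaks the causality coupling.  The default is m_pre = 1 (the two
spikes preceding the pulse as references).  Post-pulse spikes are the
references for the following intervals: band k ≥ 2 uses the (k−1)-th spike
after the pulse, reports the per-interval value (T̄ − (s_k − s_{k−1}))/T̄ at
phase (t_p − s_{k−1})/T̄, and lives on the interval [−(k−1), −(k−2)]; a
cumulative variant is available behind `cumulative_post`.

**Residual bias.**  The correction removes *most* of the traditional bias,
not all of it.  Every PRC value contains the first post-pulse spike s₁, and
the constraint s₁ > t_p couples to the sampled phase regardless of the
reference: within roughly two jitter standard deviations of the phase-
interval edges a selection bias of order −0.01…−0.02 phase-shift units
survives (for 5% jitter on the clock-like surrogate; it is milder and more
spread out for renewal-type models, where spike jitter accumulates).  At
ensemble sizes of 10⁴ sweeps the per-bin standard error is ≈ 0.002, so the
outermost bins of a 20-bin control PRC sit several standard errors below
zero even though the interior is flat.  Tests assert the interior behavior
and treat the edge bins as the known limitation they are.

**Control PRC.**  `control_points` substitutes a virtual 0 pA pulse at a
stated time, using only the unperturbed (pre-real-pulse) span of each
sweep; trials whose span does not reach the virtual time are skipped with a
logged count.  On phase-randomized spontaneous trains the corrected cPRC is
flat; the traditional cPRC reproduces the late-phase dip — the bias
signature in the absence of any stimulus effect.

**Smoothing.**  Curves are Nadaraya–Watson (Gaussian kernel) regressions of
value on phase, truncated at 3 bandwidths, with no wrap-around (phase
within a band is not periodic; edge nodes renormalize over their one-sided
neighborhood).  The default bandwidth is 0.05 phase units — no bandwidth is
prescribed by the method itself; noiseless validations use 0.0025 since
there is no variance to trade against resolution.  Node standard errors
come from the kernel-weighted variance with effective sample size
(Σw)²/Σw²; nodes below an effective-n floor (default 5) are flagged
unreliable and reported as NaN, never as 0.  Binned summaries
(`binned_means`) use cluster-robust standard errors grouped by trial,
because multi-reference points from one sweep share spike jitter and naive
SEs would be anti-conservative (by ≈ 1.3× at m_pre = 1).

**Peak-to-baseline ratio and classification.**  f_e and f_l are the
largest-magnitude values of the smoothed band-1 curve on [0, 0.5] and
[0.5, 1]; R = f_l/f_e (undefined, label "ambiguous", when |f_e| < 1e−6).
Flat curves give R ≈ 1, late-peaked curves R > 1.  `classify_curve` calls a
curve phase-independent when R ∈ [1/(1+t), 1+t] with tolerance t = 0.5,
phase-dependent above, ambiguous otherwise; the tolerance is this package's
choice — the empirical switch it mirrors is qualitative, with no published
numeric cutoff.  `prc_error` is the trapezoidal integral of
|curve − reference| over the common phase interval, with the reference
linearly interpolated onto the curve grid.

## Simulators

All simulators are deterministic given (config, protocol, seed): each trial
draws from its own substream (`numpy` `SeedSequence.spawn`), so results are
independent of internal batching.  Pulse onsets are either fixed, uniform
in a window (drawn from the trial's own substream), or explicit per trial.

**Jittered-periodic surrogate.**  Spikes at k·T̄ + ε_k, ε_k i.i.d.
N(0, σ²), drawn independently per trial; the underlying clock is not reset
by spikes.  Independent spike jitter makes the ISI sd √2·σ, hence
CV = √2·σ/T̄ — e.g. σ = 1 ms at T̄ = 20 ms gives CV ≈ 0.0707.  An injected
true PRC g(φ) advances every grid time after the pulse-containing interval
by T̄·g(φ_true), clamped at (1−φ_true)·T̄ so the advanced spike never
precedes the pulse (true PRCs obey g ≤ 1−φ).  Spikes are trimmed at the
trial edges by *grid* position with a 4σ margin: truncating the jittered
times themselves selects on the edge spikes' noise and was measured to bias
T̄ by −0.4%, which propagates into every PRC value.  `phase_randomized`
adds a uniform per-trial grid offset, emulating spontaneous firing whose
phase at any fixed wall-clock time is random — required for control-PRC
experiments with a fixed virtual pulse time.  Ordering violations after
jitter are resampled (up to 100 attempts, then an error).

**Integrate-and-fire.**  Membrane equation τ·dV/dt = −V + R_m·I(t) plus
white current noise, reset to V_reset at threshold; τ = ∞ (with explicit
capacitance C) gives the perfect integrator dV/dt = I/C.  Voltage units
are normalized by default (reset 0, threshold 1, R_m = 1); `c_m` defaults
to τ/R_m.  Because the equation is linear, each step uses the exact
exponential (Ornstein–Uhlenbeck) discretization — exact drift and exact
noise variance for step-constant input — rather than plain Euler–Maruyama,
whose deterministic period error of T·h/(2τ) would be two time steps at
τ = 5 ms and h = 0.025 ms.  With the exact update, the noiseless periods
match the closed forms T = C·(V_th−V_reset)/I (non-leaky) and
T = τ·ln(V_∞/(V_∞−V_th)) (leaky, voltages from reset) to ~1e−13.
Threshold crossings are located by linear interpolation within the step,
and the reset integrates the drift over the remainder of the step so no
time is lost.  Rectangular pulses are applied via the fractional overlap of
each step with the pulse window.  Noise convention: `noise_sd` is a white-
noise current intensity (current·√ms); the per-step current sd is
noise_sd/√h, so ISI statistics are step-size-consistent (verified by
halving the step).  `calibrate_noise_sd` tunes the intensity to a target
ISI CV by fixed-point iteration (CV is very nearly proportional to σ),
starting from the diffusion approximation CV ≈ σ·√T̄/(C·(V_th−V_reset));
it reaches 0.05 ± 0.005 in 1–3 iterations of ≈ 5,000 unperturbed ISIs.

**Morris–Lecar.**  The standard two-variable conductance model with the
widely used type-I (SNIC) parameter set (C = 20 µF/cm², g_Ca = 4, g_K = 8,
g_L = 2 mS/cm², E_Ca = 120, E_K = −84, E_L = −60 mV, V1 = −1.2, V2 = 18,
V3 = 12, V4 = 17.4 mV, φ_w = 1/15 ms⁻¹, drive 45 µA/cm²; period
≈ 99.3 ms).  Integration is stochastic Heun at the same 0.025 ms step
(plain Euler misses the sub-0.1% step-halving convergence that Heun
delivers: measured relative period change 5e−7 on halving).  Spikes are
upward 0 mV crossings with a 2 ms refractory guard; a run that produces no
spikes, or a non-finite state, raises with the offending step.

## Ground-truth oracles

A pulse of amplitude A and duration d delivers charge A·d, i.e. an
equivalent kick ΔV = A·d/C.

* **Non-leaky closed form:** constant ΔV/(V_th−V_reset) — the square,
  phase-independent PRC of the perfect integrator.  A kick that alone
  reaches threshold makes the curve 1−φ; that degenerate case is returned
  only under an explicit flag.  (The exact curve for a *finite* pulse rolls
  off over the last ΔV + d/T̄ of phase; validations keep that region out of
  the compared interior.)
* **Leaky closed form:** with V(φT) = V_∞(1−e^(−φT/τ)) measured from
  reset, a subthreshold kick advances the next spike by
  τ·ln[(V_∞−V)/(V_∞−V−ΔV)]; otherwise the spike is immediate and the
  value is exactly 1−φ.  The curve rises monotonically on the subthreshold
  branch.  Since at τ = 5 ms a 0.5 ms rectangle is measurably different
  from an instantaneous kick (the kick mis-times the perturbation by d/2 ≈
  1.25% of phase), `leaky_if_prc` also implements the exact
  rectangular-pulse solution (relaxation toward the elevated asymptote
  during the pulse, crossing computed in whichever segment it occurs);
  validations use it, and it agrees with the direct-perturbation oracle to
  8e−7.
* **Direct perturbation:** for any deterministic simulator, one
  unperturbed run establishes the period and a settled reference spike;
  one run per grid phase injects a single pulse at reference + φT and
  measures (T − perturbed ISI)/T.  This "no-noise pendant" is the
  universal numerical reference (an adjoint computation would serve the
  same role for infinitesimal pulses; direct perturbation is equivalent
  for the finite pulses used here and needs no extra machinery).  Both IF
  closed forms agree with it to < 1e−3 on interior phases; the edges
  (φ ≈ 0, 1) are excluded because the pulse then overlaps the reference or
  the next spike.

## Validation experiments and their scope

`spikeprc.validation` packages the experiments the test suite and
`prc validate` run.  Problem sizes: 10,000-trial surrogate ensembles
(bias demonstration, recovery, control flatness), 15,000-trial flat-PRC
runs at calibrated CV 0.05, 6,000-trial CV sweeps, 2,000-trial noiseless
oracle comparisons — each completes in seconds to tens of seconds on one
CPU.  Protocols use a 6-period baseline and a pulse placed uniformly over
exactly two periods, so true phases are sampled uniformly by construction.
The non-leaky model runs at 50 Hz in the noiseless comparisons and at
20 Hz (T̄ = 50 ms) in the flat-PRC experiment — the slow-firing regime
where phase-independent PRCs matter, which also keeps the finite-pulse
roll-off out of the band interior; the leaky model runs at 50 Hz (the
τ = 5 ms benchmark) in noiseless comparisons and at 100 Hz in the CV
sweep.  Pulses are small (ΔV = 1–2% of the threshold range), the
infinitesimal-PRC regime the method targets.

What the surrogate does and does not emulate: it reproduces the essential
geometry — periodic firing, independent spike jitter, a single-ISI pulse
effect with a known g(φ) — but not accumulation of phase noise (its clock
is never reset by spikes), noise-dependent changes of the underlying
dynamics, ISI correlations, or multi-ISI pulse effects (PRC₂… are
identically zero in the surrogate by construction; the IF models produce
them physically).  Passing the surrogate tests therefore demonstrates the
estimator's sampling geometry is right, not that any particular biological
noise model holds.

Known limitations, measured and deliberate:

* the corrected estimator's residual edge bias (above) — tests that demand
  every bin of a 20-bin summary within 2 SE of truth at n = 10⁴ resolve it
  and fail at the outermost bins;
* at very low noise (CV = 0.02) on the leaky model the corrected
  estimator's error integral slightly exceeds the traditional one (by
  ≈ 15% relative, consistently across seeds): there is almost no
  causality bias left to remove, while the extra reference still smears
  the steep exponential limb by one ISI of jitter.  The ordering
  "corrected < traditional" is robust from CV ≈ 0.05 upward and at all
  CVs for the non-leaky model;
* no conductance-based Purkinje models are bundled; the protocol-runner
  accepts any external per-trial model function with the documented
  signature.
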