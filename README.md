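# spikeprc

Bias-corrected estimation of neuronal **phase response curves (PRCs)** from
pulse-perturbed spike trains.

## The problem

The PRC of a spontaneously firing neuron describes how much a brief current
pulse shifts the timing of subsequent spikes as a function of the phase at
which the pulse arrives within the interspike interval (ISI).  With T̄ the
mean unperturbed ISI, s₀ the spike just before the pulse at t_p, and s₁ the
spike just after it, the traditional estimator records one point per sweep:

    φ = (t_p − s₀) / T̄        F(φ) = (T̄ − (s₁ − s₀)) / T̄

Because s₁ must follow the pulse, every such point obeys **F ≤ 1 − φ**: the
triangular region above that line is empty.  In a neuron with ISI jitter
(Purkinje cells are the motivating case: CV ≈ 0.05, thousands of sweeps
needed) this hard boundary depletes late-phase sampling and drags the
running average down — the traditional PRC acquires a spurious negative
deflection at late phases that averaging cannot remove.

The **corrected estimator** implemented here uses every spike of the train
as the reference, one at a time.  Each pre-pulse spike s with raw phase
(t_p − s)/T̄ below a cutoff contributes a point at the folded phase
raw − ⌊raw⌋ with the cumulative value ((m+1)·T̄ − (s₁ − s))/T̄, where m is
the number of spikes between s and the pulse.  Pooling these references
makes the phase sampling exactly homogeneous and removes the late-phase
bias; post-pulse spikes likewise serve as references for the following
intervals (PRC₂, PRC₃, …, plotted on phase intervals [−1,0], [−2,−1], …).

The package provides, as a library plus a `prc` command line tool:

* trial/ensemble containers with lossless TSV I/O (`spikeprc.trials`);
* traditional, corrected and control (0 pA virtual pulse) PRC points,
  Gaussian-kernel smoothing, phase histograms, causality diagnostics,
  peak-to-baseline ratio and PRC shape classification
  (`spikeprc.estimation`);
* simulators with known ground truth — a jittered-periodic surrogate with
  an injectable true PRC, leaky/non-leaky integrate-and-fire neurons with
  white current noise (plus a CV-targeted noise calibration helper), and a
  Morris–Lecar oscillator (`spikeprc.simulators`);
* closed-form PRCs for both integrate-and-fire models and a
  direct-perturbation numerical oracle for any deterministic model
  (`spikeprc.oracles`);
* packaged validation experiments (`spikeprc.validation`, `prc validate`).

## Worked example

Estimate a known PRC, g(φ) = 0.1·sin²(πφ), injected into a 50 Hz
jittered-periodic surrogate (spike jitter 1 ms, i.e. ISI CV ≈ 0.07):

```python
import numpy as np
import spikeprc as sp
from spikeprc import estimation as est
from spikeprc.validation import sin2_prc

period = 20.0                                    # 50 Hz oscillator
cfg = sp.JitteredPeriodicConfig(period=period, jitter_sd=1.0,
                                true_prc=sin2_prc(0.1))
proto = sp.ProtocolSpec(baseline=120.0, length=280.0, pulse_amplitude=1.0,
                        pulse_window=(120.0, 160.0), n_trials=10_000)
ens = sp.simulate_jittered_periodic(cfg, proto, seed=1)

stats = sp.baseline_isi_stats(ens)
print(f"T-bar = {stats.mean_isi:.3f} ms, ISI CV = {stats.cv:.4f} "
      f"({stats.n_intervals} baseline intervals)")

trad = sp.traditional_points(ens, stats)
corr = sp.corrected_points(ens, stats, m_pre=1, n_post=0)
print(f"causality violations: {len(sp.causality_violations(trad))}")

grid = np.linspace(0.0, 1.0, 101)
truth = 0.1 * np.sin(np.pi * grid) ** 2
for name, pts in [("traditional", trad), ("corrected", corr)]:
    curve = est.smooth_curve(pts, band=1, bandwidth=0.05, grid_n=101)
    err = np.nanmax(np.abs(curve.mean - truth))
    late = np.nanmax(np.abs(curve.mean - truth)[grid >= 0.9])
    print(f"{name:>11}: max |error| = {err:.4f}, late-decile |error| = {late:.4f}")

peaks = est.peak_to_baseline(est.smooth_curve(corr, 1, 0.05, 101))
print(f"peak-to-baseline ratio R = {peaks.ratio:.3f} "
      f"-> {est.classify_curve(peaks)}")
```

Output:

```
T-bar = 19.992 ms, ISI CV = 0.0707 (54974 baseline intervals)
causality violations: 0
traditional: max |error| = 0.0414, late-decile |error| = 0.0414
  corrected: max |error| = 0.0073, late-decile |error| = 0.0073
peak-to-baseline ratio R = 1.000 -> phase-independent
```

The traditional estimate misses the true curve by 0.04 phase units at late
phases (40% of the PRC amplitude) — the causality-boundary bias — while the
corrected estimate recovers g to better than 0.008 everywhere.  No point
ever violates F ≤ 1 − φ, and the flat ratio R ≈ 1 reflects the injected
curve's symmetric shape.

The same analyses run from the shell:

```sh
prc simulate config.yaml -o ensemble.tsv
prc estimate ensemble.tsv -o out/prc --method both --bandwidth 0.05
prc validate -o report.tsv          # surrogate + IF models across CVs
```

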