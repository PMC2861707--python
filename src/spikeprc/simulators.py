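"""Trial-ensemble generators with known ground truth.

Three model families:

* a *jittered-periodic surrogate* — regular spike times jittered
  independently by Gaussian noise, optionally carrying an injected true PRC
  g(φ) that advances the first post-pulse spike (and all later ones,
  rigidly) by T̄·g(φ);
* *integrate-and-fire* neurons, leaky (membrane time constant τ) or
  non-leaky (τ = ∞, a perfect integrator), with white current noise;
* a *Morris–Lecar* oscillator (two-variable conductance model).

All simulators are deterministic given (config, protocol, seed): every
trial draws from its own substream spawned from the master seed, so results
are independent of batching.  The IF membrane equation is linear, so it is
advanced with the exact exponential (Ornstein–Uhlenbeck) discretization per
step — drift and noise variance are exact for step-constant input, and the
non-leaky limit reduces to the Euler–Maruyama update V += (I/C)h + (σ/C)√h·N.
Morris–Lecar uses stochastic Heun at a fixed 0.025 ms step.  Threshold
crossings are localized by linear interpolation within the step.

Noise convention: ``noise_sd`` is the white-noise current intensity in
current·√ms units; the per-step current sd is ``noise_sd/√h``, so statistics
are step-size-consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .trials import PulseEvent, Trial, TrialEnsemble, ValidationError

__all__ = [
    "ProtocolSpec",
    "JitteredPeriodicConfig",
    "IntegrateAndFireConfig",
    "MorrisLecarConfig",
    "SimulatorConfig",
    "simulate_jittered_periodic",
    "simulate_integrate_and_fire",
    "simulate_morris_lecar",
    "run_pulse_protocol",
    "calibrate_noise_sd",
    "if_period",
    "if_drive_for_rate",
    "leaky_if_config",
    "nonleaky_if_config",
    "pulse_delta_v",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Stimulation protocol: baseline, pulse placement, trial count.

    Exactly one of ``pulse_time`` (fixed onset), ``pulse_window`` (uniform
    random onset within a window) or ``pulse_times`` (explicit per-trial
    onsets) must be given.  ``control=True`` forces amplitude 0 (virtual
    pulse).
    """

    baseline: float
    length: float
    pulse_amplitude: float
    pulse_duration: float = 0.5
    pulse_time: float | None = None
    pulse_window: tuple[float, float] | None = None
    pulse_times: Sequence[float] | None = None
    n_trials: int = 1
    control: bool = False

    def __post_init__(self) -> None:
        if not self.baseline < self.length:
            raise ValidationError("baseline must be shorter than the trial")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        if self.pulse_duration <= 0:
            raise ValidationError("pulse duration must be > 0")
        given = [self.pulse_time is not None, self.pulse_window is not None,
                 self.pulse_times is not None]
        if sum(given) != 1:
            raise ValidationError("give exactly one of pulse_time, pulse_window, pulse_times")
        if self.pulse_time is not None and not (self.baseline <= self.pulse_time <= self.length):
            raise ValidationError("pulse must fall after the baseline and within the trial")
        if self.pulse_window is not None:
            lo, hi = self.pulse_window
            if not (self.baseline <= lo < hi <= self.length):
                raise ValidationError("pulse window must lie in [baseline, length]")
        if self.pulse_times is not None and len(self.pulse_times) != self.n_trials:
            raise ValidationError("pulse_times must have one entry per trial")

    @property
    def amplitude(self) -> float:
        return 0.0 if self.control else self.pulse_amplitude

    def draw_pulse_times(self, rngs: Sequence[np.random.Generator]) -> np.ndarray:
        """Per-trial pulse onsets; random onsets use each trial's own rng first."""
        if self.pulse_times is not None:
            return np.asarray(self.pulse_times, dtype=float)
        if self.pulse_time is not None:
            return np.full(self.n_trials, float(self.pulse_time))
        lo, hi = self.pulse_window
        return np.array([rng.uniform(lo, hi) for rng in rngs])


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def _assemble(spike_lists, pulse_times, protocol: ProtocolSpec, metadata: dict) -> TrialEnsemble:
    trials = []
    for i, (spk, tp) in enumerate(zip(spike_lists, pulse_times)):
        trials.append(
            Trial(
                trial_id=f"t{i:05d}",
                spikes=np.asarray(spk, dtype=float),
                pulse=PulseEvent(float(tp), protocol.amplitude, protocol.pulse_duration),
                length=protocol.length,
            )
        )
    return TrialEnsemble(trials, metadata)


# ---------------------------------------------------------------------------
# jittered-periodic surrogate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JitteredPeriodicConfig:
    """Surrogate spike-train generator.

    Spikes sit at k·period + ε_k with ε_k i.i.d. N(0, jitter_sd²), drawn
    independently per trial (the underlying clock is not reset by spikes).
    If ``true_prc`` is given, a pulse at true phase φ (measured on the
    unjittered grid) advances every subsequent grid time by period·g(φ):
    a clean single-ISI ground truth for estimator recovery.
    """

    period: float
    jitter_sd: float = 0.0
    true_prc: Callable[[float], float] | None = None
    phase_randomized: bool = False
    max_resample: int = 100

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValidationError("period must be > 0")
        if self.jitter_sd < 0:
            raise ValidationError("jitter sd must be >= 0")


def _surrogate_trial(cfg: JitteredPeriodicConfig, pulse: PulseEvent, length: float,
                     rng: np.random.Generator) -> np.ndarray:
    # phase randomization: the spontaneous clock is not stimulus-locked, so a
    # fixed wall-clock pulse time samples all phases uniformly across trials
    offset = rng.uniform(0.0, cfg.period) if cfg.phase_randomized else 0.0
    base = offset + np.arange(-1, int(length // cfg.period) + 1, dtype=float) * cfg.period
    if cfg.true_prc is not None and pulse.amplitude != 0.0:
        phi_true = ((pulse.time - offset) % cfg.period) / cfg.period
        # causality clamp: the advanced spike cannot precede the pulse itself,
        # so the effective advance is at most (1 - phi)·T (true PRCs obey g <= 1 - phi)
        shift = min(float(cfg.true_prc(phi_true)), 1.0 - phi_true) * cfg.period
        base = base.copy()
        base[base > pulse.time - phi_true * cfg.period + 1e-12] -= shift
    # trim by *grid* position with a 4-sigma margin: selecting on the jittered
    # times themselves would condition the edge spikes' jitter and bias the
    # first/last ISI short
    margin = 4.0 * cfg.jitter_sd
    base = base[(base >= margin) & (base <= length - margin)]
    if cfg.jitter_sd == 0.0:
        spikes = base
    else:
        for _ in range(cfg.max_resample):
            spikes = base + rng.normal(0.0, cfg.jitter_sd, size=base.size)
            if np.all(np.diff(spikes) > 0):
                break
        else:
            raise ValidationError("jitter too large: spike ordering not recovered in "
                                  f"{cfg.max_resample} resamples")
        spikes = spikes[(spikes >= 0) & (spikes <= length)]
    return spikes


def simulate_jittered_periodic(cfg: JitteredPeriodicConfig, protocol: ProtocolSpec,
                               seed: int) -> TrialEnsemble:
    """Generate a jittered-periodic surrogate ensemble."""
    return run_pulse_protocol(
        lambda pulse, length, rng: _surrogate_trial(cfg, pulse, length, rng),
        protocol, seed, metadata={"model": "jittered_periodic"},
    )


def run_pulse_protocol(run_fn, protocol: ProtocolSpec, seed: int,
                       metadata: dict | None = None) -> TrialEnsemble:
    """Run ``n_trials`` independent sweeps of any per-trial model function.

    ``run_fn(pulse: PulseEvent, length: float, rng) -> array of spike times``
    is called once per trial with a substream generator spawned from
    ``seed``; the pulse onset (if randomized) is drawn from the same
    substream before the model runs.  Identical inputs give bit-identical
    ensembles.
    """
    rngs = _spawn_rngs(seed, protocol.n_trials)
    pulse_times = protocol.draw_pulse_times(rngs)
    spike_lists = []
    for tp, rng in zip(pulse_times, rngs):
        pulse = PulseEvent(float(tp), protocol.amplitude, protocol.pulse_duration)
        spike_lists.append(run_fn(pulse, protocol.length, rng))
    meta = dict(metadata or {})
    meta.setdefault("seed", seed)
    return _assemble(spike_lists, pulse_times, protocol, meta)


# ---------------------------------------------------------------------------
# integrate-and-fire
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntegrateAndFireConfig:
    """Leaky or non-leaky (``tau=math.inf``) integrate-and-fire neuron.

    Voltage units are normalized by default (reset 0, threshold 1,
    membrane resistance 1); any physical parameterization is accepted as-is.
    ``c_m`` defaults to τ/R_m and must be given explicitly for the
    non-leaky model, where the leak term vanishes and only the capacitance
    scales the input.
    """

    i_drive: float
    tau: float = 5.0
    v_reset: float = 0.0
    v_thresh: float = 1.0
    r_m: float = 1.0
    c_m: float | None = None
    noise_sd: float = 0.0
    time_step: float = 0.025

    def __post_init__(self) -> None:
        if self.time_step <= 0:
            raise ValidationError("time step must be > 0")
        if not self.v_thresh > self.v_reset:
            raise ValidationError("threshold must exceed reset")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")
        if math.isinf(self.tau) and self.c_m is None:
            raise ValidationError("non-leaky model needs an explicit capacitance c_m")

    @property
    def capacitance(self) -> float:
        return self.c_m if self.c_m is not None else self.tau / self.r_m

    @property
    def leaky(self) -> bool:
        return math.isfinite(self.tau)


def if_period(cfg: IntegrateAndFireConfig) -> float:
    """Closed-form deterministic firing period.

    Non-leaky: T = C·(V_th − V_reset)/I.  Leaky (reset 0 reference):
    T = τ·ln(V_∞/(V_∞ − V_th′)) with V_∞ = I·R_m and voltages measured
    from the reset potential.
    """
    rng_v = cfg.v_thresh - cfg.v_reset
    if not cfg.leaky:
        if cfg.i_drive <= 0:
            raise ValidationError("no limit cycle: non-positive drive")
        return cfg.capacitance * rng_v / cfg.i_drive
    v_inf = cfg.i_drive * cfg.r_m - cfg.v_reset
    if v_inf <= rng_v:
        raise ValidationError("no limit cycle: subthreshold drive")
    return cfg.tau * math.log(v_inf / (v_inf - rng_v))


def if_drive_for_rate(rate_hz: float, tau: float = 5.0, v_reset: float = 0.0,
                      v_thresh: float = 1.0, r_m: float = 1.0,
                      c_m: float | None = None) -> float:
    """Drive current producing a deterministic firing rate of ``rate_hz``."""
    T = 1000.0 / rate_hz
    rng_v = v_thresh - v_reset
    if math.isinf(tau):
        if c_m is None:
            raise ValidationError("non-leaky model needs c_m")
        return c_m * rng_v / T
    return (rng_v / (1.0 - math.exp(-T / tau)) + v_reset) / r_m


def leaky_if_config(rate_hz: float = 50.0, tau: float = 5.0, noise_sd: float = 0.0,
                    **kw) -> IntegrateAndFireConfig:
    """Leaky IF with drive set for ``rate_hz`` deterministic firing."""
    return IntegrateAndFireConfig(
        i_drive=if_drive_for_rate(rate_hz, tau=tau), tau=tau, noise_sd=noise_sd, **kw)


def nonleaky_if_config(rate_hz: float = 50.0, c_m: float = 5.0, noise_sd: float = 0.0,
                       **kw) -> IntegrateAndFireConfig:
    """Non-leaky (perfect integrator) IF with drive set for ``rate_hz``."""
    return IntegrateAndFireConfig(
        i_drive=if_drive_for_rate(rate_hz, tau=math.inf, c_m=c_m), tau=math.inf,
        c_m=c_m, noise_sd=noise_sd, **kw)


def pulse_delta_v(cfg: IntegrateAndFireConfig, amplitude: float,
                  duration: float) -> float:
    """Instantaneous-kick voltage equivalent ΔV = A·d/C of a rectangular pulse."""
    return amplitude * duration / cfg.capacitance


def _if_batch(cfg: IntegrateAndFireConfig, length: float, pulse_times: np.ndarray,
              amplitude: float, duration: float,
              rngs: Sequence[np.random.Generator]) -> list[np.ndarray]:
    """Advance a batch of independent IF trials with the exact OU update."""
    h = cfg.time_step
    n = len(pulse_times)
    n_steps = int(math.ceil(length / h))
    C = cfg.capacitance
    if cfg.leaky:
        rho = math.exp(-h / cfg.tau)
        sig_step = cfg.r_m * cfg.noise_sd * math.sqrt((1.0 - rho * rho) / (2.0 * cfg.tau))
    else:
        sig_step = cfg.noise_sd * math.sqrt(h) / C

    noisy = cfg.noise_sd > 0
    if noisy:
        noise = np.empty((n, n_steps))
        for i, rng in enumerate(rngs):
            noise[i] = rng.standard_normal(n_steps)

    v = np.full(n, float(cfg.v_reset))
    tp = pulse_times
    spikes: list[list[float]] = [[] for _ in range(n)]
    for k in range(n_steps):
        t0 = k * h
        # step-average pulse current: fractional overlap of [t0, t0+h] with the pulse
        ov = np.clip(np.minimum(t0 + h, tp + duration) - np.maximum(t0, tp), 0.0, h) / h
        i_eff = cfg.i_drive + amplitude * ov
        if cfg.leaky:
            v_inf = cfg.r_m * i_eff
            v_new = v_inf + (v - v_inf) * rho
        else:
            v_new = v + (i_eff / C) * h
        if noisy:
            v_new = v_new + sig_step * noise[:, k]
        crossed = v_new >= cfg.v_thresh
        if crossed.any():
            idx = np.nonzero(crossed)[0]
            frac = (cfg.v_thresh - v[idx]) / (v_new[idx] - v[idx])
            for i, f in zip(idx, frac):
                spikes[i].append(t0 + h * float(f))
            # reset, then integrate the drift over the remainder of the step so
            # no time is lost at the reset (keeps the noiseless period exact)
            rem = h * (1.0 - frac)
            if cfg.leaky:
                v_new[idx] = cfg.r_m * i_eff[idx] + \
                    (cfg.v_reset - cfg.r_m * i_eff[idx]) * np.exp(-rem / cfg.tau)
            else:
                v_new[idx] = cfg.v_reset + (i_eff[idx] / C) * rem
        v = v_new
    return [np.array([t for t in s if t <= length]) for s in spikes]


def simulate_integrate_and_fire(cfg: IntegrateAndFireConfig, protocol: ProtocolSpec,
                                seed: int) -> TrialEnsemble:
    """Simulate an IF trial ensemble under a pulse protocol."""
    if cfg.noise_sd == 0:
        if_period(cfg)  # raises "no limit cycle" for subthreshold deterministic drive
    if cfg.time_step > protocol.pulse_duration:
        raise ValidationError("time step larger than the pulse duration")
    rngs = _spawn_rngs(seed, protocol.n_trials)
    pulse_times = protocol.draw_pulse_times(rngs)
    spike_lists: list[np.ndarray] = []
    chunk = 2000
    for c0 in range(0, protocol.n_trials, chunk):
        c1 = min(c0 + chunk, protocol.n_trials)
        spike_lists.extend(
            _if_batch(cfg, protocol.length, pulse_times[c0:c1],
                      protocol.amplitude, protocol.pulse_duration, rngs[c0:c1])
        )
    model = "if_leaky" if cfg.leaky else "if_nonleaky"
    return _assemble(spike_lists, pulse_times, protocol, {"model": model, "seed": seed})


# ---------------------------------------------------------------------------
# Morris–Lecar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorrisLecarConfig:
    """Two-variable Morris–Lecar oscillator.

    Defaults are the standard type-I (SNIC) parameter set widely used in
    phase-resetting studies: C = 20 µF/cm², g_Ca = 4, g_K = 8, g_L = 2
    mS/cm², E_Ca = 120, E_K = −84, E_L = −60 mV, half-activations
    V1 = −1.2, V2 = 18, V3 = 12, V4 = 17.4 mV, w-rate φ_w = 1/15 ms⁻¹,
    drive 45 µA/cm² (sustained spiking above the ~40 µA/cm² SNIC
    threshold).  Spikes are upward crossings of ``spike_threshold`` with a
    refractory guard against double counting.
    """

    i_drive: float = 45.0
    c_m: float = 20.0
    g_ca: float = 4.0
    g_k: float = 8.0
    g_l: float = 2.0
    v_ca: float = 120.0
    v_k: float = -84.0
    v_l: float = -60.0
    v1: float = -1.2
    v2: float = 18.0
    v3: float = 12.0
    v4: float = 17.4
    phi_w: float = 1.0 / 15.0
    noise_sd: float = 0.0
    time_step: float = 0.025
    spike_threshold: float = 0.0
    refractory: float = 2.0

    def __post_init__(self) -> None:
        if self.time_step <= 0:
            raise ValidationError("time step must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")


def _ml_drift(cfg: MorrisLecarConfig, v, w, i_eff):
    m_inf = 0.5 * (1.0 + np.tanh((v - cfg.v1) / cfg.v2))
    w_inf = 0.5 * (1.0 + np.tanh((v - cfg.v3) / cfg.v4))
    lam = np.cosh((v - cfg.v3) / (2.0 * cfg.v4))
    dv = (i_eff - cfg.g_l * (v - cfg.v_l) - cfg.g_ca * m_inf * (v - cfg.v_ca)
          - cfg.g_k * w * (v - cfg.v_k)) / cfg.c_m
    dw = cfg.phi_w * lam * (w_inf - w)
    return dv, dw


def _ml_batch(cfg: MorrisLecarConfig, length: float, pulse_times: np.ndarray,
              amplitude: float, duration: float,
              rngs: Sequence[np.random.Generator]) -> list[np.ndarray]:
    """Stochastic-Heun integration of a batch of Morris–Lecar trials."""
    h = cfg.time_step
    n = len(pulse_times)
    n_steps = int(math.ceil(length / h))
    sig_step = cfg.noise_sd * math.sqrt(h) / cfg.c_m
    noisy = cfg.noise_sd > 0
    if noisy:
        noise = np.empty((n, n_steps))
        for i, rng in enumerate(rngs):
            noise[i] = rng.standard_normal(n_steps)

    v = np.full(n, cfg.v_l)
    w = 0.5 * (1.0 + np.tanh((v - cfg.v3) / cfg.v4))
    tp = pulse_times
    last_spike = np.full(n, -np.inf)
    spikes: list[list[float]] = [[] for _ in range(n)]
    for k in range(n_steps):
        t0 = k * h
        ov = np.clip(np.minimum(t0 + h, tp + duration) - np.maximum(t0, tp), 0.0, h) / h
        i_eff = cfg.i_drive + amplitude * ov
        dn = sig_step * noise[:, k] if noisy else 0.0
        dv1, dw1 = _ml_drift(cfg, v, w, i_eff)
        v_pred = v + dv1 * h + dn
        w_pred = w + dw1 * h
        dv2, dw2 = _ml_drift(cfg, v_pred, w_pred, i_eff)
        v_new = v + 0.5 * (dv1 + dv2) * h + dn
        w_new = w + 0.5 * (dw1 + dw2) * h
        if not np.all(np.isfinite(v_new)):
            raise ValidationError(f"Morris-Lecar integration blew up at step {k} (t={t0:.3f} ms)")
        crossed = (v < cfg.spike_threshold) & (v_new >= cfg.spike_threshold) \
            & (t0 - last_spike > cfg.refractory)
        if crossed.any():
            idx = np.nonzero(crossed)[0]
            frac = (cfg.spike_threshold - v[idx]) / (v_new[idx] - v[idx])
            for i, f in zip(idx, frac):
                ts = t0 + h * float(f)
                spikes[i].append(ts)
                last_spike[i] = ts
        v, w = v_new, w_new
    return [np.array([t for t in s if t <= length]) for s in spikes]


def simulate_morris_lecar(cfg: MorrisLecarConfig, protocol: ProtocolSpec,
                          seed: int) -> TrialEnsemble:
    """Simulate a Morris–Lecar trial ensemble under a pulse protocol."""
    if cfg.time_step > protocol.pulse_duration:
        raise ValidationError("time step larger than the pulse duration")
    rngs = _spawn_rngs(seed, protocol.n_trials)
    pulse_times = protocol.draw_pulse_times(rngs)
    spike_lists: list[np.ndarray] = []
    chunk = 2000
    for c0 in range(0, protocol.n_trials, chunk):
        c1 = min(c0 + chunk, protocol.n_trials)
        spike_lists.extend(
            _ml_batch(cfg, protocol.length, pulse_times[c0:c1],
                      protocol.amplitude, protocol.pulse_duration, rngs[c0:c1])
        )
    if all(len(s) == 0 for s in spike_lists):
        raise ValidationError("Morris-Lecar produced no spikes: check drive/parameters")
    return _assemble(spike_lists, pulse_times, protocol, {"model": "morris_lecar", "seed": seed})


# ---------------------------------------------------------------------------
# noise calibration
# ---------------------------------------------------------------------------

def calibrate_noise_sd(cfg: IntegrateAndFireConfig, target_cv: float, seed: int,
                       n_isis: int = 5000, tol: float = 0.005,
                       max_iter: int = 8) -> tuple[IntegrateAndFireConfig, float]:
    """Tune the white-noise intensity so baseline ISI CV hits ``target_cv``.

    Returns ``(config with tuned noise_sd, achieved CV)``.  The initial
    guess comes from the diffusion approximation CV ≈ σ·R_eff·√T̄ /
    (C_eff·(V_th − V_reset)) and is refined by fixed-point iteration
    (CV is very nearly proportional to σ), re-simulating ~``n_isis``
    unperturbed ISIs per iterate with a fixed seed.
    """
    T = if_period(cfg)
    rng_v = cfg.v_thresh - cfg.v_reset
    sigma = target_cv * rng_v * cfg.capacitance / math.sqrt(T)
    isis_per_trial = 40
    length = (isis_per_trial + 1) * T
    n_trials = max(1, int(math.ceil(n_isis / isis_per_trial)))
    achieved = math.nan
    for _ in range(max_iter):
        trial_cfg = replace(cfg, noise_sd=sigma)
        rngs = _spawn_rngs(seed, n_trials)
        spike_lists = []
        chunk = 2000
        times = np.zeros(n_trials)
        for c0 in range(0, n_trials, chunk):
            c1 = min(c0 + chunk, n_trials)
            spike_lists.extend(_if_batch(trial_cfg, length, times[c0:c1], 0.0, 0.5, rngs[c0:c1]))
        isis = np.concatenate([np.diff(s) for s in spike_lists if len(s) >= 2])
        achieved = float(isis.std() / isis.mean())
        if abs(achieved - target_cv) <= tol:
            break
        sigma *= target_cv / achieved
    return replace(cfg, noise_sd=sigma), achieved


# ---------------------------------------------------------------------------
# config-file umbrella
# ---------------------------------------------------------------------------

_MODEL_CONFIGS = {
    "jittered_periodic": JitteredPeriodicConfig,
    "integrate_and_fire": IntegrateAndFireConfig,
    "morris_lecar": MorrisLecarConfig,
}

_SIMULATORS = {
    "jittered_periodic": simulate_jittered_periodic,
    "integrate_and_fire": simulate_integrate_and_fire,
    "morris_lecar": simulate_morris_lecar,
}


@dataclass
class SimulatorConfig:
    """A full simulation recipe: model + parameters + protocol + seed.

    Mirrors the structured-text (YAML) config format of the CLI.  Seeds are
    mandatory — no wall-clock seeding, so every run is reproducible.
    """

    model: str
    params: dict
    protocol: ProtocolSpec
    seed: int
    calibrate_cv: float | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "SimulatorConfig":
        d = dict(d)
        model = d.pop("model")
        if model not in _MODEL_CONFIGS:
            raise ValidationError(f"unknown model {model!r}; choose from {sorted(_MODEL_CONFIGS)}")
        if "seed" not in d:
            raise ValidationError("config must specify a seed")
        proto = d.pop("protocol")
        if "pulse_window" in proto and proto["pulse_window"] is not None:
            proto["pulse_window"] = tuple(proto["pulse_window"])
        params = d.pop("params", {})
        if params.get("tau") in ("inf", "infinite", None) and "tau" in params:
            params["tau"] = math.inf
        return cls(model=model, params=params, protocol=ProtocolSpec(**proto),
                   seed=int(d.pop("seed")), calibrate_cv=d.pop("calibrate_cv", None))

    def run(self) -> tuple[TrialEnsemble, float | None]:
        """Build the model config and simulate; returns (ensemble, achieved CV or None)."""
        model_cfg = _MODEL_CONFIGS[self.model](**self.params)
        achieved = None
        if self.calibrate_cv is not None:
            if self.model != "integrate_and_fire":
                raise ValidationError("calibrate_cv is supported for integrate_and_fire only")
            model_cfg, achieved = calibrate_noise_sd(model_cfg, self.calibrate_cv,
                                                     seed=self.seed + 1)
        return _SIMULATORS[self.model](model_cfg, self.protocol, self.seed), achieved
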