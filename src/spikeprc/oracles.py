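"""Ground-truth phase response curves.

Closed forms exist for both integrate-and-fire models.  A pulse delivering
charge Q = A·d kicks the membrane by ΔV = Q/C.

*Non-leaky* (perfect integrator): the kick advances the threshold crossing
by the same amount at every phase, so the PRC is the constant
ΔV/(V_th − V_reset) — a square, phase-independent curve.

*Leaky*: with unperturbed voltage V(φT) = V_∞(1 − e^(−φT/τ)) (measured
from reset), a subthreshold kick advances the next spike by
Δt = τ·ln[(V_∞ − V(φT)) / (V_∞ − V(φT) − ΔV)], giving a monotonically
increasing PRC value Δt/T; if the kick reaches threshold the spike is
immediate and the value is exactly 1 − φ.  An exact finite-duration
(rectangular-pulse) variant is available via ``pulse_duration``, since at
τ = 5 ms a 0.5 ms rectangle is measurably different from an idealized kick.

For any deterministic simulator, :func:`direct_perturbation_prc` is the
universal numerical oracle: establish the period on an unperturbed run,
then re-run once per grid phase with a single pulse and measure the ISI
change — the "no-noise pendant" that noisy estimates are validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .simulators import (
    IntegrateAndFireConfig,
    ProtocolSpec,
    if_period,
    pulse_delta_v,
)
from .trials import ValidationError

__all__ = [
    "OracleCurve",
    "nonleaky_if_prc",
    "leaky_if_prc",
    "direct_perturbation_prc",
]


@dataclass(frozen=True)
class OracleCurve:
    """A ground-truth PRC on a phase grid in [0, 1]."""

    grid: np.ndarray
    values: np.ndarray
    provenance: str  # "closed_form" | "direct_perturbation"
    model: str
    params: dict = field(default_factory=dict)
    suprathreshold: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("oracle curve contains non-finite values")

    @property
    def mean(self) -> np.ndarray:  # duck-type as a PRCCurve for prc_error
        return self.values

    @property
    def max(self) -> float:
        return float(np.max(np.abs(self.values)))


def _grid(grid_n: int) -> np.ndarray:
    return np.linspace(0.0, 1.0, grid_n)


def nonleaky_if_prc(cfg: IntegrateAndFireConfig, amplitude: float,
                    duration: float | None = None, delta_v: float | None = None,
                    grid_n: int = 101, allow_suprathreshold: bool = False) -> OracleCurve:
    """Square PRC of the perfect integrator: constant ΔV/(V_th − V_reset).

    A kick that alone reaches threshold (ΔV ≥ V_th − V_reset) fires the
    cell immediately at every phase; that degenerate curve (1 − φ) is only
    returned under ``allow_suprathreshold``.
    """
    if delta_v is None:
        delta_v = pulse_delta_v(cfg, amplitude, 0.5 if duration is None else duration)
    rng_v = cfg.v_thresh - cfg.v_reset
    g = _grid(grid_n)
    if delta_v >= rng_v:
        if not allow_suprathreshold:
            raise ValidationError("pulse alone fires the cell (ΔV >= threshold range)")
        return OracleCurve(g, 1.0 - g, "closed_form", "if_nonleaky",
                           {"delta_v": delta_v}, suprathreshold=True)
    return OracleCurve(g, np.full_like(g, delta_v / rng_v), "closed_form",
                       "if_nonleaky", {"delta_v": delta_v})


def leaky_if_prc(cfg: IntegrateAndFireConfig, amplitude: float,
                 duration: float | None = None, delta_v: float | None = None,
                 grid_n: int = 101) -> OracleCurve:
    """Exact PRC of the leaky integrate-and-fire neuron.

    With ``duration=None`` the pulse is an instantaneous kick of
    ``delta_v`` (default A·0.5/C).  With a finite ``duration`` the exact
    rectangular-pulse solution is used: the membrane relaxes toward the
    elevated asymptote during the pulse and toward V_∞ afterwards, with
    the threshold crossing computed in whichever segment it occurs.
    The curve is monotone non-decreasing on the subthreshold branch and
    equals 1 − φ on the immediate-spike branch.
    """
    if not cfg.leaky:
        raise ValidationError("use nonleaky_if_prc for the non-leaky model")
    tau, R = cfg.tau, cfg.r_m
    rng_v = cfg.v_thresh - cfg.v_reset
    v_inf = cfg.i_drive * R - cfg.v_reset  # measured from reset
    if v_inf <= rng_v:
        raise ValidationError("no limit cycle: subthreshold drive")
    T = if_period(cfg)
    g = _grid(grid_n)
    v_phi = v_inf * (1.0 - np.exp(-g * T / tau))  # unperturbed voltage above reset

    if duration is None:
        dv = pulse_delta_v(cfg, amplitude, 0.5) if delta_v is None else delta_v
        if dv <= 0:
            raise ValidationError("kick size must be > 0")
        sub = v_phi + dv < rng_v
        vals = np.empty_like(g)
        with np.errstate(divide="ignore"):
            vals[sub] = tau * np.log((v_inf - v_phi[sub]) / (v_inf - v_phi[sub] - dv)) / T
        vals[~sub] = 1.0 - g[~sub]
        params = {"delta_v": dv, "tau": tau}
    else:
        # exact rectangular pulse of given amplitude/duration starting at φT
        v_inf_p = (cfg.i_drive + amplitude) * R - cfg.v_reset
        vals = np.empty_like(g)
        for i, (phi, v0) in enumerate(zip(g, v_phi)):
            t_unp = T  # unperturbed crossing time from the reference spike
            t0 = phi * T
            if v_inf_p > rng_v:
                t_in = tau * math.log((v_inf_p - v0) / (v_inf_p - rng_v))
            else:
                t_in = math.inf
            if t_in <= duration:          # fires during the pulse
                t_cross = t0 + t_in
            else:                          # relax from end-of-pulse voltage
                v1 = v_inf_p - (v_inf_p - v0) * math.exp(-duration / tau)
                t_cross = t0 + duration + tau * math.log((v_inf - v1) / (v_inf - rng_v))
            vals[i] = (t_unp - t_cross) / T
        params = {"amplitude": amplitude, "duration": duration, "tau": tau}
    return OracleCurve(g, vals, "closed_form", "if_leaky", params)


def direct_perturbation_prc(simulate_fn, cfg, amplitude: float, duration: float = 0.5,
                            grid_n: int = 41, settle_periods: int = 8,
                            period_tol: float = 1e-4, probe_len: float = 2000.0) -> OracleCurve:
    """Numerical no-noise PRC of any deterministic simulator.

    ``simulate_fn(cfg, protocol, seed) -> TrialEnsemble`` must be one of the
    package simulators (or anything matching that interface) configured with
    zero noise.  Procedure: one unperturbed run establishes the period T and
    a settled reference spike; then, for each grid phase φ, a fresh run
    injects one pulse at reference + φT and the PRC value is
    (T − perturbed ISI)/T.  Deterministic: repeated calls are bit-identical.
    """
    noise = getattr(cfg, "noise_sd", 0.0)
    if noise != 0.0:
        raise ValidationError("direct perturbation requires a zero-noise configuration")

    # unperturbed run: establish period and reference spike
    probe = ProtocolSpec(baseline=1.0, length=probe_len, pulse_amplitude=0.0,
                         pulse_duration=duration, pulse_time=probe_len / 2, n_trials=1)
    spikes = simulate_fn(cfg, probe, seed=0).trials[0].spikes
    if spikes.size < settle_periods + 4:
        raise ValidationError("non-periodic dynamics: too few spikes in the probe run")
    isis = np.diff(spikes)
    late = isis[settle_periods:]
    T = float(late.mean())
    if late.std() > period_tol * T:
        raise ValidationError("non-periodic dynamics: late ISIs not constant")
    s_ref = float(spikes[settle_periods])

    grid = _grid(grid_n)
    pulse_times = s_ref + grid * T
    length = float(pulse_times.max() + duration + 3 * T)
    proto = ProtocolSpec(baseline=1.0, length=length, pulse_amplitude=amplitude,
                         pulse_duration=duration, pulse_times=list(pulse_times),
                         n_trials=grid_n)
    ens = simulate_fn(cfg, proto, seed=0)
    vals = np.empty(grid_n)
    for i, trial in enumerate(ens.trials):
        after = trial.spikes[trial.spikes > s_ref + 1e-9]
        if after.size == 0:
            raise ValidationError("perturbed run lost periodicity: no spike after reference")
        vals[i] = (T - (after[0] - s_ref)) / T
    return OracleCurve(grid, vals, "direct_perturbation",
                       getattr(cfg, "model", type(cfg).__name__),
                       {"amplitude": amplitude, "duration": duration, "period": T})
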