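"""Phase response curve estimation from pulse-perturbed spike trains.

Two point extractors are provided.  The *traditional* estimator references
each trial's pulse to the spike immediately preceding it:

    phase  φ = (t_pulse − s_0) / T̄
    value  F = (T̄ − (s_1 − s_0)) / T̄

with s_0 the last spike at or before the pulse, s_1 the first spike after
it, and T̄ the unperturbed mean ISI.  Causality forces F ≤ 1 − φ: the plane
region above that line (the "Bermuda triangle") is empty, and under ISI
jitter this boundary depletes late-phase sampling and biases the running
average downward.

The *corrected* estimator takes several spikes as the reference, one at a
time.  Every pre-pulse spike s with raw phase (t_pulse − s)/T̄ < m_pre + 1
contributes a band-1 point at the folded phase

    phase  φ = raw − ⌊raw⌋
    value  F = ((m+1)·T̄ − (s_1 − s)) / T̄ ,

where m is the realized number of spikes between s and the pulse (the
cumulative construction over the intervening ISIs).  Selecting references
by raw phase and folding by its integer part makes the pooled phase
sampling exactly homogeneous — each spike in the window contributes once,
and points reassigned to a neighboring cycle by jitter land where their
values belong — which is what cancels the late-phase depletion bias.  For
m = 1 both coordinates are independent of the jitter of s_0.  A small
residual bias of selection origin survives within ~2 jitter-sd of the
phase-interval edges (the first post-pulse spike must follow the pulse, a
constraint no choice of reference can remove); the correction eliminates
most, not all, of the traditional bias.  Spikes after the pulse act as
references for the following intervals (bands 2, 3, …), quantifying how
the pulse affects subsequent ISIs; band k lives on the phase interval
[−(k−1), −(k−2)].

Point tables are plain :class:`pandas.DataFrame` objects with columns
``trial_id, band, ref_offset, phase, value`` (the on-disk TSV dialect).
"""

from __future__ import annotations

import math

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .trials import ISIStats, TrialEnsemble, ValidationError, usable_trials

__all__ = [
    "PRCPoint",
    "PhaseHistogram",
    "PRCCurve",
    "PeakStats",
    "band_interval",
    "traditional_points",
    "corrected_points",
    "control_points",
    "phase_histogram",
    "smooth_curve",
    "binned_means",
    "causality_violations",
    "peak_to_baseline",
    "prc_error",
    "classify_curve",
]

POINT_COLUMNS = ["trial_id", "band", "ref_offset", "phase", "value"]

#: numeric tolerance on the causality bound F <= 1 - phase
CAUSALITY_TOL = 1e-12


class PRCPoint(NamedTuple):
    """One (phase, phase-shift) sample; row type of the point tables."""

    trial_id: str
    band: int
    ref_offset: int
    phase: float
    value: float


def band_interval(band: int) -> tuple[float, float]:
    """Canonical phase interval of a band: [0,1] for band 1, [−(k−1),−(k−2)] for k ≥ 2."""
    if band < 1:
        raise ValueError(f"band must be >= 1, got {band}")
    if band == 1:
        return (0.0, 1.0)
    return (-(band - 1.0), -(band - 2.0))


def _points_frame(rows: list[tuple]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=POINT_COLUMNS)
    df["band"] = df["band"].astype(int)
    df["ref_offset"] = df["ref_offset"].astype(int)
    return df


def traditional_points(
    ensemble: TrialEnsemble,
    stats: ISIStats,
    drop_phase_gt_1: bool = False,
) -> pd.DataFrame:
    """One PRC point per usable trial, referenced to the spike just before the pulse.

    Points with phase > 1 (the pulse fell beyond one mean period after s_0,
    possible under jitter) are retained by default; deleting them
    (``drop_phase_gt_1=True``) reproduces the variant that, notably, does
    *not* remove the late-phase bias.
    """
    T = stats.mean_isi
    rows = []
    for t in usable_trials(ensemble):
        i0 = t.n_before() - 1          # index of s_0 (last spike <= pulse)
        s0, s1 = t.spikes[i0], t.spikes[i0 + 1]
        phase = (t.pulse.time - s0) / T
        value = (T - (s1 - s0)) / T
        rows.append((t.trial_id, 1, 0, phase, value))
    if not rows:
        raise ValidationError("no usable trials")
    df = _points_frame(rows)
    if drop_phase_gt_1:
        df = df[df["phase"] <= 1.0].reset_index(drop=True)
    return df


def corrected_points(
    ensemble: TrialEnsemble,
    stats: ISIStats,
    m_pre: int = 1,
    n_post: int = 4,
    cumulative_post: bool = False,
) -> pd.DataFrame:
    """Multi-reference PRC points: every spike is the reference, one at a time.

    Band 1 pools the references s_0 … s_{−m_pre} (cumulative construction,
    see module docstring).  Bands 2 … n_post+1 use the 1st … n_post-th spike
    after the pulse as reference and report the per-interval phase shift of
    the ISI starting there (``cumulative_post=True`` reports the total
    accumulated shift instead).  Trials with fewer surrounding spikes
    contribute only the bands they can.
    """
    if m_pre < 0 or n_post < 0:
        raise ValueError("m_pre and n_post must be >= 0")
    T = stats.mean_isi
    rows = []
    for t in usable_trials(ensemble):
        i0 = t.n_before() - 1
        spikes = t.spikes
        s1 = spikes[i0 + 1]
        # Band 1: pre-pulse spikes as references, one at a time.  Two details
        # make the pooled phase sampling exactly homogeneous (and with it the
        # late-phase bias cancel): (i) references are selected by *raw phase*
        # (t_pulse - s)/T̄ < m_pre + 1, not by spike index, so each spike in
        # the window contributes exactly once and the selection boundary is
        # crisp; (ii) the displayed phase folds the raw phase by its integer
        # part, so that when jitter reassigns the pulse to a neighboring
        # cycle the point lands where its value belongs.  The value keeps the
        # realized-index cumulative form ((m+1)·T̄ - (s_1 - s_{-m}))/T̄.
        for j in range(i0, -1, -1):
            raw = (t.pulse.time - spikes[j]) / T
            if raw >= m_pre + 1:
                break
            m = i0 - j
            phase = raw - math.floor(raw)
            value = ((m + 1) * T - (s1 - spikes[j])) / T
            rows.append((t.trial_id, 1, m, phase, value))
        # bands k >= 2: reference s_{k-1}, the (k-1)-th spike after the pulse
        n_av = spikes.size - (i0 + 1)  # spikes after the pulse
        for k in range(2, 2 + n_post):
            if k > n_av:  # need s_k, i.e. k spikes after the pulse
                break
            s_ref, s_k = spikes[i0 + k - 1], spikes[i0 + k]
            phase = (t.pulse.time - s_ref) / T
            if cumulative_post:
                value = (k * T - (s_k - spikes[i0])) / T
            else:
                value = (T - (s_k - s_ref)) / T
            rows.append((t.trial_id, k, -(k - 1), phase, value))
    if not rows:
        raise ValidationError("no usable trials")
    return _points_frame(rows)


def control_points(
    ensemble: TrialEnsemble,
    stats: ISIStats,
    virtual_pulse_time: float,
    method: str = "corrected",
    **kwargs,
) -> pd.DataFrame:
    """Control PRC (cPRC) points: a virtual 0 pA pulse at ``virtual_pulse_time``.

    The cPRC should be zero at every phase; the traditional estimator's cPRC
    nevertheless dips at late phases under ISI jitter, which is the bias
    signature this package quantifies.  Only the unperturbed (pre-real-pulse)
    span of each trial is used.
    """
    control = ensemble.with_control_pulse(virtual_pulse_time)
    if method == "traditional":
        return traditional_points(control, stats, **kwargs)
    if method == "corrected":
        return corrected_points(control, stats, **kwargs)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# histograms and smoothing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseHistogram:
    """Counts of sampled phases over a band's canonical interval.

    Points outside the interval are tallied in ``overflow_low`` /
    ``overflow_high``, never silently dropped.
    """

    band: int
    edges: np.ndarray
    counts: np.ndarray
    overflow_low: int
    overflow_high: int

    @property
    def n_in_interval(self) -> int:
        return int(self.counts.sum())


def phase_histogram(points: pd.DataFrame, band: int, n_bins: int) -> PhaseHistogram:
    """Histogram of sampled phases for one band."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    sel = points.loc[points["band"] == band, "phase"].to_numpy()
    if sel.size == 0:
        raise ValidationError(f"no points in band {band}")
    lo, hi = band_interval(band)
    edges = np.linspace(lo, hi, n_bins + 1)
    inside = (sel >= lo) & (sel <= hi)
    counts, _ = np.histogram(sel[inside], bins=edges)
    return PhaseHistogram(
        band=band,
        edges=edges,
        counts=counts,
        overflow_low=int((sel < lo).sum()),
        overflow_high=int((sel > hi).sum()),
    )


@dataclass(frozen=True)
class PRCCurve:
    """Gaussian-kernel moving average of raw PRC points on a phase grid.

    ``reliable`` flags nodes whose effective sample size reaches the floor;
    unreliable nodes carry NaN means rather than a silent 0.
    """

    band: int
    grid: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_eff: np.ndarray
    reliable: np.ndarray
    bandwidth: float

    def interval(self) -> tuple[float, float]:
        return float(self.grid[0]), float(self.grid[-1])


def smooth_curve(
    points: pd.DataFrame,
    band: int = 1,
    bandwidth: float = 0.05,
    grid_n: int = 101,
    min_n_eff: float = 5.0,
) -> PRCCurve:
    """Nadaraya–Watson kernel regression of PRC value on phase.

    At each grid node x the estimate is Σ w_i v_i / Σ w_i with Gaussian
    weights w_i = exp(−(φ_i − x)² / 2h²), truncated at 3 bandwidths (no
    wrap-around: phase within a band is not periodic, so edge nodes simply
    renormalize over the one-sided neighborhood).  The standard error is the
    weighted sd divided by √n_eff with n_eff = (Σw)²/Σw².
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    sel = points[points["band"] == band]
    if len(sel) < 10:
        raise ValidationError(f"need >= 10 points in band {band}, got {len(sel)}")
    phases = sel["phase"].to_numpy()
    values = sel["value"].to_numpy()
    lo, hi = band_interval(band)
    grid = np.linspace(lo, hi, grid_n)

    # pairwise |phase - node| with 3h truncation; grid_n x n_points
    d = np.abs(phases[None, :] - grid[:, None])
    w = np.exp(-0.5 * (d / bandwidth) ** 2)
    w[d > 3.0 * bandwidth] = 0.0
    sw = w.sum(axis=1)
    sw2 = (w**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (w @ values) / sw
        var = (w @ values**2) / sw - mean**2
        var = np.clip(var, 0.0, None)
        n_eff = np.where(sw2 > 0, sw**2 / sw2, 0.0)
        se = np.sqrt(var / np.maximum(n_eff, 1.0))
    reliable = (sw > 0) & (n_eff >= min_n_eff)
    mean[~reliable] = np.nan
    se[~reliable] = np.nan
    return PRCCurve(
        band=band, grid=grid, mean=mean, se=se,
        n_eff=n_eff, reliable=reliable, bandwidth=bandwidth,
    )


def binned_means(
    points: pd.DataFrame,
    band: int = 1,
    n_bins: int = 20,
    cluster_by_trial: bool = True,
) -> pd.DataFrame:
    """Per-bin mean and standard error of PRC values over the band interval.

    With ``cluster_by_trial`` (default) the SE accounts for within-trial
    correlation of multi-reference points (cluster-robust over trial_id);
    points from the same trial share spike jitter, so the naive SE would be
    anti-conservative.

    Returns a frame with columns ``bin_lo, bin_hi, center, n, mean, se``.
    """
    sel = points[points["band"] == band]
    if sel.empty:
        raise ValidationError(f"no points in band {band}")
    lo, hi = band_interval(band)
    edges = np.linspace(lo, hi, n_bins + 1)
    out = []
    phase = sel["phase"].to_numpy()
    for i in range(n_bins):
        hi_edge = (phase < edges[i + 1]) if i < n_bins - 1 else (phase <= edges[i + 1])
        in_bin = (phase >= edges[i]) & hi_edge
        sub = sel[in_bin]
        n = len(sub)
        if n == 0:
            out.append((edges[i], edges[i + 1], (edges[i] + edges[i + 1]) / 2, 0, np.nan, np.nan))
            continue
        m = sub["value"].mean()
        if cluster_by_trial and sub["trial_id"].nunique() > 1:
            g = sub.groupby("trial_id")["value"]
            resid_sums = g.sum() - g.count() * m
            c = len(resid_sums)
            se = np.sqrt(c / (c - 1) * (resid_sums**2).sum()) / n
        elif n > 1:
            se = sub["value"].std(ddof=1) / np.sqrt(n)
        else:
            se = np.nan
        out.append((edges[i], edges[i + 1], (edges[i] + edges[i + 1]) / 2, n, m, se))
    return pd.DataFrame(out, columns=["bin_lo", "bin_hi", "center", "n", "mean", "se"])


# ---------------------------------------------------------------------------
# diagnostics and summary statistics
# ---------------------------------------------------------------------------

def causality_violations(points: pd.DataFrame) -> pd.DataFrame:
    """Traditional band-1 points violating F ≤ 1 − φ.

    The region F > 1 − φ is unreachable for physically generated data (the
    next spike cannot precede the pulse), so any returned row signals
    corrupted input or an estimator bug.
    """
    sel = points[(points["band"] == 1) & (points["ref_offset"] == 0)]
    mask = sel["value"] > 1.0 - sel["phase"] + CAUSALITY_TOL
    return sel[mask]


@dataclass(frozen=True)
class PeakStats:
    """Early/late extrema of a smoothed band-1 curve and their ratio.

    ``early`` (f_e) is the largest-magnitude value on phases [0, 0.5],
    ``late`` (f_l) the same on [0.5, 1]; the peak-to-baseline ratio
    R = f_l / f_e is ≈1 for flat (phase-independent) curves and >1 for
    late-peaked ones.
    """

    early: float
    late: float
    ratio: float
    label: str


def peak_to_baseline(curve: PRCCurve, eps: float = 1e-6) -> PeakStats:
    """Peak-to-baseline statistics of a band-1 smoothed curve."""
    if curve.band != 1:
        raise ValueError("peak-to-baseline is defined on the band-1 curve")
    first = curve.grid <= 0.5
    second = curve.grid >= 0.5
    for half, name in ((first, "early"), (second, "late")):
        bad = (~curve.reliable[half]).mean()
        if bad > 0.20:
            raise ValidationError(f"insufficient sampling: {bad:.0%} of the {name} half unreliable")
    def extremum(mask: np.ndarray) -> float:
        vals = curve.mean[mask & curve.reliable]
        return float(vals[np.argmax(np.abs(vals))])
    f_e, f_l = extremum(first), extremum(second)
    if abs(f_e) < eps:
        return PeakStats(early=f_e, late=f_l, ratio=float("nan"), label="ambiguous")
    return PeakStats(early=f_e, late=f_l, ratio=f_l / f_e, label="")


def classify_curve(stats: PeakStats, tolerance: float = 0.5) -> str:
    """Classify a PRC as phase-independent, phase-dependent, or ambiguous.

    Phase-independent if R ∈ [1/(1+tol), 1+tol]; phase-dependent if R
    exceeds the band (late peak dominates); ambiguous otherwise (undefined,
    negative, or early-dominated ratios).
    """
    r = stats.ratio
    if not np.isfinite(r):
        return "ambiguous"
    if 1.0 / (1.0 + tolerance) <= r <= 1.0 + tolerance:
        return "phase-independent"
    if r > 1.0 + tolerance:
        return "phase-dependent"
    return "ambiguous"


def prc_error(curve: PRCCurve, reference) -> float:
    """Integral of |curve − reference| over the common phase interval.

    ``reference`` is a :class:`PRCCurve` or any object with ``grid`` and
    value arrays (oracle curves qualify); it is linearly interpolated onto
    the curve's grid.  Trapezoidal rule; identical curves give exactly 0.
    """
    ref_grid = np.asarray(reference.grid, dtype=float)
    ref_vals = getattr(reference, "mean", None)
    if ref_vals is None:
        ref_vals = reference.values
    ref_vals = np.asarray(ref_vals, dtype=float)
    ok = np.isfinite(ref_vals)
    ref_grid, ref_vals = ref_grid[ok], ref_vals[ok]
    if ref_grid.size < 2:
        raise ValidationError("reference curve has fewer than 2 finite nodes")
    lo = max(curve.grid[0], ref_grid[0])
    hi = min(curve.grid[-1], ref_grid[-1])
    if hi <= lo:
        raise ValidationError("disjoint grids")
    mask = (curve.grid >= lo) & (curve.grid <= hi) & curve.reliable
    x = curve.grid[mask]
    if x.size < 2:
        raise ValidationError("fewer than 2 reliable nodes on the common interval")
    diff = np.abs(curve.mean[mask] - np.interp(x, ref_grid, ref_vals))
    return float(np.trapezoid(diff, x))
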