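"""Spike-train trial containers, delimited-text I/O, and baseline ISI statistics.

A *trial* is one stimulation sweep: a strictly increasing sequence of spike
times (ms), a single rectangular current pulse, and the sweep length.  A
*trial ensemble* pools sweeps recorded (or simulated) under one protocol and
is the input to every PRC estimator.

Time is in milliseconds throughout the package; phases are dimensionless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "PulseEvent",
    "Trial",
    "TrialEnsemble",
    "ISIStats",
    "ValidationError",
    "read_trials",
    "write_trials",
    "baseline_isi_stats",
    "usable_trials",
]

logger = logging.getLogger(__name__)

#: columns of the long-format trial table, in file order
_COLUMNS = ["trial_id", "record_type", "time_ms", "amplitude_pA", "duration_ms", "length_ms"]

#: float serialization format; 17 significant digits guarantee a bit-exact
#: round trip for IEEE doubles
_FLOAT_FMT = "%.17g"


class ValidationError(ValueError):
    """An invariant of the trial data model was violated."""


@dataclass(frozen=True)
class PulseEvent:
    """A rectangular current pulse.

    Parameters
    ----------
    time:
        Pulse onset, ms from trial start.
    amplitude:
        Pulse amplitude in current units (pA for physical models).  ``0``
        denotes a virtual/control pulse.
    duration:
        Pulse duration in ms; must be positive (default 0.5 ms).
    """

    time: float
    amplitude: float
    duration: float = 0.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValidationError(f"pulse time must be finite and >= 0, got {self.time}")
        if not np.isfinite(self.duration) or self.duration <= 0:
            raise ValidationError(f"pulse duration must be > 0, got {self.duration}")
        if not np.isfinite(self.amplitude):
            raise ValidationError("pulse amplitude must be finite")


@dataclass(frozen=True)
class Trial:
    """One stimulation sweep.

    ``spikes`` must be strictly increasing and contained in ``[0, length]``.
    The usability rule for estimation (>= 2 spikes at or before the pulse,
    >= 1 after) is *not* enforced here; estimators skip unusable trials.
    """

    trial_id: str
    spikes: np.ndarray
    pulse: PulseEvent
    length: float

    def __post_init__(self) -> None:
        spikes = np.asarray(self.spikes, dtype=float)
        object.__setattr__(self, "spikes", spikes)
        if spikes.ndim != 1:
            raise ValidationError(f"trial {self.trial_id}: spikes must be 1-D")
        if spikes.size and not np.all(np.diff(spikes) > 0):
            raise ValidationError(f"trial {self.trial_id}: spike times not strictly increasing")
        if spikes.size and (spikes[0] < 0 or spikes[-1] > self.length):
            raise ValidationError(f"trial {self.trial_id}: spikes outside [0, {self.length}]")
        if not 0 <= self.pulse.time <= self.length:
            raise ValidationError(f"trial {self.trial_id}: pulse time outside trial")

    # -- spike bookkeeping around the pulse ---------------------------------
    # A pulse coincident with a spike belongs to the ISI *beginning* at that
    # spike (half-open convention [s_k, s_{k+1})), so "before" means <= pulse.

    def n_before(self, t: float | None = None) -> int:
        t = self.pulse.time if t is None else t
        return int(np.searchsorted(self.spikes, t, side="right"))

    def n_after(self, t: float | None = None) -> int:
        t = self.pulse.time if t is None else t
        return int(self.spikes.size - self.n_before(t))

    def is_usable(self, t: float | None = None) -> bool:
        return self.n_before(t) >= 2 and self.n_after(t) >= 1


@dataclass
class TrialEnsemble:
    """A non-empty set of trials sharing one pulse protocol.

    All trials must share pulse amplitude and duration; heterogeneous
    ensembles are rejected so that pooled PRC points are comparable.
    """

    trials: Sequence[Trial]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trials = list(self.trials)
        if not self.trials:
            raise ValidationError("ensemble must contain at least one trial")
        amp0, dur0 = self.trials[0].pulse.amplitude, self.trials[0].pulse.duration
        for t in self.trials:
            if t.pulse.amplitude != amp0 or t.pulse.duration != dur0:
                raise ValidationError(
                    f"trial {t.trial_id}: mixed pulse specs in ensemble "
                    f"(({t.pulse.amplitude}, {t.pulse.duration}) vs ({amp0}, {dur0}))"
                )

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    @property
    def pulse_amplitude(self) -> float:
        return self.trials[0].pulse.amplitude

    @property
    def pulse_duration(self) -> float:
        return self.trials[0].pulse.duration

    def with_control_pulse(self, virtual_time: float) -> "TrialEnsemble":
        """Re-stamp every trial with a zero-amplitude pulse at ``virtual_time``.

        Spikes after the *real* pulse of a stimulated trial are perturbed and
        must not enter a control estimate, so they are truncated away.  Trials
        whose truncated train ends before ``virtual_time`` are dropped with a
        logged count.
        """
        vpulse_dur = self.pulse_duration
        kept: list[Trial] = []
        dropped = 0
        for t in self.trials:
            spikes = t.spikes
            if t.pulse.amplitude != 0.0:
                spikes = spikes[spikes <= t.pulse.time]
            if spikes.size and spikes[-1] > virtual_time and virtual_time <= t.length:
                kept.append(
                    Trial(
                        trial_id=t.trial_id,
                        spikes=spikes,
                        pulse=PulseEvent(virtual_time, 0.0, vpulse_dur),
                        length=t.length,
                    )
                )
            else:
                dropped += 1
        if dropped:
            logger.info("control pulse at %g ms: dropped %d/%d trials without "
                        "unperturbed span", virtual_time, dropped, len(self.trials))
        if not kept:
            raise ValidationError("virtual pulse time beyond every trial's unperturbed span")
        return TrialEnsemble(kept, dict(self.metadata))


@dataclass(frozen=True)
class ISIStats:
    """Baseline (pre-pulse) interspike-interval statistics.

    ``mean_isi`` is the unperturbed mean ISI T̄ used as the oscillation
    period; ``cv`` is sd/mean with the population (n) standard deviation.
    """

    mean_isi: float
    cv: float
    n_intervals: int

    def __post_init__(self) -> None:
        if not self.mean_isi > 0:
            raise ValidationError(f"mean ISI must be > 0, got {self.mean_isi}")
        if self.cv < 0:
            raise ValidationError("CV must be >= 0")


def usable_trials(ensemble: TrialEnsemble) -> list[Trial]:
    """Trials satisfying the ">=2 spikes before pulse, >=1 after" rule.

    Unusable sweeps are skipped with a logged count, mirroring the practical
    discard of sweeps in which the pulse missed the spiking epoch.
    """
    good = [t for t in ensemble if t.is_usable()]
    skipped = len(ensemble) - len(good)
    if skipped:
        logger.info("skipped %d/%d unusable trials", skipped, len(ensemble))
    return good


def baseline_isi_stats(ensemble: TrialEnsemble, scope: str = "pooled") -> ISIStats:
    """Mean ISI and CV from unperturbed baseline segments.

    Only intervals ``[s_k, s_{k+1}]`` with ``s_{k+1} <= pulse.time`` qualify:
    no interval containing or following the pulse is ever used.

    Parameters
    ----------
    scope:
        ``"pooled"`` (default) pools all qualifying intervals across trials —
        T̄ is then the ensemble's (the cell's) global mean ISI.
        ``"per_trial"`` averages per-trial mean ISIs instead; the CV is still
        computed on the pooled intervals.
    """
    per_trial: list[np.ndarray] = []
    for t in ensemble:
        pre = t.spikes[t.spikes <= t.pulse.time]
        if pre.size >= 2:
            per_trial.append(np.diff(pre))
    if not per_trial:
        raise ValidationError("no baseline intervals")
    pooled = np.concatenate(per_trial)
    if scope == "pooled":
        mean = float(pooled.mean())
    elif scope == "per_trial":
        mean = float(np.mean([isi.mean() for isi in per_trial]))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    cv = float(pooled.std() / pooled.mean())  # population (n) sd convention
    return ISIStats(mean_isi=mean, cv=cv, n_intervals=int(pooled.size))


# ---------------------------------------------------------------------------
# delimited-text I/O (long format, one file per ensemble)
# ---------------------------------------------------------------------------

def write_trials(ensemble: TrialEnsemble, path: str | Path) -> Path:
    """Write an ensemble as long-format TSV.

    Layout: header row, then per trial one ``meta`` row (length_ms), one
    ``pulse`` row (time_ms, amplitude_pA, duration_ms) and one ``spike`` row
    per spike.  Ensemble metadata is stored in leading ``#`` comment lines.
    Floats carry 17 significant digits so the round trip is bit-exact.
    """
    path = Path(path)
    f = lambda x: _FLOAT_FMT % x  # noqa: E731
    lines: list[str] = []
    for key, val in ensemble.metadata.items():
        lines.append(f"# {key}\t{val}")
    lines.append("\t".join(_COLUMNS))
    for t in ensemble:
        lines.append(f"{t.trial_id}\tmeta\t\t\t\t{f(t.length)}")
        lines.append(f"{t.trial_id}\tpulse\t{f(t.pulse.time)}\t{f(t.pulse.amplitude)}\t{f(t.pulse.duration)}\t")
        for s in t.spikes:
            lines.append(f"{t.trial_id}\tspike\t{f(s)}\t\t\t")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_trials(path: str | Path) -> TrialEnsemble:
    """Read an ensemble written by :func:`write_trials`.

    Raises a parse error naming the offending line for malformed rows, and a
    :class:`ValidationError` for non-monotone spikes or mixed pulse specs.
    """
    path = Path(path)
    metadata: dict = {}
    header_idx = None
    with open(path) as fh:
        raw = fh.read().splitlines()
    for i, line in enumerate(raw):
        if line.startswith("#"):
            body = line[1:].strip()
            if "\t" in body:
                key, val = body.split("\t", 1)
                metadata[key.strip()] = val
            continue
        header_idx = i
        break
    if header_idx is None or raw[header_idx].split("\t") != _COLUMNS:
        raise ValidationError(f"{path}: line {(header_idx or 0) + 1}: missing or bad header row")

    spikes: dict[str, list[float]] = {}
    pulses: dict[str, PulseEvent] = {}
    lengths: dict[str, float] = {}
    order: list[str] = []
    for lineno, line in enumerate(raw[header_idx + 1:], start=header_idx + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(_COLUMNS):
            raise ValidationError(f"{path}: line {lineno}: expected {len(_COLUMNS)} fields, got {len(fields)}")
        tid, rtype = fields[0], fields[1]
        if tid not in spikes:
            spikes[tid] = []
            order.append(tid)
        try:
            if rtype == "spike":
                spikes[tid].append(float(fields[2]))
            elif rtype == "pulse":
                if tid in pulses:
                    raise ValidationError(f"{path}: line {lineno}: duplicate pulse row for trial {tid}")
                pulses[tid] = PulseEvent(float(fields[2]), float(fields[3]), float(fields[4]))
            elif rtype == "meta":
                if tid in lengths:
                    raise ValidationError(f"{path}: line {lineno}: duplicate meta row for trial {tid}")
                lengths[tid] = float(fields[5])
            else:
                raise ValidationError(f"{path}: line {lineno}: unknown record_type {rtype!r}")
        except (ValueError, IndexError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ValidationError(f"{path}: line {lineno}: {exc}") from exc

    trials = []
    for tid in order:
        if tid not in pulses:
            raise ValidationError(f"{path}: trial {tid}: missing pulse row")
        if tid not in lengths:
            raise ValidationError(f"{path}: trial {tid}: missing meta row")
        trials.append(Trial(tid, np.array(spikes[tid], dtype=float), pulses[tid], lengths[tid]))
    return TrialEnsemble(trials, metadata)
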