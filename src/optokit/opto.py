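"""Spike/light alignment statistics: pulse schedules, fidelity, latency,
PSTHs, firing rates, silencing and rebound metrics.

*Spike probability* (fidelity) for a pulse is the number of spikes in the
full inter-pulse window [onset, onset + IPI); with doublets a pulse can
contribute more than one spike, so per-pulse probabilities may exceed 1.
*First-spike latency* is the time from pulse onset to the first spike in
that window; its 1-ms-binned histogram mode characterizes activation
onset.  Silencing epochs are scored per trial as firing rates over the
pre-light, light-on and post-light windows, with any in-light spike
flagging the trial as breakthrough.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError, WrongProtocolError
from .io import SpikeTrain, TTLTrace

_CONTINUOUS_MIN_WIDTH_S = 0.5  # single pulses at least this long => continuous


@dataclass
class PulseSchedule:
    """Light pulses grouped into trains, parsed from TTL."""

    pulses: np.ndarray                      # (n, 2) on/off seconds
    train_slices: list[tuple[int, int]]     # [start, stop) pulse indices
    protocol_kind: str                      # pulse_train | continuous

    @property
    def n_pulses(self) -> int:
        return int(self.pulses.shape[0])

    @property
    def n_trains(self) -> int:
        return len(self.train_slices)

    @property
    def train_onsets_s(self) -> np.ndarray:
        return np.array([self.pulses[a, 0] for a, _ in self.train_slices])

    def train_pulses(self, k: int) -> np.ndarray:
        a, b = self.train_slices[k]
        return self.pulses[a:b]

    def train_ipi_s(self, k: int) -> float:
        """Within-train inter-onset interval (median; NaN for 1 pulse)."""
        p = self.train_pulses(k)[:, 0]
        return float(np.median(np.diff(p))) if p.size > 1 else float("nan")

    def train_frequency_hz(self, k: int) -> float:
        ipi = self.train_ipi_s(k)
        return 1.0 / ipi if np.isfinite(ipi) and ipi > 0 else float("nan")


@dataclass
class FidelityResult:
    """Per-pulse-position spike probabilities and first-spike latencies."""

    per_position_prob: np.ndarray
    sem_per_position: np.ndarray
    mean_prob: float
    sem_prob: float
    latencies_ms: np.ndarray
    latency_mode_ms: float | None
    n_trains: int
    counts: np.ndarray = field(repr=False, default=None)  # (trains, positions)

    @property
    def n_positions(self) -> int:
        return int(self.per_position_prob.size)


@dataclass
class PSTH:
    """Event-aligned binned spike counts over repetitions."""

    bin_edges_s: np.ndarray
    counts: np.ndarray          # summed over events
    n_events: int
    counts_per_event: np.ndarray = field(repr=False, default=None)

    @property
    def bin_centers_s(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_s[:-1] + self.bin_edges_s[1:])

    @property
    def bin_s(self) -> float:
        return float(self.bin_edges_s[1] - self.bin_edges_s[0])

    def rate_hz(self) -> np.ndarray:
        """Counts converted to mean firing rate per bin."""
        return self.counts / (self.n_events * self.bin_s)

    def sem_rate_hz(self) -> np.ndarray:
        """SEM across events, in rate units."""
        per_event_rate = self.counts_per_event / self.bin_s
        sd = per_event_rate.std(axis=0, ddof=1) if self.n_events > 1 else \
            np.zeros(self.counts.size)
        return sd / np.sqrt(self.n_events)


@dataclass
class SilencingResult:
    """Per-trial pre/during/post rates and breakthrough bookkeeping."""

    pre_rate_hz: np.ndarray
    during_rate_hz: np.ndarray
    post_rate_hz: np.ndarray
    breakthrough_spike_counts: np.ndarray
    n_trials: int

    @property
    def n_breakthrough_trials(self) -> int:
        return int(np.count_nonzero(self.breakthrough_spike_counts > 0))

    @property
    def breakthrough_fraction(self) -> float:
        return self.n_breakthrough_trials / self.n_trials

    @property
    def rebound_index_per_trial(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.post_rate_hz / self.pre_rate_hz

    @property
    def rebound_index(self) -> float:
        """Pooled post/pre rate ratio (NaN when no pre-light spikes)."""
        pre = float(np.mean(self.pre_rate_hz))
        return float(np.mean(self.post_rate_hz) / pre) if pre > 0 else float("nan")


# ---------------------------------------------------------------------------


def parse_schedule(ttl: TTLTrace, train_gap_s: float = 1.0) -> PulseSchedule:
    """Group TTL pulses into trains wherever the inter-onset gap exceeds
    ``train_gap_s``; classify the protocol from the pulse shape (single
    long pulses per train => continuous illumination)."""
    pulses = np.asarray(ttl.intervals, dtype=float).reshape(-1, 2)
    if pulses.shape[0] == 0:
        return PulseSchedule(pulses, [], "pulse_train")
    if np.any(pulses[1:, 0] < pulses[:-1, 1]):
        raise ValidationError("overlapping TTL intervals")
    gaps = np.diff(pulses[:, 0])
    breaks = np.flatnonzero(gaps > train_gap_s) + 1
    bounds = np.r_[0, breaks, pulses.shape[0]]
    slices = [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]
    widths = pulses[:, 1] - pulses[:, 0]
    continuous = (
        all(b - a == 1 for a, b in slices)
        and float(np.median(widths)) >= _CONTINUOUS_MIN_WIDTH_S
    )
    return PulseSchedule(pulses, slices,
                         "continuous" if continuous else "pulse_train")


def spike_counts_in_windows(times: np.ndarray, starts: np.ndarray,
                            stops: np.ndarray) -> np.ndarray:
    """Spike count in each half-open window [start, stop)."""
    return (np.searchsorted(times, stops, side="left")
            - np.searchsorted(times, starts, side="left"))


def spike_fidelity(spikes: SpikeTrain, schedule: PulseSchedule,
                   sem_across: str = "positions") -> FidelityResult:
    """Per-pulse spike probabilities for a pulse-train schedule.

    The response window for pulse *i* is the full inter-pulse interval
    [onset_i, onset_i + IPI); the last pulse of a train uses the same
    width.  ``per_position_prob[p]`` is the mean spike count at pulse
    position *p* across trains.  ``sem_prob`` is, by default, the SEM of
    the per-position probabilities across positions (the convention for
    "mean probability over the 100 pulses of a train"); set
    ``sem_across='trains'`` for the SEM of per-train means instead.
    """
    if schedule.protocol_kind != "pulse_train":
        raise WrongProtocolError("spike_fidelity requires a pulse-train schedule")
    if schedule.n_trains < 1:
        raise ValidationError("schedule has no trains")
    sizes = {b - a for a, b in schedule.train_slices}
    if len(sizes) != 1:
        raise ValidationError(
            f"trains have unequal pulse counts {sorted(sizes)}; "
            "fidelity needs a rectangular train x position layout"
        )
    n_pos = sizes.pop()
    t = spikes.times_s

    counts = np.empty((schedule.n_trains, n_pos))
    latencies = []
    for k in range(schedule.n_trains):
        onsets = schedule.train_pulses(k)[:, 0]
        ipi = schedule.train_ipi_s(k)
        if not np.isfinite(ipi):  # single-pulse train: 50 ms default window
            ipi = 0.05
        counts[k] = spike_counts_in_windows(t, onsets, onsets + ipi)
        first = np.searchsorted(t, onsets, side="left")
        has = (first < t.size)
        has[has] &= t[first[has]] < onsets[has] + ipi
        latencies.append((t[first[has]] - onsets[has]) * 1000.0)
    lat = np.concatenate(latencies) if latencies else np.empty(0)

    per_pos = counts.mean(axis=0)
    sem_pos = (counts.std(axis=0, ddof=1) / np.sqrt(schedule.n_trains)
               if schedule.n_trains > 1 else np.zeros(n_pos))
    if sem_across == "positions":
        sem = float(per_pos.std(ddof=1) / np.sqrt(n_pos)) if n_pos > 1 else 0.0
    elif sem_across == "trains":
        per_train = counts.mean(axis=1)
        sem = (float(per_train.std(ddof=1) / np.sqrt(schedule.n_trains))
               if schedule.n_trains > 1 else 0.0)
    else:
        raise ValidationError("sem_across must be 'positions' or 'trains'")
    return FidelityResult(
        per_position_prob=per_pos,
        sem_per_position=sem_pos,
        mean_prob=float(per_pos.mean()),
        sem_prob=sem,
        latencies_ms=np.sort(lat),
        latency_mode_ms=latency_mode(lat),
        n_trains=schedule.n_trains,
        counts=counts,
    )


def latency_mode(latencies_ms, bin_ms: float = 1.0) -> float | None:
    """Center of the maximal 1-ms histogram bin; ties break toward the
    smaller latency.  None for empty input."""
    lat = np.asarray(latencies_ms, dtype=float).ravel()
    if lat.size == 0:
        return None
    n_bins = int(np.floor(lat.max() / bin_ms)) + 1
    counts = np.bincount(np.floor(lat / bin_ms).astype(int), minlength=n_bins)
    k = int(np.argmax(counts))  # argmax returns the first (smallest) maximum
    return (k + 0.5) * bin_ms


def psth(spikes: SpikeTrain, event_times_s, window_s: tuple[float, float],
         bin_s: float) -> PSTH:
    """Event-aligned histogram over ``window_s = (t0, t1)`` relative to
    each event.  Total counts conserve the number of in-window spikes."""
    events = np.asarray(event_times_s, dtype=float).ravel()
    if events.size == 0:
        raise ValidationError("psth requires at least one alignment event")
    t0, t1 = float(window_s[0]), float(window_s[1])
    if not (t1 > t0 and bin_s > 0):
        raise ValidationError("need window end > start and bin_s > 0")
    n_bins = int(round((t1 - t0) / bin_s))
    if n_bins < 1 or abs(n_bins * bin_s - (t1 - t0)) > bin_s * 1e-6 + 1e-12:
        raise ValidationError("bin_s must divide the window length")
    edges = t0 + np.arange(n_bins + 1) * bin_s
    per_event = np.empty((events.size, n_bins))
    t = spikes.times_s
    for i, ev in enumerate(events):
        rel = t[np.searchsorted(t, ev + t0):np.searchsorted(t, ev + t1)] - ev
        per_event[i] = np.histogram(rel, bins=edges)[0] if rel.size else 0.0
    return PSTH(edges, per_event.sum(axis=0), events.size, per_event)


def firing_rate(spikes: SpikeTrain, window: tuple[float, float]) -> float:
    """Spike count in [start, end) divided by the window duration, Hz."""
    start, end = float(window[0]), float(window[1])
    if not end > start:
        raise ValidationError("firing_rate window must have end > start")
    n = int(spike_counts_in_windows(spikes.times_s,
                                    np.array([start]), np.array([end]))[0])
    return n / (end - start)


def silencing_metrics(spikes: SpikeTrain, schedule: PulseSchedule,
                      pre_s: float = 5.0, post_s: float = 5.0
                      ) -> SilencingResult:
    """Per-trial pre/during/post firing rates for continuous-light trials.

    A trial is breakthrough iff ≥ 1 spike falls in its light-on interval.
    Pre/post windows are truncated (with a warning) where they would
    overlap the neighboring trial or run outside the recording.
    """
    if schedule.protocol_kind != "continuous":
        raise WrongProtocolError("silencing_metrics requires continuous light")
    n = schedule.n_pulses
    if n == 0:
        raise ValidationError("schedule has no light epochs")
    pre = np.empty(n)
    during = np.empty(n)
    post = np.empty(n)
    bcounts = np.empty(n, dtype=int)
    truncated = False
    for k, (on, off) in enumerate(schedule.pulses):
        lo = max(on - pre_s, 0.0,
                 schedule.pulses[k - 1, 1] if k > 0 else 0.0)
        hi = min(off + post_s, spikes.duration_s,
                 schedule.pulses[k + 1, 0] if k + 1 < n else np.inf)
        truncated |= (lo > on - pre_s) or (hi < off + post_s)
        pre[k] = firing_rate(spikes, (lo, on)) if on > lo else np.nan
        during[k] = firing_rate(spikes, (on, off))
        post[k] = firing_rate(spikes, (off, hi)) if hi > off else np.nan
        bcounts[k] = spike_counts_in_windows(
            spikes.times_s, np.array([on]), np.array([off]))[0]
    if truncated:
        warnings.warn(
            "pre/post windows truncated to avoid neighboring trials or the "
            "recording edge", stacklevel=2)
    return SilencingResult(pre, during, post, bcounts, n)
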