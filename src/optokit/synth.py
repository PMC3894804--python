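"""Ground-truthed synthetic extracellular sessions.

Emulates the two optogenetic experiments the analysis pipeline targets:

* **ChR2 photoactivation** — trains of brief (default 10 ms) light pulses;
  each pulse evokes a spike with probability ``evoked_prob`` at a latency
  whose 1-ms-binned histogram mode is ``latency_mode_ms`` (default 7 ms),
  occasionally followed by a doublet so the per-pulse spike count can
  exceed one.
* **NpHR photoinhibition** — continuous light epochs (default 10 s)
  during which spontaneous spikes are suppressed with probability
  ``silencing_efficacy``; surviving "breakthrough" spikes are logged per
  trial, and an optional rebound transiently raises the rate after light
  offset.

Spontaneous firing is homogeneous Poisson ("non-phasic") or a sinusoidally
rate-modulated inhomogeneous Poisson ("phasic").  Every generated session
carries its full ground truth (true spike times, evoked flags, per-pulse
counts, per-trial breakthrough flags) so downstream detection and
statistics can be scored exactly.  The voltage trace is i.i.d. Gaussian
noise with one fixed biphasic waveform added per true spike; identical
config + seed gives bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ValidationError
from .io import TTLTrace, VoltageTrace

_BAND_UPPER_HZ = 8000.0  # recording passband upper edge the rate must support


@dataclass
class SynthConfig:
    """Generator parameters.  Voltages in µV, times in the stated units."""

    duration_s: float | None = None  # None: derived from the protocol
    sampling_rate_hz: float = 20_000.0
    noise_sd: float = 10.0
    spike_amplitude: float = -80.0  # negative peak, µV
    spike_width_ms: float = 1.0
    spont_rate_hz: float = 1.0
    spont_mode: str = "poisson"  # poisson | phasic
    phasic_period_s: float = 0.5
    phasic_depth: float = 0.9
    evoked_prob: float = 1.0
    doublet_prob: float = 0.0
    latency_mode_ms: float = 7.0
    latency_jitter_ms: float = 1.5
    silencing_efficacy: float = 1.0
    rebound_gain: float = 1.0
    rebound_tau_s: float = 0.1
    refractory_ms: float = 2.0
    seed: int = 0

    def validate(self) -> "SynthConfig":
        for name in ("evoked_prob", "doublet_prob", "silencing_efficacy",
                     "phasic_depth"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.duration_s is not None and not self.duration_s > 0:
            raise ValidationError("duration_s must be positive")
        if not self.sampling_rate_hz > 2 * _BAND_UPPER_HZ:
            raise ValidationError(
                "sampling_rate_hz must exceed twice the passband upper edge "
                f"({2 * _BAND_UPPER_HZ:.0f} Hz)"
            )
        for name in ("noise_sd", "spont_rate_hz", "latency_jitter_ms",
                     "rebound_tau_s", "refractory_ms"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for name in ("spike_width_ms", "latency_mode_ms", "phasic_period_s",
                     "rebound_gain"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if self.spont_mode not in ("poisson", "phasic"):
            raise ValidationError("spont_mode must be 'poisson' or 'phasic'")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StimProtocol:
    """Light-delivery protocol: pulse trains or continuous epochs."""

    kind: str = "pulse_train"  # pulse_train | continuous
    pulse_width_ms: float = 10.0
    frequency_hz: float = 20.0
    pulses_per_train: int = 100
    n_trains: int = 1
    inter_train_interval_s: float = 120.0
    baseline_s: float = 5.0
    light_duration_s: float = 10.0  # continuous mode only

    def validate(self) -> "StimProtocol":
        if self.kind not in ("pulse_train", "continuous"):
            raise ValidationError("kind must be 'pulse_train' or 'continuous'")
        if self.kind == "pulse_train":
            if not self.pulse_width_ms < 1000.0 / self.frequency_hz:
                raise ValidationError(
                    "pulse_width_ms must be shorter than the inter-pulse "
                    f"interval ({1000.0 / self.frequency_hz:.1f} ms)"
                )
            if self.pulses_per_train < 1:
                raise ValidationError("pulses_per_train must be >= 1")
        else:
            if not self.light_duration_s > 0:
                raise ValidationError("light_duration_s must be positive")
        if self.n_trains < 1:
            raise ValidationError("n_trains must be >= 1")
        if self.baseline_s < 0:
            raise ValidationError("baseline_s must be non-negative")
        if self.n_trains > 1 and not self.inter_train_interval_s > 0:
            raise ValidationError("inter_train_interval_s must be positive")
        return self

    @property
    def ipi_s(self) -> float:
        """Within-train inter-pulse (onset-to-onset) interval."""
        return 1.0 / self.frequency_hz

    def train_onsets_s(self) -> np.ndarray:
        return self.baseline_s + np.arange(self.n_trains) * self.inter_train_interval_s

    def session_duration_s(self) -> float:
        """Default session length: baseline plus one full inter-train slot
        per train, so each train keeps a quiet post-light window."""
        return self.baseline_s + self.n_trains * self.inter_train_interval_s

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Generator event log; the oracle against which analyses are scored."""

    true_spike_times_s: np.ndarray
    evoked_flags: np.ndarray
    per_pulse_counts: np.ndarray | None = None
    per_trial_breakthrough: np.ndarray | None = None

    @property
    def n_spikes(self) -> int:
        return int(self.true_spike_times_s.size)


# ---------------------------------------------------------------------------
# waveform template


def spike_waveform(amplitude: float, width_ms: float,
                   sampling_rate_hz: float) -> np.ndarray:
    """One fixed biphasic extracellular template.

    A single windowless sine cycle spanning ``width_ms``: exactly
    zero-integral, first lobe carries the sign of ``amplitude`` and its
    extremum equals ``amplitude``.  ``amplitude`` of zero gives an all-zero
    template; its sign encodes polarity (negative = conventional
    extracellular trough first).
    """
    if not width_ms > 0:
        raise ValidationError("width_ms must be positive")
    if not sampling_rate_hz > 0:
        raise ValidationError("sampling_rate_hz must be positive")
    n = max(int(round(width_ms * sampling_rate_hz / 1000.0)), 2)
    phase = np.sin(2 * np.pi * np.arange(n) / n)
    if amplitude == 0:
        return np.zeros(n)
    w = np.sign(amplitude) * phase / np.max(np.abs(phase))
    return np.abs(amplitude) * w


def _template_peak_index(template: np.ndarray) -> int:
    return int(np.argmax(np.abs(template))) if template.size else 0


# ---------------------------------------------------------------------------
# spike-time machinery


def _enforce_refractory(times, flags, pulse_idx, refractory_s):
    """Greedy left-to-right pruning to a minimum inter-spike separation."""
    if times.size == 0:
        return times, flags, pulse_idx
    order = np.argsort(times, kind="stable")
    times, flags, pulse_idx = times[order], flags[order], pulse_idx[order]
    keep = np.ones(times.size, dtype=bool)
    last = -np.inf
    for i, t in enumerate(times):
        if t - last < refractory_s:
            keep[i] = False
        else:
            last = t
    return times[keep], flags[keep], pulse_idx[keep]


def _poisson_times(rng, rate_hz, t0, t1):
    if rate_hz <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate_hz * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def _inhomogeneous_times(rng, rate_fn, max_rate_hz, t0, t1):
    """Thinning (Lewis & Shedler) sampler for a bounded rate function."""
    cand = _poisson_times(rng, max_rate_hz, t0, t1)
    if cand.size == 0:
        return cand
    keep = rng.uniform(0, max_rate_hz, size=cand.size) < rate_fn(cand)
    return cand[keep]


def _spontaneous_times(rng, config: SynthConfig, t0, t1):
    r = config.spont_rate_hz
    if config.spont_mode == "poisson" or config.phasic_depth == 0:
        return _poisson_times(rng, r, t0, t1)
    d, period = config.phasic_depth, config.phasic_period_s

    def rate(t):
        return r * (1.0 + d * np.sin(2 * np.pi * t / period))

    return _inhomogeneous_times(rng, rate, r * (1.0 + d), t0, t1)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection sampler; falls back to uniform if the window is extreme."""
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    out = np.empty(size)
    filled = 0
    for _ in range(1000):
        draw = rng.normal(mean, sd, size=size - filled)
        ok = draw[(draw > lo) & (draw < hi)]
        out[filled:filled + ok.size] = ok
        filled += ok.size
        if filled == size:
            return out
    out[filled:] = rng.uniform(lo, hi, size=size - filled)
    return out


def build_ttl(protocol: StimProtocol) -> TTLTrace:
    """Light-on intervals implied by a protocol (pulse onset = first high
    sample; times in seconds from session start)."""
    protocol.validate()
    onsets = []
    if protocol.kind == "pulse_train":
        w = protocol.pulse_width_ms / 1000.0
        for t0 in protocol.train_onsets_s():
            p = t0 + np.arange(protocol.pulses_per_train) * protocol.ipi_s
            onsets.append(np.column_stack([p, p + w]))
    else:
        t0 = protocol.train_onsets_s()
        onsets.append(np.column_stack([t0, t0 + protocol.light_duration_s]))
    return TTLTrace(np.concatenate(onsets), "intervals")


# ---------------------------------------------------------------------------
# session generators


def generate_chr2_events(config: SynthConfig, protocol: StimProtocol
                         ) -> tuple[TTLTrace, GroundTruth]:
    """Event-level ChR2 session: TTL schedule plus ground-truth spikes,
    without rendering the voltage trace (useful for long protocols)."""
    config.validate()
    protocol.validate()
    if protocol.kind != "pulse_train":
        raise ValidationError("generate_chr2_session requires kind='pulse_train'")
    rng = np.random.default_rng(config.seed)
    ttl = build_ttl(protocol)
    duration = config.duration_s or protocol.session_duration_s()

    ipi_ms = protocol.ipi_s * 1000.0
    pulse_onsets = ttl.onsets_s
    n_pulses = pulse_onsets.size
    # Latency distribution: truncated Gaussian whose continuous mode sits at
    # the center of the 1-ms bin labelled latency_mode_ms, so the binned
    # latency histogram peaks in [mode, mode+1) ms.
    lat_center = config.latency_mode_ms + 0.5

    evoked = rng.random(n_pulses) < config.evoked_prob
    lat = _truncated_normal(rng, lat_center, config.latency_jitter_ms,
                            0.0, ipi_ms, n_pulses)
    doublet = evoked & (rng.random(n_pulses) < config.doublet_prob)
    gap = rng.uniform(3.0, 8.0, size=n_pulses)
    doublet &= (lat + gap) < ipi_ms  # second spike stays in the interval

    t_first = pulse_onsets[evoked] + lat[evoked] / 1000.0
    idx_first = np.flatnonzero(evoked)
    t_second = pulse_onsets[doublet] + (lat[doublet] + gap[doublet]) / 1000.0
    idx_second = np.flatnonzero(doublet)

    spont = _spontaneous_times(rng, config, 0.0, duration)
    times = np.concatenate([t_first, t_second, spont])
    flags = np.concatenate([
        np.ones(t_first.size + t_second.size, dtype=bool),
        np.zeros(spont.size, dtype=bool),
    ])
    pulse_idx = np.concatenate([
        idx_first, idx_second, np.full(spont.size, -1, dtype=int)
    ])
    inside = times < duration
    times, flags, pulse_idx = times[inside], flags[inside], pulse_idx[inside]
    times, flags, pulse_idx = _enforce_refractory(
        times, flags, pulse_idx, config.refractory_ms / 1000.0)

    counts = np.bincount(pulse_idx[pulse_idx >= 0], minlength=n_pulses)
    gt = GroundTruth(times, flags, per_pulse_counts=counts)
    return ttl, gt


def generate_chr2_session(config: SynthConfig, protocol: StimProtocol
                          ) -> tuple[VoltageTrace, TTLTrace, GroundTruth]:
    """Full ChR2 photoactivation session: noise trace with one inserted
    waveform per true spike, TTL channel, and the generator's event log."""
    ttl, gt = generate_chr2_events(config, protocol)
    trace = _render_trace(config, gt.true_spike_times_s,
                          config.duration_s or protocol.session_duration_s())
    return trace, ttl, gt


def generate_nphr_events(config: SynthConfig, protocol: StimProtocol
                         ) -> tuple[TTLTrace, GroundTruth]:
    """Event-level NpHR silencing session (no voltage trace)."""
    config.validate()
    protocol.validate()
    if protocol.kind != "continuous":
        raise ValidationError("generate_nphr_session requires kind='continuous'")
    if config.spont_rate_hz == 0:
        warnings.warn("spont_rate_hz is zero: nothing to silence", stacklevel=2)
    rng = np.random.default_rng(config.seed)
    ttl = build_ttl(protocol)
    duration = config.duration_s or protocol.session_duration_s()

    times = _spontaneous_times(rng, config, 0.0, duration)
    # silencing: delete each in-light spike with probability efficacy
    in_light = np.zeros(times.size, dtype=bool)
    for on, off in ttl.intervals:
        in_light |= (times >= on) & (times < off)
    suppressed = in_light & (rng.random(times.size) < config.silencing_efficacy)
    times = times[~suppressed]

    # rebound: extra rate r0*(gain-1)*exp(-dt/tau) after each light offset
    if config.rebound_gain > 1 and config.spont_rate_hz > 0:
        extra_amp = config.spont_rate_hz * (config.rebound_gain - 1.0)
        tau = config.rebound_tau_s
        extras = []
        for _, off in ttl.intervals:
            t1 = min(off + 8 * tau, duration)

            def rate(t, off=off):
                return extra_amp * np.exp(-(t - off) / tau)

            extras.append(_inhomogeneous_times(rng, rate, extra_amp, off, t1))
        times = np.concatenate([times] + extras)

    flags = np.zeros(times.size, dtype=bool)
    pulse_idx = np.full(times.size, -1, dtype=int)
    times, flags, _ = _enforce_refractory(times, flags, pulse_idx,
                                          config.refractory_ms / 1000.0)

    breakthrough = np.array([
        bool(np.any((times >= on) & (times < off)))
        for on, off in ttl.intervals
    ])
    gt = GroundTruth(times, flags, per_trial_breakthrough=breakthrough)
    return ttl, gt


def generate_nphr_session(config: SynthConfig, protocol: StimProtocol
                          ) -> tuple[VoltageTrace, TTLTrace, GroundTruth]:
    """Full NpHR photoinhibition session with rendered voltage trace."""
    ttl, gt = generate_nphr_events(config, protocol)
    trace = _render_trace(config, gt.true_spike_times_s,
                          config.duration_s or protocol.session_duration_s())
    return trace, ttl, gt


def _render_trace(config: SynthConfig, spike_times_s, duration_s) -> VoltageTrace:
    """Gaussian noise plus the fixed template at each spike time.

    The template's extremum sample lands on round(t * fs), so the spike
    "time" is the waveform trough, matching extremum-aligned detection.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    fs = config.sampling_rate_hz
    n = int(round(duration_s * fs))
    x = rng.standard_normal(n).astype(np.float32) * np.float32(config.noise_sd)
    template = spike_waveform(config.spike_amplitude, config.spike_width_ms,
                              fs).astype(np.float32)
    k0 = _template_peak_index(template)
    m = template.size
    for t in np.asarray(spike_times_s):
        i = int(round(t * fs)) - k0
        lo, hi = max(i, 0), min(i + m, n)
        if hi > lo:
            x[lo:hi] += template[lo - i:hi - i]
    return VoltageTrace(x, fs)


def expected_pulse_response(config: SynthConfig, protocol: StimProtocol
                            ) -> tuple[float, float]:
    """Analytic mean and per-pulse variance of the spike count in one
    inter-pulse window: evoked (Bernoulli + doublet) plus Poisson leakage
    from spontaneous firing.  Used as the recovery oracle in tests."""
    p, d = config.evoked_prob, config.doublet_prob
    leak = config.spont_rate_hz * protocol.ipi_s
    mean = p * (1 + d) + leak
    # C = B1(1 + B2): E[C^2] = p(1 + 3d); add independent Poisson leakage
    var = p * (1 + 3 * d) - (p * (1 + d)) ** 2 + leak
    return mean, var
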