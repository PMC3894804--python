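"""Session container and event-table input/output.

A recorded session is a voltage trace (extracellular signal, µV) plus the
TTL laser-command channel.  On disk a session is a two-file pair:

* ``<name>.oesb`` — a human-readable JSON header (format version, sampling
  rate, channel labels/units, payload byte count, TTL representation);
* ``<name>.oesb.bin`` — little-endian 32-bit float payload, channels
  concatenated in header order.

TTL can be stored either as an interval list ``[(on_s, off_s), ...]``
embedded in the header, or as a second binary channel sampled at the trace
rate; the two representations are interconvertible and agree to one sample
at the edges.

Spike timestamps travel as single-column plain-text tables (seconds, one
per line, ``#`` comments tolerated), matching the shape of deposited
spike-event exports.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    CorruptFileError,
    SpikeTableParseError,
    UnsupportedFormatError,
    ValidationError,
)

FORMAT_NAME = "oesb"
FORMAT_VERSION = 1
_PAYLOAD_DTYPE = "<f4"


# ---------------------------------------------------------------------------
# containers


@dataclass
class VoltageTrace:
    """Uniformly sampled extracellular voltage, in microvolts."""

    samples: np.ndarray
    sampling_rate_hz: float
    start_time_s: float = 0.0
    channel_label: str = "electrode"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 1:
            raise ValidationError("samples must be one-dimensional")
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return self.start_time_s + np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass
class TTLTrace:
    """Laser-command channel: light-on intervals in seconds.

    ``representation`` records how the channel was captured ("intervals"
    or "stream"); internally intervals are canonical.  Pulse onset is the
    time of the first high sample.
    """

    intervals: np.ndarray
    representation: str = "intervals"
    sampling_rate_hz: float | None = None

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if iv.size:
            if np.any(iv[:, 1] <= iv[:, 0]):
                raise ValidationError("TTL intervals must have off > on")
            order = np.argsort(iv[:, 0], kind="stable")
            iv = iv[order]
            if np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValidationError("TTL intervals must be non-overlapping")
        self.intervals = iv
        if self.representation not in ("intervals", "stream"):
            raise ValidationError("representation must be 'intervals' or 'stream'")

    @property
    def n_pulses(self) -> int:
        return int(self.intervals.shape[0])

    @property
    def onsets_s(self) -> np.ndarray:
        return self.intervals[:, 0]

    @property
    def offsets_s(self) -> np.ndarray:
        return self.intervals[:, 1]

    @classmethod
    def from_stream(cls, samples, sampling_rate_hz, threshold=0.5) -> "TTLTrace":
        """Extract on/off intervals from a sampled TTL channel."""
        x = np.asarray(samples) > threshold
        if x.size == 0:
            return cls(np.empty((0, 2)), "stream", sampling_rate_hz)
        edges = np.diff(x.astype(np.int8))
        rises = np.flatnonzero(edges == 1) + 1
        falls = np.flatnonzero(edges == -1) + 1
        if x[0]:
            rises = np.r_[0, rises]
        if x[-1]:
            falls = np.r_[falls, x.size]
        iv = np.column_stack([rises, falls]) / sampling_rate_hz
        return cls(iv, "stream", sampling_rate_hz)

    def to_stream(self, sampling_rate_hz, n_samples) -> np.ndarray:
        """Render the interval list as a 0/1 sample stream."""
        out = np.zeros(n_samples, dtype=np.float32)
        idx = np.round(self.intervals * sampling_rate_hz).astype(int)
        for i0, i1 in np.clip(idx, 0, n_samples):
            out[i0:i1] = 1.0
        return out


@dataclass
class SpikeTrain:
    """Sorted spike timestamps (seconds) over a known recording duration."""

    times_s: np.ndarray
    duration_s: float
    source: str = "detected"  # detected | imported | ground_truth

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float).ravel()
        if t.size and np.any(np.diff(t) <= 0):
            raise ValidationError("spike times must be strictly increasing")
        if not self.duration_s > 0:
            raise ValidationError("duration_s must be positive")
        if t.size and (t[0] < 0 or t[-1] > self.duration_s):
            raise ValidationError("spike times must lie in [0, duration_s]")
        if self.source not in ("detected", "imported", "ground_truth"):
            raise ValidationError("unknown spike-train source")
        self.times_s = t

    @property
    def n_spikes(self) -> int:
        return int(self.times_s.size)

    def rate_hz(self) -> float:
        return self.n_spikes / self.duration_s

    def shifted(self, dt_s: float) -> "SpikeTrain":
        return SpikeTrain(self.times_s + dt_s, self.duration_s + dt_s, self.source)


# ---------------------------------------------------------------------------
# session container


def _payload_path(path: Path) -> Path:
    return path.with_name(path.name + ".bin")


def write_session(trace: VoltageTrace, ttl: TTLTrace, path) -> Path:
    """Write a session as a JSON header + float32 binary payload pair."""
    path = Path(path)
    channels = [{"label": trace.channel_label, "units": "uV"}]
    payload = [np.asarray(trace.samples, dtype=_PAYLOAD_DTYPE)]
    if ttl.representation == "stream":
        stream = ttl.to_stream(trace.sampling_rate_hz, trace.n_samples)
        channels.append({"label": "ttl", "units": "logic"})
        payload.append(stream.astype(_PAYLOAD_DTYPE))
        ttl_header = {"representation": "stream", "channel": 1}
    else:
        ttl_header = {
            "representation": "intervals",
            "intervals": [[float(a), float(b)] for a, b in ttl.intervals],
        }
    header = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "sampling_rate_hz": float(trace.sampling_rate_hz),
        "start_time_s": float(trace.start_time_s),
        "n_samples": trace.n_samples,
        "dtype": _PAYLOAD_DTYPE,
        "channels": channels,
        "ttl": ttl_header,
    }
    path.write_text(json.dumps(header, indent=1) + "\n")
    np.concatenate(payload).tofile(_payload_path(path))
    return path


def read_session(path) -> tuple[VoltageTrace, TTLTrace]:
    """Read a session pair written by :func:`write_session`."""
    path = Path(path)
    header = json.loads(path.read_text())
    if header.get("format") != FORMAT_NAME or header.get("version") != FORMAT_VERSION:
        raise UnsupportedFormatError(
            f"{path}: unsupported format "
            f"{header.get('format')!r} v{header.get('version')!r}"
        )
    n = int(header["n_samples"])
    n_channels = len(header["channels"])
    raw = np.fromfile(_payload_path(path), dtype=header["dtype"])
    if raw.size != n * n_channels:
        raise CorruptFileError(
            f"{path}: header promises {n * n_channels} samples "
            f"({n_channels} channel(s) x {n}), payload holds {raw.size}"
        )
    fs = float(header["sampling_rate_hz"])
    trace = VoltageTrace(
        raw[:n],
        fs,
        start_time_s=float(header.get("start_time_s", 0.0)),
        channel_label=header["channels"][0]["label"],
    )
    ttl_header = header["ttl"]
    if ttl_header["representation"] == "stream":
        c = int(ttl_header["channel"])
        ttl = TTLTrace.from_stream(raw[c * n : (c + 1) * n], fs)
    else:
        ttl = TTLTrace(np.asarray(ttl_header["intervals"], float).reshape(-1, 2))
    return trace, ttl


# ---------------------------------------------------------------------------
# plain-text event tables


def _parse_numeric_lines(path, n_columns):
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        parts = stripped.replace(",", " ").split()
        try:
            values = [float(p) for p in parts]
        except ValueError:
            raise SpikeTableParseError(path, lineno, line) from None
        if len(values) != n_columns:
            raise SpikeTableParseError(path, lineno, line)
        rows.append(values)
    return np.asarray(rows, dtype=float).reshape(-1, n_columns)


def read_spike_table(path, duration_s: float | None = None) -> SpikeTrain:
    """Read a single-column timestamp table (seconds).

    Unsorted input is sorted; duplicate timestamps are collapsed with a
    warning.  If the file carries a ``# duration_s = X`` comment it sets
    the train duration unless ``duration_s`` overrides it.
    """
    path = Path(path)
    for line in path.read_text().splitlines():
        if duration_s is None and line.startswith("#") and "duration_s" in line:
            try:
                duration_s = float(line.split("=", 1)[1])
            except (IndexError, ValueError):
                pass
    t = np.sort(_parse_numeric_lines(path, 1).ravel())
    unique = np.unique(t)
    if unique.size < t.size:
        warnings.warn(
            f"{path}: collapsed {t.size - unique.size} duplicate timestamp(s)",
            stacklevel=2,
        )
    if duration_s is None:
        duration_s = float(unique[-1]) if unique.size else 1.0
    return SpikeTrain(unique, duration_s, source="imported")


def write_spike_table(train: SpikeTrain, path) -> Path:
    path = Path(path)
    lines = ["# optokit spike table (seconds)"]
    lines.append(f"# duration_s = {train.duration_s:.6f}")
    lines.append(f"# source = {train.source}")
    lines.extend(f"{t:.6f}" for t in train.times_s)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_interval_table(path) -> TTLTrace:
    """Read a two-column (on_s, off_s) light-interval table."""
    return TTLTrace(_parse_numeric_lines(path, 2))


def write_interval_table(ttl: TTLTrace, path) -> Path:
    path = Path(path)
    lines = ["# optokit light intervals: on_s, off_s"]
    lines.extend(f"{a:.6f}, {b:.6f}" for a, b in ttl.intervals)
    path.write_text("\n".join(lines) + "\n")
    return path
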