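"""Optional matplotlib views: raster, PSTH, ACH.

Imported lazily so the core library carries no plotting dependency.
"""

from __future__ import annotations

import numpy as np

from .ach import ACHResult
from .io import SpikeTrain
from .opto import PSTH, PulseSchedule


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def raster(spikes: SpikeTrain, event_times_s, window_s=(-1.0, 6.0), ax=None):
    """Event-aligned raster: one row per repetition, one dot per spike."""
    ax = _ax(ax)
    t = spikes.times_s
    for row, ev in enumerate(np.asarray(event_times_s)):
        rel = t[np.searchsorted(t, ev + window_s[0]):
                np.searchsorted(t, ev + window_s[1])] - ev
        ax.plot(rel, np.full(rel.size, row), "|", color="k", markersize=3)
    ax.set_xlabel("time from event (s)")
    ax.set_ylabel("repetition")
    return ax


def psth_plot(h: PSTH, rate: bool = True, ax=None):
    ax = _ax(ax)
    y = h.rate_hz() if rate else h.counts
    ax.step(h.bin_centers_s, y, where="mid", color="k")
    if rate and h.n_events > 1:
        sem = h.sem_rate_hz()
        ax.fill_between(h.bin_centers_s, y - sem, y + sem,
                        step="mid", alpha=0.3, color="k")
    ax.set_xlabel("time from event (s)")
    ax.set_ylabel("rate (Hz)" if rate else "count")
    return ax


def ach_plot(res: ACHResult, ax=None):
    ax = _ax(ax)
    ax.bar(res.bin_centers_s, res.counts, width=res.bin_s, color="0.3")
    for lag in res.peak_lags_s:
        ax.axvline(lag, color="r", lw=0.8, ls="--")
    ax.set_xlabel("lag (s)")
    ax.set_ylabel("pair count")
    ax.set_title(res.classification)
    return ax
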