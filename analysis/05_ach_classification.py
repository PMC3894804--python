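#!/usr/bin/env python
"""Autocorrelogram classification: examples and error rates.

Builds the ACH (20 ms bins, all spike pairs up to 2 s lag) for one
homogeneous Poisson unit and one sinusoid-modulated unit (depth 0.9,
period 0.5 s), writes both histograms, then measures classifier
specificity and sensitivity over 100 simulations of each kind.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from optokit import autocorrelogram
from optokit.benchmarks import (
    _phasic_times,
    _poisson_times,
    ach_classifier_benchmark,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(0)
    examples = {
        "non_phasic": _poisson_times(rng, 5.0, 2000.0),
        "phasic": _phasic_times(np.random.default_rng(1), 10_000),
    }
    print("Example units (10k spikes each):")
    for label, t in examples.items():
        res = autocorrelogram(t)
        pd.DataFrame({"lag_s": res.bin_centers_s,
                      "pair_count": res.counts}).to_csv(
            RESULTS / f"ach_example_{label}.csv", index=False)
        peaks = ", ".join(f"{v:.2f}" for v in res.peak_lags_s[:4])
        print(f"  simulated {label:10s} -> classified {res.classification}"
              + (f", peaks at {peaks} s" if res.peak_lags_s.size else ""))

    print("\nError rates over 100 seeds per class:")
    bench = ach_classifier_benchmark(seed=0, n_seeds=100)
    pd.DataFrame([bench]).to_csv(RESULTS / "ach_classifier_rates.csv",
                                 index=False)
    print(f"  specificity {bench['specificity']:.2f}, "
          f"sensitivity {bench['sensitivity']:.2f}, "
          f"first peak within one bin of the 0.5 s period in "
          f"{100 * bench['first_peak_at_period_fraction']:.0f}% of phasic "
          f"units")


if __name__ == "__main__":
    main()
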