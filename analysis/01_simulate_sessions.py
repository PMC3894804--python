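#!/usr/bin/env python
"""Generate the reference synthetic sessions the later analyses use.

Three protocols: a pulse-frequency sweep (1/5/10/20 Hz, 10 pulses each),
the repeated 2-hour 20 Hz protocol (100 pulses x 61 trains, 2 min apart,
event-level only — the full trace would be ~0.6 GB), and continuous-light
silencing epochs.  Voltage-trace sessions go to scratch/sessions (binary);
session inventories go to results/.
"""

import sys
from pathlib import Path

import pandas as pd

from optokit.cli import main as cli

ROOT = Path(__file__).resolve().parents[1]
SESSIONS = ROOT / "scratch" / "sessions"
RESULTS = ROOT / "results"


def run(args):
    print("  optokit " + " ".join(args))
    cli.main(args=args, standalone_mode=False)


def main():
    RESULTS.mkdir(exist_ok=True)
    rows = []
    print("Simulating the three stimulation protocols (seed 0):")
    run(["simulate", "--preset", "chr2-freqs", "--seed", "0",
         "--out", str(SESSIONS / "chr2_freqs")])
    rows.append(("chr2_freqs", "pulse trains at 1/5/10/20 Hz, 10 pulses",
                 "with trace"))
    run(["simulate", "--preset", "chr2-20hz-2hr", "--seed", "0",
         "--doublet-prob", "0.2", "--events-only",
         "--out", str(SESSIONS / "chr2_20hz_2hr")])
    rows.append(("chr2_20hz_2hr", "61 x 100 pulses at 20 Hz, 2 min apart",
                 "events only"))
    run(["simulate", "--preset", "nphr-10s", "--seed", "0",
         "--spont-rate", "2", "--silencing-efficacy", "0.95",
         "--out", str(SESSIONS / "nphr_10s")])
    rows.append(("nphr_10s", "5 x 10 s continuous light", "with trace"))

    inventory = pd.DataFrame(rows, columns=["session", "protocol", "payload"])
    inventory.to_csv(RESULTS / "session_inventory.csv", index=False)
    print(f"\nWrote {SESSIONS} and {RESULTS / 'session_inventory.csv'}")
    print(inventory.to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
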