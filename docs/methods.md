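# Methods

`optokit` analyzes single-unit extracellular recordings made during
optogenetic stimulation: brief blue-light pulse trains driving a
ChR2-expressing neuron, and continuous green-light epochs silencing an
NpHR-expressing neuron. This note documents the models, the estimators,
the numerical choices, and what the synthetic benchmark does and does not
establish about real recordings.

## Signal model and synthetic sessions

A session is a voltage trace sampled at 20 kHz (µV) plus a TTL
laser-command channel. The generator (`optokit.synth`) renders

* i.i.d. Gaussian noise of configurable SD (default 10 µV). Real
  extracellular noise is colored and nonstationary; we use the simplest
  model for which detection behavior is analyzable. After band-passing to
  0.3–8 kHz the noise SD shrinks by ≈ √(7.7/10).
* one fixed biphasic template per true spike — a single sine cycle of
  `spike_width_ms` (default 1 ms) scaled so its first-lobe extremum equals
  `spike_amplitude` (default −80 µV, trough-first). The template has
  exactly zero integral and its trough sample lands on `round(t·fs)`, so
  extremum-aligned detection should recover the true time to within one
  sample.
* spontaneous firing: homogeneous Poisson (`spont_mode="poisson"`) or a
  sinusoidally modulated inhomogeneous Poisson
  r(t) = r₀·(1 + d·sin 2πt/T) sampled by thinning
  (`spont_mode="phasic"`, default depth 0.9, period 0.5 s — a plausible
  slow network rhythm under urethane anesthesia; the period of real
  prelimbic phasic units is not calibrated to any dataset).
* evoked spikes: each pulse independently evokes a spike with probability
  `evoked_prob`; with probability `doublet_prob` a second spike follows
  3–8 ms later (uniform), provided it stays inside the inter-pulse
  interval. Doublets are what push per-pulse spike counts above 1.
* first-spike latency: truncated Gaussian on (0, IPI) with SD
  `latency_jitter_ms` (default 1.5 ms) whose mean sits at the **center of
  the 1-ms bin labelled `latency_mode_ms`** (default 7 → mean 7.5 ms).
  `latency_mode_ms` is therefore the label of the modal latency histogram
  bin, which is the quantity a binned latency analysis reports; placing a
  symmetric continuous mode exactly on a bin edge would instead split the
  mass evenly between two bins and make the binned mode a coin flip.
* silencing: during each light-on interval every would-be spontaneous
  spike is independently deleted with probability `silencing_efficacy`;
  survivors are breakthrough spikes. With a Poisson unit the expected
  breakthrough-free fraction of a 10-s trial is exp(−r·10·(1−e)), so even
  e = 0.95 at r = 2 Hz leaves breakthrough in most trials — complete
  per-trial silence effectively requires e ≈ 1.
* rebound: after light offset the rate gains an additive component
  r₀·(g−1)·exp(−Δt/τ) (defaults g = 1 i.e. off; τ = 100 ms, the time
  scale of an Ih-like post-hyperpolarization transient).
* a 2 ms minimum separation is enforced on the merged spike list
  (physiological refractory floor; it also makes the detection ground
  truth unambiguous).

Identical config + seed gives bit-identical traces, TTL and ground truth.
The generator does **not** model: biophysical opsin kinetics, multi-unit
overlap or sorting ambiguity, electrode drift, colored noise, or
activity-dependent changes in spike amplitude. Passing benchmarks
therefore demonstrate that the estimators are correct and well calibrated
under the stated statistical model — not that the detector's defaults are
optimal for any particular real electrode.

## Detection

Zero-phase 4th-order Butterworth band-pass (0.3–8 kHz,
forward-backward via `scipy.signal.sosfiltfilt`). Zero-phase filtering is
deliberate: group delay would bias the ~7 ms latency mode measured at
1 ms resolution. Noise SD is estimated as median(|x|)/0.6745 (robust to
spike contamination at realistic firing rates). Threshold =
`threshold_k` × noise SD (default 4, negative-going); each accepted
crossing is aligned to the extremum within the 1 ms dead time, and
crossings within the dead time of the previous detection are discarded,
so no two detections are closer than `dead_time_ms`.

Threshold choice: for Gaussian noise band-limited to 0.3–8 kHz, Rice's
crossing-rate formula gives ν(u) ≈ 4.7 kHz · exp(−u²/2σ²), i.e. ≈ 1.6
false excursions/s at 4σ but ≈ 0.02/s at 5σ. The accuracy benchmarks
therefore run at `threshold_k = 5`, where an SNR-10 spike still clears
the threshold by > 5 noise SDs; 4 remains the package default for
interactive use on high-SNR units where recall matters more than the
false-positive rate.

## Fidelity, latency, rates

`parse_schedule` groups TTL pulses into trains wherever the inter-onset
gap exceeds 1 s, and calls a schedule "continuous" when every train is a
single pulse at least 0.5 s long. The response window for pulse *i* is
the full inter-pulse interval [onsetᵢ, onsetᵢ + IPI) — the whole-interval
window is required for per-pulse probabilities above 1 to be meaningful,
and the last pulse of a train uses the same width. Per-position
probability is the mean count over trains at that pulse position;
`sem_prob` is by default the SEM over pulse positions ("mean probability
over the 100 pulses", matching how such protocols are summarized), with
SEM over trains available as an option. First-spike latency is measured
per window; its mode is the center of the maximal 1-ms histogram bin,
ties broken toward the smaller latency. PSTHs conserve counts exactly
(verified bin-sum vs direct window count) and convert to rate as
count/(n_events·Δ) with SEM across events. Firing rate over a window is
count/duration; session blocks such as "first/last 10 minutes" select
trains by train onset.

Silencing metrics score each continuous-light trial with rates over
[on−5 s, on), [on, off) and [off, off+5 s) (windows truncated, with a
warning, at neighboring trials or the recording edge); a trial is
breakthrough iff at least one spike falls in [on, off). The rebound index
is the pooled post/pre rate ratio; it is purely descriptive and no
hypothesis test is attached, since the transient is better seen in the
100-ms-bin post-offset PSTH (`analysis/04`).

## Autocorrelogram and phasic classification

The ACH counts all ordered spike pairs (i < j), consecutive and
non-consecutive, with lag ≤ 2 s in 20 ms bins. Bins are half-open
[kΔ, (k+1)Δ) except the last, which closes at the maximum lag so the
pair-count conservation identity is exact; a lag within one part in 10⁹
of a bin edge is assigned to the upper bin so that decimal spike times
land where exact arithmetic would put them. For a homogeneous Poisson
train the expected bin count is N·r·Δ.

Classification: baseline = mean count over the upper half of the lag
range (1–2 s); a unit is phasic iff any bin at lag ≥ 2 bins (≥ 40 ms,
skipping the refractory/burst shoulder) exceeds baseline + z·spread.
Two numerical points matter here:

* pair counts are over-dispersed relative to Poisson because pairs share
  spikes — Var ≈ µ(1 + 2rΔ) — so spread = √(baseline·(1 + 2·baseline/N));
* ~98 bins are tested, so the default z is the Bonferroni-corrected
  one-sided normal quantile at a family-wise level of 1% (z ≈ 3.7 at the
  default binning), not a fixed per-bin 3σ, which would flag ~12% of
  homogeneous trains as phasic. `z` is overridable.

The empirical upper-half SD is *not* used as the spread: for a genuinely
periodic unit the oscillation itself inflates that SD above the peak
amplitude and would make the test blind to exactly the structure it
looks for. Peak lags are reported as local maxima of the
coverage-normalized 100-ms moving average that clear the same
significance level (with a matching prominence requirement); smoothing
prevents the decaying shoulder near zero lag and single noisy bins from
being reported as peaks, so a 0.5-s-period unit's first reported peak is
at ≈ 0.5 s. Histograms with fewer than 100 pairs are unclassifiable.
Measured over 100 simulations per class (10,000 spikes, rate 5 Hz):
specificity 0.99, sensitivity 1.00 (`analysis/05`).

## Benchmark problem sizes

The recovery benchmarks (tests, `scripts/acceptance.py`, `analysis/`)
use: 1000 inserted spikes at SNR 10 for detection; 10 trains × 100 pulses
per fidelity condition; 25 trains (2500 evoked spikes) for the latency
mode; 30 × 10 s trials for silencing; 100 simulations per class of 10,000
spikes for the classifier. These sizes put Monte-Carlo error well inside
the 3-SE acceptance bands while a full run stays under a minute. The
repeated 2-hour protocol (61 trains, 2 min apart) is analyzed at
event level; rendering its full 20 kHz trace (~0.6 GB) is supported but
unnecessary for event statistics, and `generate_chr2_events` /
`--events-only` skip it.

## Importing recorded data

Plain-text exports are the interchange format: single-column spike
timestamp tables (seconds, `#` comments) and two-column light-interval
tables, plus the `.oesb` session pair (JSON header + float32 payload) for
raw traces. Validation against deposited recordings is sensitive to the
original (unreported) detection parameters — above all `threshold_k` —
so imported-timestamp and re-detected workflows are both supported and
may legitimately disagree.

## Known limitations

* The whole-interval response window counts spontaneous spikes as evoked
  (leakage r·IPI, 0.05 spikes/pulse at 1 Hz and 20 Hz stimulation); the
  recovery oracle accounts for it, but low-fidelity units with high
  spontaneous rates will read high.
* The phasic classifier assumes a stationary baseline over the upper half
  of the lag range; rhythms with period ≳ 1 s violate that and would
  depress apparent significance.
* Latency jitter is Gaussian; real ChR2 latency distributions are
  right-skewed, which would shift the mean but not the binned mode the
  pipeline reports.
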