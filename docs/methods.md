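# Methods

This note records the models, estimators, and numerical choices behind
`periseq`, and what the synthetic benchmarks do and do not demonstrate.

## Behavioral timeline

All intervals are half-open `[onset, offset)` seconds (float64); a frame is
labeled by its start time. Syllable annotations are grouped into **bouts**
(runs of song elements with silences < 0.5 s — long enough to keep
intra-bout syllable gaps and mini-breaths inside "song", short enough that
genuine between-bout silences become their own category) and bouts into
**phrases** with the strict < 2 s silence rule; a 2.0-s gap starts a new
phrase. Phrase onset is the first vocal element including introductory
notes. The 0.5-s bout gap is this package's choice; the phrase rule and all
window sizes below are fixed properties of the analysis.

Epoch labels are assigned with precedence song > peri_gap > peri_pre/post >
baseline > other:

- `peri_pre` / `peri_post`: up to 5 s before/after each phrase. When the
  post window of one phrase would overlap the pre window of the next, the
  midpoint of the inter-phrase gap splits them — symmetric and
  deterministic where the analysis convention is otherwise unspecified.
- `peri_gap`: silences between bouts inside one phrase; counted as
  peri-song wherever events are tallied.
- `baseline`: ≥ 10 s from every bout *and every call*. Calls inside peri
  windows keep the peri label (they are vocal but not song) but reset the
  baseline exclusion clock.
- Pre-/post-analysis eligibility demands 5 s free of any vocal element
  before onset / after offset; phrases too close to the trial edge are
  flagged truncated and ineligible.

## Calcium pipeline

**Background correction** subtracts the mean of a ring extending 6 pixels
beyond the ROI (excluding all neuronal ROIs) with unit weight — no neuropil
coefficient.

**Baseline and noise** are estimated iteratively: a centered running
20th-percentile filter (30-s window) over currently quiescent frames,
recentred by the quiescent-frame residual mean (the raw percentile of a
noise process sits ~0.84 SD below its mean; recentring removes that offset
while keeping the percentile filter's robustness to transients), noise SD
from quiescent residuals (n−1 denominator), and an active mask at 3 SD
dilated ±2 frames, iterated to a fixed mask or 20 rounds. The SD is floored
at `1e-6·max(|trace|, 1)` so noiseless synthetic input keeps finite
thresholds. A trace whose every frame ends active has no quiescent baseline
and is rejected.

**Deconvolution** solves
`min Σ (y_t − c_t)² s.t. c_t ≥ γ·c_{t−1}, c_t ≥ 0` exactly. Substituting
`z_t = c_t γ^{−t}` reduces it to weighted isotonic regression, solved by
pool adjacent violators. Pools are merged with running discounted sums
(`Σ y_k γ^k`, `Σ γ^{2k}` accumulated left-to-right within each pool), so no
explicit `γ^{2t}` weight is ever formed — those underflow beyond a few
thousand frames. The nonnegativity bound is exact clipping of pool values
at zero (the bounded-isotonic projection result). γ defaults to
`exp(−Δt/1.25 s)` at 30 frames/s, the GCaMP6s decay; the rise-time target
of the synthetic kernel (0.112 s onset-to-peak) fixes its rise constant by
root-finding. Tests verify optimality against two independent oracles: a
brute-force SLSQP quadratic program and scikit-learn's isotonic regression
on the transformed problem (objective gap < 1e−6 on length-20 inputs).

**Event detection** thresholds the *deconvolved* trace at 3 SD (the dashed
3-SD convention is drawn against inferred traces; a flag applies it to the
raw corrected trace instead). Because the indicator decay bridges
transients fired in quick succession, suprathreshold runs are split at
clusters of significant deconvolved drive (> 1.5 SD; 1-frame gaps within a
cluster tolerated): each cluster is one event, its first frame the onset.
Runs with no significant drive anywhere — threshold excursions carried by
decay plus noise — yield no event; this is what keeps the false-positive
rate on pure-noise traces below 5 % per 10-s trace. The peak is located on
a 3-frame-averaged copy of the inferred trace (deconvolution pools
violators only on decays, so upward noise survives near the peak;
the short average removes the resulting late-peak wander without moving
the noise-free peak). Rise time is peak minus onset. Tie-breaks take the
earliest frame. Gap-filling is implemented explicitly rather than by
morphological closing, whose boundary handling erodes run starts at the
array edges.

## Population analysis

Events are labeled by the epoch of their onset frame; a transient whose
rise straddles song onset is labeled by where it began. The phrase-index
denominator counts song + peri events only (the bounded −1/+1 definition);
baseline/other events are excluded, with a flag to include them. Neurons
pooled across trials within a day share counts; across days they are
distinct identities. The near-zero pan-song band query uses |PI| ≤ 0.18.

Event-rate traces use 100-ms bins over ±5 s, per-phrase traces averaged
across phrases (a pooled mode exists). The 1-s moving average is centered
but never crosses the −5/+5 edges or the alignment point — pre-onset rates
must not borrow post-onset events — and slides inward near a boundary so
its length never drops below 0.5 s. Onset prediction takes baseline
statistics from the −5..−4 s bins and reports the earliest crossing of
mean + 3 SD sustained for ≥ 0.2 s (the dwell suppresses single-bin noise
crossings; SD floored at 0.05 events/s). Peri-event histograms use 200-ms
bins in event-count or distinct-neuron mode.

## Electrophysiology

Voltage is bandpassed 0.3–5 kHz with a 4th-order zero-phase Butterworth
(the band is fixed; the filter family/order is our choice). Multiunit
spikes are negative peaks below −4 SD of the filtered signal over
spontaneous segments, 1-ms lockout. Rates: 10-ms bins averaged across
renditions, 500-ms centered moving average (shrinking at edges), and 0–1
normalization between baseline and song means. Onset latency is the
earliest pre-song time from which the smoothed rate stays above
mean + 2 SD of the spontaneous rate until song onset; the threshold SD is
computed over the *smoothed* spontaneous trace (the raw 10-ms-bin
alternative is exposed via `smooth=0`). Note the estimator's inherent
lag on ramped activity: a threshold crossing happens once the ramp clears
the noise band, ~0.1–0.2 s after the true ramp foot under the default
synthetic conditions.

Single-unit ISI variability: only intervals with both spikes inside one
epoch window count (boundary-spanning ISIs are discarded, not truncated),
pooled across bouts per unit; CV uses the sample SD. Epochs with < 5 ISIs
are marked insufficient rather than reported.

## Respiration

Pressure is low-passed at 400 Hz. Cycles are delimited by hysteretic
ambient crossings (band ±5 % of quiet peak-to-peak, suppressing chatter on
slow asymptotic returns to ambient) with each crossing backtracked to the
exact interpolated ambient level, so boundaries are sample-accurate and
invariant to positive rescaling. A cycle is inspiration (subambient) then
expiration; partial cycles at trace edges are dropped. The ambient level
is taken from `ambient_level` when the recording provides a calibrated
zero; otherwise it is estimated in two passes — median of the 3-s quiet
window, then the mean over the complete quiet cycles found there. The
refinement exploits flow balance: net airflow over a whole cycle is near
zero, so the mean relative pressure over complete cycles estimates ambient
without the duty-cycle bias a raw median or mean has on asymmetric
breathing waveforms.

Song markers per phrase: onset is the inspiration onset of the last cycle
starting before the first introductory note; offset is the end of the
expiration containing the last syllable offset. One phrase is the unit of
respiratory analysis. Cycles are assigned to pre/song/post epochs by
inspiration onset and additionally keyed to 1-s bins for time-course
summaries feeding stock repeated-measures ANOVA.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions: 30-fps imaging, noise
SD 1 with event amplitude 10 SD, GCaMP6s kernel (rise 0.112 s, decay
1.25 s), slow sinusoidal drift; phrases of 1–3 bouts of ~0.7-s motifs with
intro notes, inter-bout gaps of 1 s and inter-phrase gaps above the 2-s
rule; peri-song Gaussian event-rate ramps peaking 1.5 s before phrase
onset (0.45 events/s at peak, support ending 0.25 s before onset), a
post-offset bump at +0.5 s, sparse gap activity; motif-locked song events
at a per-neuron phase with 55-ms Gaussian jitter and 0.7 per-motif
participation; a 0.25-s refractory separation between one neuron's events
(transients are bursts of finite width; closer spacings are unresolvable
at the frame rate); multiunit baseline 20 spikes/s ramping from −1.5 s to
120 spikes/s during song; single units as gamma-renewal processes, regular
(shape 8) in spontaneous epochs and irregular (shape ≤ 0.7) around song;
respiratory cycles N(0.38, 0.04²) s quiet and N(0.18, 0.03²) s in song at
58 % expiratory duty, rendered as flow-balanced half-sines (inspiration
deeper and shorter than expiration, as in real air-sac records).

A single master seed fans out to counter-keyed substreams per neuron and
per signal, so outputs are bit-reproducible and adding a neuron never
perturbs another's data.

Deliberately *not* emulated: motion artifacts and slow photobleaching
beyond sinusoidal drift, neuropil cross-contamination between overlapping
somata, spike-to-calcium nonlinearity, non-Poisson history dependence of
peri-song events, respiratory amplitude variability within a state, or
annotation errors. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated statistical structure, not
robustness to every artifact of real recordings.

## Problem sizes

Tests and the acceptance checks use sessions of 3–100 phrases (trials of
~80 s to ~45 min of timeline, events only at the large end), populations
of 120 neurons for class recovery, 20 seeds for multiunit latency, 19
units for the ISI-CV comparison (matching the recorded sample size), and
5–10 seeds for respiratory statistics. These sizes give the recovery
statistics comfortable margins over their tolerances while keeping the
full suite under a minute of compute for the unit tests and a few minutes
including the end-to-end checks.

## Known limitations

- The drive-based event splitter cannot separate transients closer than
  ~3 frames; the generator's refractory separation reflects that limit.
- Onset-latency estimates on ramped multiunit activity are biased late by
  the threshold-crossing construction (see above); the recovery tolerance
  absorbs this under the default conditions.
- The ambient-level refinement assumes approximate per-cycle flow balance;
  recordings with strong DC drift should supply a calibrated
  `ambient_level`.
- `interval_fluorescence` normalizes to the song mean and is undefined for
  trials without song frames (reported as an error, not a number).
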