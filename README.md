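# periseq

Analysis pipeline for **song and peri-song neural activity in singing
birds**: calcium imaging of cortical premotor neurons, multiunit and
single-unit electrophysiology, and air-sac pressure recordings, aligned to
a common behavioral timeline of song bouts and phrases.

The scientific question the pipeline serves: premotor neurons in the song
nucleus HVC fire sparse, precisely timed sequences *during* song — but do
they also carry preparatory activity *around* song? Answering it requires
classifying each neuron's calcium events as song or peri-song, which in
turn requires careful behavioral segmentation, deconvolution of slow
indicator dynamics, and population-level timing statistics. The same
session logic extends downstream: multiunit rate ramps before song onset,
single-unit spike-train irregularity across behavioral epochs, and
respiratory acceleration as the bird prepares to sing.

## Core definitions

- **Phrase**: song bouts separated by < 2 s of silence (strict), one
  singing episode; phrase onset includes introductory notes.
- **Peri-song**: the 5-s windows before and after each phrase plus the
  silent gaps between bouts within it. **Baseline** frames are ≥ 10 s from
  any singing or calling.
- **Phrase index** of a neuron with `n_song` song events and `n_peri`
  peri-song events over a day:

  ```
  PI = (n_song − n_peri) / (n_song + n_peri)   ∈ [−1, +1]
  ```

  PI = −1 → *peri-song* neuron, PI = +1 → *song* neuron, interior →
  *pan-song*; fewer than two events → excluded.
- **Calcium events**: the deconvolved (inferred) trace must exceed 3 SD of
  the estimated noise; deconvolution solves the AR(1) nonnegative
  least-squares problem
  `min Σ (y_t − c_t)²  s.t.  c_t ≥ γ c_{t−1}, c_t ≥ 0`
  exactly by pool adjacent violators, with γ = exp(−Δt/τ_decay) for
  GCaMP6s. Event timing is read from the onset-to-peak **rise time**.
- **Multiunit spikes**: negative peaks of the 0.3–5 kHz bandpassed voltage
  below −4 SD of spontaneous activity; onset latency is the sustained
  crossing of mean + 2 SD of the spontaneous smoothed rate.
- **CV_ISI**: SD/mean of within-epoch inter-spike intervals (epochs:
  spontaneous, pre-song [−2.5, −0.5] s, song, post-song [+0.5, +2.5] s).
- **Respiratory cycle**: inspiration (subambient pressure) followed by
  expiration; duty cycle is the percent of the cycle spent in expiration.

Every pipeline stage is paired with a ground-truth **synthetic-data
generator** (`periseq.synth`) that emulates the statistical structure of
directed-song sessions, so all recovery properties are testable without
recorded data.

## Worked example

`examples/03_phrase_index_population.py` runs the full calcium pipeline on
120 synthetic neurons (40 planted per class) and prints:

```
recovered classes (planted 40/40/40): {'peri_song': 38, 'excluded': 2, 'pan_song': 41, 'song': 39}
peri-song event-rate peak at -1.95 s (planted -1.5 s)
population rate crosses baseline+3SD at -3.95 s before onset
```

Classification recovers the planted classes (the two `excluded` neurons
genuinely produced fewer than two events, the pipeline's sparsity rule);
the peri-song population event rate peaks roughly 1.5–2 s before phrase
onset, and the population rate crosses its 3-SD onset-prediction threshold
seconds before the bird begins to sing. `examples/05_respiration.py`
prints the respiratory side of the same preparation:

```
  pre : duration 0.376 s, duty 58.0 % (13 cycles)
  song: duration 0.180 s, duty 57.9 % (25 cycles)
  post: duration 0.402 s, duty 58.0 % (13 cycles)
```

— song respiration runs roughly twice as fast as quiet breathing at a
similar expiratory duty cycle. The other examples cover behavioral
segmentation, single-neuron event detection, and multiunit latency.

## Package layout

| module                | contents |
|-----------------------|----------|
| `periseq.behavior`    | syllable annotations → bouts, phrases, epoch masks, eligibility rules |
| `periseq.calcium`     | ROI/ring extraction, baseline+noise estimation, PAVA deconvolution, event detection |
| `periseq.population`  | event labeling, phrase index, neuron classes, rate traces, onset prediction, SNR, active fractions |
| `periseq.ephys`       | multiunit spike detection, normalized aligned rates, latencies, epoch ISI CV |
| `periseq.respiration` | pressure-cycle segmentation, song markers, epoch/bin summaries |
| `periseq.synth`       | ground-truth generators for timelines, events, fluorescence, movies, spikes, pressure |
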