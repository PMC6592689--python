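"""Population-level analysis of calcium events around singing.

Implements the phrase index — (song events − peri-song events) / (song +
peri-song events), bounded to [−1, +1] — the derived neuron classes
(peri-song / pan-song / song), alignment-relative event-rate traces and
peri-event histograms, the 3-SD onset-prediction statistic, per-neuron
signal-to-noise ratios, interval-normalized fluorescence, and per-phrase
active fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .behavior import PERI_LABELS, EpochMask, Phrase
from .calcium import CalciumEvent, FluorescenceTrace

__all__ = [
    "NeuronSummary",
    "RateTrace",
    "OnsetPrediction",
    "label_events",
    "phrase_index",
    "classify_neuron",
    "summarize_neuron",
    "event_rate_trace",
    "perievent_histogram",
    "onset_prediction",
    "event_snr",
    "interval_fluorescence",
    "active_fraction",
]

PAN_SONG_BAND = 0.18  # |phrase index| band used to select near-zero pan-song neurons


@dataclass(frozen=True)
class NeuronSummary:
    """Per-neuron event counts over one day of singing and derived class."""

    neuron_id: str | int
    n_song_events: int
    n_peri_events: int
    n_other_events: int = 0
    phrase_index: float | None = None
    neuron_class: str = "excluded"


@dataclass
class RateTrace:
    """Binned, smoothed event/spike rate relative to an alignment point."""

    alignment: str  # "phrase_onset" or "phrase_offset"
    rel_times: np.ndarray  # bin centers, seconds
    rate: np.ndarray  # events/s per bin (averaged over trials)
    rate_smooth: np.ndarray | None
    bin_width: float
    smoothing_window: float
    n_trials: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alignment": self.alignment,
                "rel_time_s": self.rel_times,
                "rate": self.rate,
                "rate_smooth": self.rate_smooth,
                "n_trials": self.n_trials,
            }
        )


@dataclass(frozen=True)
class OnsetPrediction:
    """3-SD threshold crossing of the population rate before song onset."""

    baseline_rate_mean: float
    baseline_rate_sd: float
    threshold: float
    crossing_time: float | None  # seconds relative to phrase onset (negative) or None


# ---------------------------------------------------------------------------
# Event labeling and phrase index


def label_events(events: list[CalciumEvent], mask: EpochMask) -> list[CalciumEvent]:
    """Label each event by the epoch of the frame containing its onset.

    The onset frame governs even when the transient's rise extends into
    the next epoch.  Peri_pre / peri_gap / peri_post all count as
    peri-song for indexing.
    """
    onsets = np.array([e.onset_time for e in events], dtype=float)
    labels = mask.label_at(onsets) if events else np.array([])
    return [replace(e, epoch_label=str(lab)) for e, lab in zip(events, labels)]


def phrase_index(n_song: int, n_peri: int) -> float | None:
    """(song − peri) / (song + peri); None (excluded) below two events.

    Events labeled baseline or other never enter either count.
    """
    if n_song < 0 or n_peri < 0:
        raise ValueError("event counts must be nonnegative")
    total = n_song + n_peri
    if total < 2:
        return None
    return (n_song - n_peri) / total


def classify_neuron(summary: NeuronSummary) -> NeuronSummary:
    """Assign peri_song (−1) / song (+1) / pan_song (interior) / excluded."""
    pi = summary.phrase_index
    if pi is None:
        cls = "excluded"
    elif pi == -1.0:
        cls = "peri_song"
    elif pi == 1.0:
        cls = "song"
    else:
        cls = "pan_song"
    return replace(summary, neuron_class=cls)


def summarize_neuron(
    neuron_id, labeled_events: list[CalciumEvent], include_other: bool = False
) -> NeuronSummary:
    """Pool labeled events into a classified NeuronSummary.

    With ``include_other=True`` baseline/other events enter the index
    denominator (off by default: the bounded −1/+1 index counts only song
    and peri-song events).
    """
    n_song = sum(1 for e in labeled_events if e.epoch_label == "song")
    n_peri = sum(1 for e in labeled_events if e.epoch_label in PERI_LABELS)
    n_other = len(labeled_events) - n_song - n_peri
    if include_other:
        total = n_song + n_peri + n_other
        pi = None if total < 2 else (n_song - n_peri) / total
        summary = NeuronSummary(neuron_id, n_song, n_peri, n_other, pi)
    else:
        summary = NeuronSummary(neuron_id, n_song, n_peri, n_other,
                                phrase_index(n_song, n_peri))
    return classify_neuron(summary)


def in_pan_song_band(summary: NeuronSummary, band: float = PAN_SONG_BAND) -> bool:
    """Pan-song neurons with phrase index inside [−band, +band]."""
    return (
        summary.neuron_class == "pan_song"
        and summary.phrase_index is not None
        and -band <= summary.phrase_index <= band
    )


# ---------------------------------------------------------------------------
# Rate traces and histograms


def _boundary_moving_average(
    rate: np.ndarray, centers: np.ndarray, segments: list[tuple[float, float]],
    window: float, floor: float,
) -> np.ndarray:
    """Centered moving average that truncates at segment boundaries.

    The averaging window never crosses a segment boundary (the −5/+5 s
    edges and the alignment point at 0) and never shrinks below ``floor``
    seconds: near a boundary the window slides inward to keep its length.
    """
    out = np.full_like(rate, np.nan, dtype=float)
    half = window / 2.0
    eps = 1e-9
    for a, b in segments:
        idx = np.flatnonzero((centers >= a) & (centers < b))
        if idx.size == 0:
            continue
        eff_floor = min(floor, b - a)
        for i in idx:
            t = centers[i]
            lo = max(t - half, a)
            hi = min(t + half, b)
            if hi - lo < eff_floor:  # truncated: slide inward to keep the floor
                if lo <= a + eps:
                    lo, hi = a, min(a + eff_floor, b)
                else:
                    lo, hi = max(b - eff_floor, a), b
            sel = idx[(centers[idx] >= lo - eps) & (centers[idx] <= hi + eps)]
            out[i] = rate[sel].mean()
    return out


def event_rate_trace(
    event_onsets: np.ndarray,
    alignments: np.ndarray,
    alignment: str = "phrase_onset",
    span: tuple[float, float] = (-5.0, 5.0),
    bin_width: float = 0.1,
    window: float = 1.0,
    floor: float = 0.5,
    pooled: bool = False,
) -> RateTrace:
    """Alignment-relative event rate in 100-ms bins with boundary-aware smoothing.

    Counts event onsets per bin relative to each alignment time, converts
    to events/s, averages per-trial traces across trials (``pooled=True``
    instead pools all events and divides by the trial count), then applies
    a centered 1-s moving average that truncates at the span edges and at
    the alignment point so pre- and post-alignment rates never blur into
    each other, with a 0.5-s window floor.
    """
    alignments = np.atleast_1d(np.asarray(alignments, dtype=float))
    event_onsets = np.asarray(event_onsets, dtype=float)
    lo, hi = span
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    centers = edges[:-1] + bin_width / 2
    if alignments.size == 0:
        return RateTrace(alignment, centers, np.zeros(centers.size), None,
                         bin_width, window, 0)
    per_trial = np.zeros((alignments.size, centers.size))
    for j, t0 in enumerate(alignments):
        rel = event_onsets - t0
        counts, _ = np.histogram(rel, bins=edges)
        per_trial[j] = counts / bin_width
    rate = per_trial.sum(axis=0) / alignments.size if pooled else per_trial.mean(axis=0)
    segments = [(lo, 0.0), (0.0, hi)] if lo < 0.0 < hi else [(lo, hi)]
    smooth = _boundary_moving_average(rate, centers, segments, window, floor)
    return RateTrace(alignment, centers, rate, smooth, bin_width, window,
                     int(alignments.size))


def perievent_histogram(
    event_onsets: np.ndarray,
    alignments: np.ndarray,
    neuron_ids: np.ndarray | None = None,
    span: tuple[float, float] = (-5.0, 5.0),
    bin_width: float = 0.2,
    mode: str = "events",
) -> tuple[np.ndarray, np.ndarray]:
    """200-ms peri-event histogram of events or of distinct active neurons.

    In ``mode="neurons"`` a neuron contributes at most one count per bin
    per alignment.  Returns (bin_centers, counts).
    """
    alignments = np.atleast_1d(np.asarray(alignments, dtype=float))
    event_onsets = np.asarray(event_onsets, dtype=float)
    lo, hi = span
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    centers = edges[:-1] + bin_width / 2
    counts = np.zeros(centers.size)
    if mode not in ("events", "neurons"):
        raise ValueError("mode must be 'events' or 'neurons'")
    if mode == "neurons" and neuron_ids is None:
        raise ValueError("neuron mode requires neuron_ids")
    for t0 in alignments:
        rel = event_onsets - t0
        if mode == "events":
            c, _ = np.histogram(rel, bins=edges)
            counts += c
        else:
            which = np.digitize(rel, edges) - 1
            ok = (which >= 0) & (which < centers.size)
            pairs = set(zip(np.asarray(neuron_ids)[ok].tolist(), which[ok].tolist()))
            for _, b in pairs:
                counts[b] += 1
    return centers, counts


# ---------------------------------------------------------------------------
# Onset prediction


def onset_prediction(
    trace: RateTrace,
    k: float = 3.0,
    baseline_span: tuple[float, float] = (-5.0, -4.0),
    dwell: float = 0.2,
    sd_floor: float = 0.05,
) -> OnsetPrediction:
    """Earliest sustained crossing of baseline mean + k·SD before onset.

    Baseline statistics come from the −5..−4 s bins of the smoothed trace;
    the crossing must stay above threshold for at least ``dwell`` seconds
    to suppress single-bin noise.  The SD is floored at ``sd_floor``
    events/s.
    """
    rate = trace.rate_smooth if trace.rate_smooth is not None else trace.rate
    t = trace.rel_times
    base = rate[(t >= baseline_span[0]) & (t < baseline_span[1])]
    if base.size == 0:
        raise ValueError("trace does not cover the baseline span")
    mu = float(np.mean(base))
    sd = max(float(np.std(base, ddof=1)) if base.size > 1 else 0.0, sd_floor)
    thr = mu + k * sd
    dwell_bins = max(1, int(round(dwell / trace.bin_width)))
    pre = np.flatnonzero((t >= baseline_span[1]) & (t < 0.0))
    above = rate[pre] > thr
    crossing = None
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= dwell_bins:
            crossing = float(t[pre[i - dwell_bins + 1]])
            break
    return OnsetPrediction(mu, sd, thr, crossing)


# ---------------------------------------------------------------------------
# SNR, interval fluorescence, active fractions


def event_snr(
    song_event_peaks: np.ndarray, baseline_fluorescence_mean: float
) -> float:
    """Per-neuron SNR: mean over song events of peak / baseline-period mean."""
    peaks = np.asarray(song_event_peaks, dtype=float)
    if baseline_fluorescence_mean <= 0:
        raise ValueError("baseline fluorescence mean must be positive")
    if peaks.size == 0:
        raise ValueError("no song events for this neuron")
    return float(np.mean(peaks / baseline_fluorescence_mean))


def interval_fluorescence(trace: FluorescenceTrace, mask: EpochMask) -> dict[str, float]:
    """Mean corrected fluorescence per interval class, normalized to song.

    Returns baseline / peri_pre / peri_post / song means each divided by
    the song mean (song maps to 1 by construction).
    """
    f = np.asarray(trace.corrected, dtype=float)
    if f.size != mask.labels.size:
        raise ValueError("trace and mask must share the frame grid")
    song = f[mask.labels == "song"]
    if song.size == 0:
        raise ValueError("no song frames: interval normalization undefined")
    song_mean = float(np.mean(song))
    out = {}
    for lab in ("baseline", "peri_pre", "peri_post", "song"):
        vals = f[mask.labels == lab]
        out[lab] = float(np.mean(vals)) / song_mean if vals.size else np.nan
    return out


def active_fraction(
    events_by_neuron: dict, phrases: list[Phrase], mask: EpochMask, epoch: str = "song"
) -> np.ndarray:
    """Percentage of imaged neurons active (>= 1 event) in an epoch, per phrase.

    ``epoch`` is "song" or "peri" (the latter pools peri_pre / peri_gap /
    peri_post windows belonging to that phrase).
    """
    if not events_by_neuron:
        raise ValueError("no imaged neurons")
    n_neurons = len(events_by_neuron)
    labels = PERI_LABELS if epoch == "peri" else ("song",)
    fractions = np.zeros(len(phrases))
    for i, p in enumerate(phrases):
        lo = p.onset - mask.pre_window
        hi = p.offset + mask.post_window
        n_active = 0
        for _, events in events_by_neuron.items():
            for e in events:
                if e.epoch_label in labels and lo <= e.onset_time < hi:
                    n_active += 1
                    break
        fractions[i] = 100.0 * n_active / n_neurons
    return fractions
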