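"""Extracellular electrophysiology: multiunit spike detection and
song-aligned normalized rate traces (HVC), and single-unit inter-spike-
interval variability across behavioral epochs (RA).

Multiunit spikes are negative peaks of the 0.3–5 kHz bandpassed voltage
exceeding 4 SD of spontaneous activity, with a 1-ms lockout.  Rates are
binned at 10 ms, averaged across song renditions, smoothed with a 500-ms
moving average, and normalized so 0 is the baseline mean and 1 the song
mean.  Onset/offset latencies are crossings of mean + 2 SD of the
spontaneous rate that persist until song onset (resp. from song offset).
Single-unit regularity is quantified by the coefficient of variation of
within-epoch ISIs, with epochs: spontaneous (> 10 s from song), pre-song
[−2.5, −0.5] s before the first vocal element, song, and post-song
[+0.5, +2.5] s after the last syllable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "MultiUnitChannel",
    "NormalizedRate",
    "EpochISIStats",
    "bandpass_voltage",
    "detect_mu_spikes",
    "aligned_rate",
    "normalize_rate",
    "rate_onset_offset",
    "spontaneous_rate_stats",
    "epoch_isi_cv",
    "epoch_windows_for_bout",
]

FS_DEFAULT = 25_000.0  # Hz
BAND_DEFAULT = (300.0, 5000.0)  # Hz

PRE_SONG_WINDOW = (-2.5, -0.5)  # s relative to first song syllable / intro note
POST_SONG_WINDOW = (0.5, 2.5)  # s relative to last syllable offset
SPONT_EXCLUSION = 10.0  # s from the nearest song bout


@dataclass
class MultiUnitChannel:
    """One electrode channel after filtering and spike detection."""

    channel_id: str | int
    spike_times: np.ndarray
    spont_sd: float
    fs: float = FS_DEFAULT


@dataclass
class NormalizedRate:
    """Rendition-averaged spike rate with smoothing and 0–1 normalization."""

    rel_times: np.ndarray
    rate_raw: np.ndarray
    rate_smooth: np.ndarray
    rate_norm: np.ndarray | None = None
    onset_latency: float | None = None
    offset_latency: float | None = None
    bin_width: float = 0.01


@dataclass(frozen=True)
class EpochISIStats:
    """ISI count and coefficient of variation for one unit in one epoch."""

    unit_id: str | int
    epoch: str
    n_isis: int
    cv: float | None  # None when fewer than min_isis intervals were available

    @property
    def sufficient(self) -> bool:
        return self.cv is not None


def bandpass_voltage(
    voltage: np.ndarray,
    fs: float = FS_DEFAULT,
    band: tuple[float, float] = BAND_DEFAULT,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward)."""
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(voltage, dtype=float))


def detect_mu_spikes(
    voltage: np.ndarray,
    spont_segments: list[tuple[float, float]],
    fs: float = FS_DEFAULT,
    k: float = 4.0,
    lockout: float = 1e-3,
    prefiltered: bool = False,
    channel_id: str | int = 0,
) -> MultiUnitChannel:
    """Detect multiunit spikes as negative peaks below −k·SD of spontaneous activity.

    The SD is computed from the bandpassed voltage over the spontaneous
    segments (seconds, >= 10 s from any song bout by convention of the
    caller).  Peaks within one ``lockout`` interval keep only the first.
    """
    if not spont_segments:
        raise ValueError("at least one spontaneous segment is required")
    v = np.asarray(voltage, dtype=float)
    if not prefiltered:
        v = bandpass_voltage(v, fs=fs)
    t = np.arange(v.size) / fs
    spont_mask = np.zeros(v.size, dtype=bool)
    for a, b in spont_segments:
        spont_mask |= (t >= a) & (t < b)
    if not spont_mask.any():
        raise ValueError("spontaneous segments do not overlap the recording")
    sd = float(np.std(v[spont_mask], ddof=1))
    if sd == 0.0:
        raise ValueError("zero spontaneous SD: cannot set threshold")
    peaks, _ = sps.find_peaks(-v, height=k * sd, distance=max(1, int(round(lockout * fs))))
    return MultiUnitChannel(channel_id=channel_id, spike_times=peaks / fs, spont_sd=sd, fs=fs)


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if n <= 1:
        return x.astype(float)
    kernel = np.ones(n)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def aligned_rate(
    spike_times: np.ndarray,
    alignments: np.ndarray,
    span: tuple[float, float] = (-5.0, 5.0),
    bin_width: float = 0.01,
    smooth: float = 0.5,
) -> NormalizedRate:
    """Rendition-averaged firing rate in 10-ms bins, 500-ms smoothed."""
    alignments = np.atleast_1d(np.asarray(alignments, dtype=float))
    spike_times = np.asarray(spike_times, dtype=float)
    lo, hi = span
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    centers = edges[:-1] + bin_width / 2
    if alignments.size == 0:
        z = np.zeros(centers.size)
        return NormalizedRate(centers, z, z.copy(), bin_width=bin_width)
    per = np.zeros((alignments.size, centers.size))
    for j, t0 in enumerate(alignments):
        counts, _ = np.histogram(spike_times - t0, bins=edges)
        per[j] = counts / bin_width
    rate_raw = per.mean(axis=0)
    n = max(1, int(round(smooth / bin_width)))
    rate_smooth = _moving_average(rate_raw, n)
    return NormalizedRate(centers, rate_raw, rate_smooth, bin_width=bin_width)


def normalize_rate(
    rate: NormalizedRate, baseline_mean: float, song_mean: float
) -> NormalizedRate:
    """Affine rescale of the smoothed rate: baseline mean -> 0, song mean -> 1."""
    if song_mean == baseline_mean:
        raise ValueError("song and baseline mean rates coincide: normalization undefined")
    rate.rate_norm = (rate.rate_smooth - baseline_mean) / (song_mean - baseline_mean)
    return rate


def rate_onset_offset(
    rate: NormalizedRate, spont_mean: float, spont_sd: float, k: float = 2.0
) -> NormalizedRate:
    """Latencies where the smoothed rate crosses mean + k·SD of spontaneous rate.

    Onset latency: earliest pre-song time from which the rate stays above
    threshold all the way to song onset (t = 0).  Offset latency: latest
    post-song time until which the rate has stayed above threshold since
    song offset.  Either is None when never crossed.
    """
    thr = spont_mean + k * spont_sd
    t = rate.rel_times
    r = rate.rate_smooth
    pre = np.flatnonzero(t < 0)
    post = np.flatnonzero(t >= 0)
    onset = None
    if pre.size:
        above = r[pre] > thr
        if above[-1]:
            # walk back from song onset while continuously above threshold
            i = above.size - 1
            while i > 0 and above[i - 1]:
                i -= 1
            onset = float(t[pre[i]])
    offset = None
    if post.size:
        above = r[post] > thr
        if above[0]:
            i = 0
            while i + 1 < above.size and above[i + 1]:
                i += 1
            offset = float(t[post[i]])
    rate.onset_latency = onset
    rate.offset_latency = offset
    return rate


def spontaneous_rate_stats(
    spike_times: np.ndarray,
    spont_segments: list[tuple[float, float]],
    bin_width: float = 0.01,
    smooth: float = 0.5,
) -> tuple[float, float]:
    """Mean and SD of the smoothed spontaneous spike rate.

    Statistics are taken over the 500-ms-smoothed 10-ms-binned rate within
    the spontaneous segments (SD with n − 1 denominator); the raw-bin
    alternative is ``smooth=0``.
    """
    spikes = np.asarray(spike_times, dtype=float)
    chunks = []
    for a, b in spont_segments:
        edges = np.arange(a, b + bin_width / 2, bin_width)
        if edges.size < 2:
            continue
        counts, _ = np.histogram(spikes, bins=edges)
        r = counts / bin_width
        n = max(1, int(round(smooth / bin_width)))
        chunks.append(_moving_average(r, n) if smooth > 0 else r.astype(float))
    if not chunks:
        raise ValueError("no usable spontaneous segments")
    allr = np.concatenate(chunks)
    return float(np.mean(allr)), float(np.std(allr, ddof=1))


# ---------------------------------------------------------------------------
# Single-unit ISI variability


def epoch_windows_for_bout(
    bout_onset: float, bout_offset: float
) -> dict[str, tuple[float, float]]:
    """Pre-song / song / post-song epoch windows for one song bout."""
    return {
        "pre_song": (bout_onset + PRE_SONG_WINDOW[0], bout_onset + PRE_SONG_WINDOW[1]),
        "song": (bout_onset, bout_offset),
        "post_song": (bout_offset + POST_SONG_WINDOW[0], bout_offset + POST_SONG_WINDOW[1]),
    }


def epoch_isi_cv(
    spike_times: np.ndarray,
    epoch_windows: dict[str, list[tuple[float, float]]],
    unit_id: str | int = 0,
    min_isis: int = 5,
) -> dict[str, EpochISIStats]:
    """Coefficient of variation of within-epoch ISIs, pooled across bouts.

    Only intervals whose two bounding spikes both fall inside one window
    count; ISIs spanning an epoch boundary are discarded.  Epochs with
    fewer than ``min_isis`` intervals are marked insufficient (cv None).
    The CV uses the sample SD (n − 1 denominator).
    """
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    out = {}
    for epoch, windows in epoch_windows.items():
        isis = []
        for a, b in windows:
            inside = spikes[(spikes >= a) & (spikes < b)]
            if inside.size >= 2:
                isis.append(np.diff(inside))
        pooled = np.concatenate(isis) if isis else np.zeros(0)
        if pooled.size < min_isis:
            out[epoch] = EpochISIStats(unit_id, epoch, int(pooled.size), None)
        else:
            cv = float(np.std(pooled, ddof=1) / np.mean(pooled))
            out[epoch] = EpochISIStats(unit_id, epoch, int(pooled.size), cv)
    return out
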