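"""Air-sac pressure analysis: respiratory-cycle segmentation and
song-aligned cycle statistics.

A respiratory cycle is an inspiration (subambient pressure) followed by
an expiration (return to or above ambient).  For each cycle we compute
its duration, the expiratory duty cycle (% of the cycle spent above
ambient), and the mean rectified amplitude.  Cycles are aligned to song
by two markers: song onset is the inspiration onset of the last cycle
beginning before the first introductory note, and song offset is the end
of the expiration generating the last song syllable.

Segmentation uses hysteretic crossings of the ambient level (band = ±5 %
of the quiet-breathing peak-to-peak amplitude, to suppress chatter on
slow asymptotic returns to ambient) but reports crossing times backtracked
to the exact ambient crossing, so cycle boundaries are sample-accurate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile

from .behavior import SongTimeline

__all__ = [
    "PressureTrace",
    "RespiratoryCycle",
    "read_pressure_wav",
    "segment_cycles",
    "song_markers",
    "summarize_epochs",
    "cycles_to_frame",
]

LOWPASS_HZ = 400.0


@dataclass
class PressureTrace:
    """Sampled relative air-sac pressure (ambient ~ 0 after correction)."""

    samples: np.ndarray
    fs: float
    ambient_level: float | None = None
    song_onset_marker: float | None = None
    song_offset_marker: float | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class RespiratoryCycle:
    """One inspiration + expiration cycle."""

    insp_onset: float
    exp_onset: float
    cycle_end: float
    amplitude: float
    rel_time: float | None = None
    epoch: str | None = None

    @property
    def duration(self) -> float:
        return self.cycle_end - self.insp_onset

    @property
    def duty_cycle(self) -> float:
        """Percent of the cycle spent in the expiratory (supra-ambient) phase."""
        return 100.0 * (self.cycle_end - self.exp_onset) / self.duration


def read_pressure_wav(path) -> PressureTrace:
    """Read a 16-bit WAV pressure recording into a PressureTrace."""
    fs, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    return PressureTrace(samples=data.astype(float), fs=float(fs))


def _interp_crossing(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def segment_cycles(
    trace: PressureTrace,
    quiet_window: tuple[float, float] | None = None,
    hysteresis: float = 0.05,
    lowpass: float = LOWPASS_HZ,
    ambient: float | None = None,
    _refine: bool = True,
) -> list[RespiratoryCycle]:
    """Segment a pressure trace into respiratory cycles.

    A cycle begins when the low-passed signal drops through ambient by
    more than the hysteresis band (±``hysteresis`` of the quiet-breathing
    peak-to-peak amplitude), enters expiration when it rises back through
    ambient, and ends at the next inspiratory crossing.  Partial cycles
    at the trace edges are dropped.  Crossing times are linearly
    interpolated at the exact ambient level, so boundaries are
    sample-accurate.  Segmentation is invariant to positive rescaling of
    the signal.

    The ambient level is ``trace.ambient_level`` or the ``ambient``
    argument when given.  Otherwise it is estimated in two passes: an
    initial median over ``quiet_window`` (default: the first 3 s), then a
    refinement to the signal mean over the complete quiet cycles found in
    that window — over a whole cycle the net airflow, hence the mean
    relative pressure, is approximately zero, which removes the duty-cycle
    bias of the raw median on asymmetric breathing waveforms.
    """
    x = np.asarray(trace.samples, dtype=float)
    fs = trace.fs
    if lowpass and lowpass < fs / 2:
        sos = sps.butter(4, lowpass, btype="low", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
    if quiet_window is None:
        quiet_window = (0.0, min(3.0, x.size / fs))
    qa, qb = quiet_window
    quiet = x[int(qa * fs) : max(int(qb * fs), int(qa * fs) + 1)]
    if ambient is None:
        ambient = trace.ambient_level
    if ambient is None:
        ambient = float(np.median(quiet))
        if _refine:
            first_pass = segment_cycles(
                trace, quiet_window, hysteresis, lowpass, ambient=ambient, _refine=False
            )
            in_window = [c for c in first_pass if qa <= c.insp_onset and c.cycle_end <= qb]
            if in_window:
                i0 = int(in_window[0].insp_onset * fs)
                i1 = int(in_window[-1].cycle_end * fs)
                if i1 > i0:
                    ambient = float(np.mean(x[i0:i1]))
    trace.ambient_level = ambient
    p2p = float(np.ptp(quiet))
    if p2p == 0.0:
        return []
    band = hysteresis * p2p
    t = trace.times

    # hysteretic state machine: -1 inspiratory, +1 expiratory, 0 undecided
    lo_cross = np.flatnonzero((x[:-1] >= ambient - band) & (x[1:] < ambient - band))
    hi_cross = np.flatnonzero((x[:-1] <= ambient + band) & (x[1:] > ambient + band))
    events = sorted(
        [(i, -1) for i in lo_cross] + [(i, +1) for i in hi_cross], key=lambda e: e[0]
    )
    # debounce: keep only alternating state changes
    transitions = []
    state = 0
    for i, s in events:
        if s != state:
            transitions.append((i, s))
            state = s

    def exact_cross(i: int) -> float:
        """Backtrack from the hysteresis exit to the true ambient crossing."""
        j = i
        while j > 0 and (x[j] - ambient) * (x[i + 1] - ambient) > 0:
            j -= 1
        return _interp_crossing(t[j], t[j + 1], x[j], x[j + 1], ambient)

    cycles = []
    k = 0
    while k + 2 < len(transitions):
        (i0, s0), (i1, s1), (i2, s2) = transitions[k], transitions[k + 1], transitions[k + 2]
        if (s0, s1, s2) == (-1, +1, -1):
            insp = exact_cross(i0)
            expo = exact_cross(i1)
            end = exact_cross(i2)
            seg = x[int(insp * fs) : int(end * fs) + 1]
            amp = float(np.mean(np.abs(seg - ambient))) if seg.size else 0.0
            cycles.append(RespiratoryCycle(insp, expo, end, amp))
            k += 2  # cycle end is the next cycle's inspiration onset
        else:
            k += 1
    return cycles


def song_markers(
    cycles: list[RespiratoryCycle], timeline: SongTimeline, phrase: int = 0
) -> tuple[float, float]:
    """Song-relative alignment markers for one song phrase.

    Onset: inspiration onset of the last cycle starting before the first
    introductory note (or first song element) of the phrase.  Offset: end
    of the expiration of the cycle containing the phrase's last syllable
    offset.  One song phrase is the unit of respiratory analysis; pass
    ``phrase`` to select among several.
    """
    if not timeline.phrases:
        raise ValueError("timeline contains no song phrases")
    p = timeline.phrases[phrase]
    song_sylls = [
        s
        for s in timeline.syllables
        if s.label.startswith(("intro_note", "motif_syllable"))
        and p.onset <= s.onset < p.offset
    ]
    if not song_sylls or not cycles:
        raise ValueError("need song syllables and at least one cycle")
    first_on = song_sylls[0].onset
    last_off = max(s.offset for s in song_sylls)
    before = [c for c in cycles if c.insp_onset < first_on]
    if not before:
        raise ValueError("no respiratory cycle precedes the first song element")
    onset_marker = before[-1].insp_onset
    containing = [c for c in cycles if c.insp_onset <= last_off < c.cycle_end]
    if containing:
        offset_marker = containing[0].cycle_end
    else:
        after = [c for c in cycles if c.cycle_end > last_off]
        if not after:
            raise ValueError("no respiratory cycle covers the last syllable offset")
        offset_marker = after[0].cycle_end
    return onset_marker, offset_marker


def _assign_epoch(c: RespiratoryCycle, onset: float, offset: float,
                  pre_window: float, post_window: float) -> str | None:
    if onset - pre_window <= c.insp_onset < onset:
        return "pre"
    if onset <= c.insp_onset < offset:
        return "song"
    if offset <= c.insp_onset < offset + post_window:
        return "post"
    return None


def summarize_epochs(
    cycles: list[RespiratoryCycle],
    markers: tuple[float, float],
    pre_window: float = 5.0,
    post_window: float = 5.0,
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Per-epoch and per-1-s-bin means of duration, duty cycle, amplitude.

    Cycles are assigned to pre / song / post epochs by their inspiration
    onset relative to the markers; pre/post cycles are additionally keyed
    to 1-s bins of time before onset (negative bin index) or after offset.
    Returns a tidy frame with one row per (epoch, bin) cell.
    """
    onset, offset = markers
    rows = []
    for c in cycles:
        epoch = _assign_epoch(c, onset, offset, pre_window, post_window)
        if epoch is None:
            continue
        if epoch == "pre":
            rel = c.insp_onset - onset
            b = -int(np.ceil(-rel / bin_width))  # −1 = last second before onset
        elif epoch == "post":
            rel = c.insp_onset - offset
            b = int(np.floor(rel / bin_width)) + 1  # +1 = first second after offset
        else:
            rel, b = c.insp_onset - onset, 0
        rows.append(
            {"epoch": epoch, "bin": b, "rel_time_s": rel,
             "duration_s": c.duration, "duty_pct": c.duty_cycle, "amplitude": c.amplitude}
        )
    per_cycle = pd.DataFrame(rows)
    if per_cycle.empty:
        return per_cycle
    summary = (
        per_cycle.groupby(["epoch", "bin"])
        .agg(n=("duration_s", "size"), duration_s=("duration_s", "mean"),
             duty_pct=("duty_pct", "mean"), amplitude=("amplitude", "mean"))
        .reset_index()
    )
    return summary


def cycles_to_frame(
    cycles: list[RespiratoryCycle], markers: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Tabulate cycles (insp_onset_s, duration_s, duty_pct, amplitude, rel_time_s)."""
    df = pd.DataFrame(
        {
            "insp_onset_s": [c.insp_onset for c in cycles],
            "duration_s": [c.duration for c in cycles],
            "duty_pct": [c.duty_cycle for c in cycles],
            "amplitude": [c.amplitude for c in cycles],
        }
    )
    if markers is not None:
        onset, _ = markers
        df["rel_time_s"] = df["insp_onset_s"] - onset
    return df
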