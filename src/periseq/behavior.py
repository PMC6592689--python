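"""Behavioral timeline segmentation for singing birds.

Builds song bouts, song phrases, and frame-wise behavioral epoch labels
(song / peri-song / baseline / other) from a syllable annotation table.

Conventions
-----------
All intervals are half-open ``[onset, offset)`` in seconds (float64); a
sample or frame at time ``t`` belongs to an interval iff
``onset <= t < offset``.  A *bout* is a run of song elements (introductory
notes and motif syllables) separated by short silences; a *phrase* merges
bouts separated by strictly less than ``gap_threshold`` (2 s) of silence.
Peri-song is the union of the 5-s windows before and after each phrase
plus the silent gaps between bouts inside a phrase.  Baseline requires at
least 10 s of separation from any singing or calling.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyllableInterval",
    "Bout",
    "Phrase",
    "EpochMask",
    "SongTimeline",
    "EligibilityResult",
    "assemble_phrases",
    "build_epoch_mask",
    "eligible_for_pre_analysis",
    "eligible_for_post_analysis",
    "read_annotations",
    "phrases_to_frame",
    "mask_to_runlength",
]

#: labels counting as song elements (can seed bouts/phrases)
SONG_LABELS_PREFIX = ("intro_note", "motif_syllable")
#: all vocal labels (song elements plus calls): reset the baseline clock
VOCAL_LABELS_PREFIX = SONG_LABELS_PREFIX + ("call",)

#: epoch labels collapsed into "peri-song" for event counting
PERI_LABELS = ("peri_pre", "peri_gap", "peri_post")

EPOCH_LABELS = ("song", "peri_pre", "peri_gap", "peri_post", "baseline", "other")


def is_song_element(label: str) -> bool:
    return label.startswith(SONG_LABELS_PREFIX)


def is_vocal(label: str) -> bool:
    return label.startswith(VOCAL_LABELS_PREFIX)


@dataclass(frozen=True)
class SyllableInterval:
    """One annotated vocal (or noise) interval, ``[onset, offset)`` seconds."""

    onset: float
    offset: float
    label: str

    def __post_init__(self):
        if not self.onset < self.offset:
            raise ValueError(
                f"interval must satisfy onset < offset, got [{self.onset}, {self.offset})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class Bout:
    """A run of song elements with no silence >= the bout gap between them."""

    onset: float
    offset: float
    n_syllables: int
    n_motifs: int


@dataclass(frozen=True)
class Phrase:
    """Bouts separated by < 2 s of silence, treated as one singing episode.

    The onset is the onset of the first vocal element (introductory notes
    included); the offset is the offset of the last syllable.
    """

    onset: float
    offset: float
    bouts: tuple[Bout, ...]
    motif_count: int

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    truncated: bool = False

    def __bool__(self) -> bool:  # allows use as a plain boolean
        return self.eligible


def _motif_index(label: str) -> int | None:
    """Parse the within-motif syllable index from labels like 'motif_syllable:2'."""
    if not label.startswith("motif_syllable"):
        return None
    _, _, suffix = label.partition(":")
    try:
        return int(suffix)
    except ValueError:
        return 0


def _count_motifs(syllables: list[SyllableInterval]) -> int:
    """Count motif renditions in a bout.

    A new motif begins whenever the within-motif syllable index does not
    increase (the syllable sequence restarts).  Unindexed motif syllables
    each count as their own run boundary only on restart, so a contiguous
    run of unindexed motif syllables counts as one motif.
    """
    n = 0
    prev = None
    for s in syllables:
        idx = _motif_index(s.label)
        if idx is None:
            continue
        if prev is None or idx <= prev:
            n += 1
        prev = idx
    return n


def _check_sorted(syllables) -> None:
    onsets = [s.onset for s in syllables]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("syllables must be sorted by onset")


def assemble_phrases(
    syllables: list[SyllableInterval],
    gap_threshold: float = 2.0,
    bout_gap: float = 0.5,
) -> list[Phrase]:
    """Group song elements into bouts and bouts into phrases.

    Bouts separated by strictly less than ``gap_threshold`` seconds of
    silence belong to one phrase; a silent gap of exactly the threshold or
    more starts a new phrase.  Calls and noise never seed bouts or phrases.

    Parameters
    ----------
    syllables
        Annotated intervals sorted by onset.
    gap_threshold
        Maximum (exclusive) inter-bout silence within one phrase, seconds.
    bout_gap
        Maximum (exclusive) inter-syllable silence within one bout, seconds.
    """
    _check_sorted(syllables)
    song = [s for s in syllables if is_song_element(s.label)]
    if not song:
        return []

    # group syllables into bouts
    bout_groups: list[list[SyllableInterval]] = [[song[0]]]
    for s in song[1:]:
        if s.onset - bout_groups[-1][-1].offset < bout_gap:
            bout_groups[-1].append(s)
        else:
            bout_groups.append([s])
    bouts = [
        Bout(
            onset=g[0].onset,
            offset=max(s.offset for s in g),
            n_syllables=len(g),
            n_motifs=_count_motifs(g),
        )
        for g in bout_groups
    ]

    # group bouts into phrases: gaps strictly < gap_threshold merge
    phrase_groups: list[list[int]] = [[0]]
    for i in range(1, len(bouts)):
        if bouts[i].onset - bouts[phrase_groups[-1][-1]].offset < gap_threshold:
            phrase_groups[-1].append(i)
        else:
            phrase_groups.append([i])

    phrases = []
    for idxs in phrase_groups:
        bb = tuple(bouts[i] for i in idxs)
        phrases.append(
            Phrase(
                onset=bb[0].onset,
                offset=bb[-1].offset,
                bouts=bb,
                motif_count=sum(b.n_motifs for b in bb),
            )
        )
    return phrases


def _label_points(
    times: np.ndarray, intervals: list[tuple[float, float]], labels: np.ndarray, value: str
) -> None:
    for a, b in intervals:
        labels[(times >= a) & (times < b)] = value


def build_epoch_mask(
    phrases: list[Phrase],
    calls: list[SyllableInterval],
    times: np.ndarray,
    pre_window: float = 5.0,
    post_window: float = 5.0,
    baseline_exclusion: float = 10.0,
) -> "EpochMask":
    """Assign exactly one behavioral epoch label to every time point.

    Precedence (highest first): song (within-bout time), peri_gap (silent
    gaps between bouts inside a phrase), peri_pre / peri_post (up to
    ``pre_window`` / ``post_window`` seconds around each phrase, split at
    the midpoint of the inter-phrase gap when windows would collide),
    baseline (>= ``baseline_exclusion`` seconds from any singing or
    calling), other.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or (times.size > 1 and np.any(np.diff(times) <= 0)):
        raise ValueError("sample grid must be 1-D and strictly increasing")
    phrases = sorted(phrases, key=lambda p: p.onset)
    for a, b in zip(phrases, phrases[1:]):
        if b.onset < a.offset:
            raise ValueError("phrases must be non-overlapping")

    labels = np.full(times.shape, "other", dtype="U9")

    # baseline: >= baseline_exclusion from every bout and every call
    guarded: list[tuple[float, float]] = []
    for p in phrases:
        for b in p.bouts:
            guarded.append((b.onset, b.offset))
    for c in calls:
        guarded.append((c.onset, c.offset))
    ok = np.ones(times.shape, dtype=bool)
    for a, b in guarded:
        ok &= (times <= a - baseline_exclusion) | (times >= b + baseline_exclusion)
    labels[ok] = "baseline"

    # peri windows, clipped at inter-phrase gap midpoints
    for i, p in enumerate(phrases):
        pre_start = p.onset - pre_window
        if i > 0:
            gap_mid = 0.5 * (phrases[i - 1].offset + p.onset)
            pre_start = max(pre_start, gap_mid)
        post_end = p.offset + post_window
        if i + 1 < len(phrases):
            gap_mid = 0.5 * (p.offset + phrases[i + 1].onset)
            post_end = min(post_end, gap_mid)
        _label_points(times, [(pre_start, p.onset)], labels, "peri_pre")
        _label_points(times, [(p.offset, post_end)], labels, "peri_post")

    # within-phrase silent gaps, then song (highest precedence)
    for p in phrases:
        gaps = [
            (a.offset, b.onset) for a, b in zip(p.bouts, p.bouts[1:]) if b.onset > a.offset
        ]
        _label_points(times, gaps, labels, "peri_gap")
        _label_points(times, [(b.onset, b.offset) for b in p.bouts], labels, "song")

    return EpochMask(
        times=times,
        labels=labels,
        pre_window=pre_window,
        post_window=post_window,
        baseline_exclusion=baseline_exclusion,
    )


@dataclass
class EpochMask:
    """Frame-wise epoch labels on a common sample grid."""

    times: np.ndarray
    labels: np.ndarray
    pre_window: float = 5.0
    post_window: float = 5.0
    baseline_exclusion: float = 10.0

    def label_at(self, t: float | np.ndarray) -> np.ndarray:
        """Label of the frame containing time ``t`` (frame-start convention)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.full(t.shape, "other", dtype="U9")
        inside = idx >= 0
        out[inside] = self.labels[idx[inside]]
        if np.any(~inside):
            warnings.warn("events before mask coverage labeled 'other'")
        return out

    def fraction(self, label: str) -> float:
        return float(np.mean(self.labels == label))


def eligible_for_pre_analysis(
    phrase: Phrase,
    syllables: list[SyllableInterval],
    min_silence: float = 5.0,
    trial_start: float = 0.0,
) -> EligibilityResult:
    """True iff no vocal element falls within ``min_silence`` s before phrase onset.

    A phrase starting less than ``min_silence`` after the trial start is
    ineligible and flagged as truncated.
    """
    if phrase.onset - trial_start < min_silence:
        return EligibilityResult(False, truncated=True)
    lo, hi = phrase.onset - min_silence, phrase.onset
    for s in syllables:
        if not is_vocal(s.label):
            continue
        if s.offset > lo and s.onset < hi and not (phrase.onset <= s.onset < phrase.offset):
            return EligibilityResult(False)
    return EligibilityResult(True)


def eligible_for_post_analysis(
    phrase: Phrase,
    syllables: list[SyllableInterval],
    min_silence: float = 5.0,
    trial_end: float = np.inf,
) -> EligibilityResult:
    """True iff no vocal element falls within ``min_silence`` s after phrase offset."""
    if trial_end - phrase.offset < min_silence:
        return EligibilityResult(False, truncated=True)
    lo, hi = phrase.offset, phrase.offset + min_silence
    for s in syllables:
        if not is_vocal(s.label):
            continue
        if s.offset > lo and s.onset < hi and not (phrase.onset <= s.onset < phrase.offset):
            return EligibilityResult(False)
    return EligibilityResult(True)


@dataclass
class SongTimeline:
    """Annotated vocal intervals of one trial plus derived phrases.

    The temporal scaffold shared by all analyses: phrases are assembled
    lazily with the default gap rules and cached.
    """

    syllables: list[SyllableInterval]
    trial_start: float = 0.0
    trial_end: float | None = None
    _phrases: list[Phrase] | None = field(default=None, repr=False)

    def __post_init__(self):
        _check_sorted(self.syllables)
        if self.trial_end is None:
            self.trial_end = max((s.offset for s in self.syllables), default=0.0) + 10.0

    @property
    def phrases(self) -> list[Phrase]:
        if self._phrases is None:
            self._phrases = assemble_phrases(self.syllables)
        return self._phrases

    @property
    def calls(self) -> list[SyllableInterval]:
        return [s for s in self.syllables if s.label.startswith("call")]

    def epoch_mask(self, times: np.ndarray, **kw) -> EpochMask:
        return build_epoch_mask(self.phrases, self.calls, times, **kw)

    def eligible_phrases(self, min_silence: float = 5.0, which: str = "pre") -> list[Phrase]:
        fn = eligible_for_pre_analysis if which == "pre" else eligible_for_post_analysis
        bound = {"trial_start": self.trial_start} if which == "pre" else {"trial_end": self.trial_end}
        return [p for p in self.phrases if fn(p, self.syllables, min_silence, **bound)]


# ---------------------------------------------------------------------------
# I/O

REQUIRED_COLUMNS = ("onset_s", "offset_s", "label")


def read_annotations(path_or_buf, trial_id=None) -> SongTimeline:
    """Read a syllable annotation table (CSV or TSV) into a SongTimeline.

    Expects columns ``onset_s, offset_s, label`` and optionally
    ``trial_id``; validates sorting and non-overlap of same-trial
    intervals.
    """
    if isinstance(path_or_buf, (str, io.IOBase)) or hasattr(path_or_buf, "read"):
        df = pd.read_csv(path_or_buf, sep=None, engine="python")
    else:
        df = pd.read_csv(str(path_or_buf), sep=None, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if trial_id is not None and "trial_id" in df.columns:
        df = df[df["trial_id"] == trial_id]
    if not df["onset_s"].is_monotonic_increasing:
        raise ValueError("annotations must be sorted by onset_s")
    if np.any(df["offset_s"].to_numpy()[:-1] > df["onset_s"].to_numpy()[1:]):
        raise ValueError("annotated intervals overlap")
    sylls = [
        SyllableInterval(float(r.onset_s), float(r.offset_s), str(r.label))
        for r in df.itertuples()
    ]
    return SongTimeline(sylls)


def phrases_to_frame(phrases: list[Phrase], trial_id="trial0") -> pd.DataFrame:
    """Tabulate phrases: (trial_id, phrase_idx, onset_s, offset_s, n_bouts, n_motifs)."""
    return pd.DataFrame(
        {
            "trial_id": trial_id,
            "phrase_idx": np.arange(len(phrases)),
            "onset_s": [p.onset for p in phrases],
            "offset_s": [p.offset for p in phrases],
            "n_bouts": [len(p.bouts) for p in phrases],
            "n_motifs": [p.motif_count for p in phrases],
        }
    )


def mask_to_runlength(mask: EpochMask) -> pd.DataFrame:
    """Run-length-encode an epoch mask as (label, start_s, end_s) rows."""
    lab = mask.labels
    change = np.flatnonzero(lab[1:] != lab[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [lab.size]))
    dt = np.median(np.diff(mask.times)) if mask.times.size > 1 else 0.0
    return pd.DataFrame(
        {
            "label": lab[starts],
            "start_s": mask.times[starts],
            "end_s": np.where(ends < lab.size, mask.times[np.minimum(ends, lab.size - 1)],
                              mask.times[-1] + dt),
        }
    )
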