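"""Ground-truth-annotated synthetic data for every pipeline stage.

Emulates the statistical structure of directed-song recording sessions:
a song timeline (introductory notes, ~0.7 s motifs grouped into bouts and
phrases with silent gaps straddling the 2-s phrase rule), three neuron
classes with class-structured calcium-event statistics (sparse peri-song
events ramping toward −1.5 s before phrase onset; motif-locked song
events with ~55 ms onset jitter and ~0.7 per-motif participation),
GCaMP6s-kernel fluorescence (0.112 s onset-to-peak rise, 1.25 s decay)
with Gaussian noise and slow drift, multiunit spike trains with a rate
ramp beginning ~1.5 s before song, tonic single units that become
irregular in pre/song/post epochs, and air-sac pressure waveforms with
~0.38 s quiet-breathing cycles and ~0.18 s song cycles at 58 % expiratory
duty.

Every generated observable is reproducible from ``(config, seed)``; the
master seed fans out to per-neuron / per-signal substreams through
counter-based spawn keys, so adding a neuron never perturbs the data of
the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .behavior import SongTimeline, SyllableInterval
from .calcium import FluorescenceTrace
from .respiration import PressureTrace

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "PlantedNeuron",
    "gen_timeline",
    "gen_neuron_events",
    "gen_fluorescence",
    "gen_movie",
    "gen_mu_spiketrain",
    "gen_mu_voltage",
    "gen_su_spiketrain",
    "gen_pressure",
    "calcium_kernel",
    "kernel_rise_time",
    "solve_tau_rise",
]


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-based substream: independent of how many other streams exist."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


# stream ids
_TIMELINE, _EVENTS, _FLUOR, _SPIKES, _PRESSURE, _MOVIE = range(6)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic session.

    Defaults mirror the summary statistics of directed zebra finch song
    sessions: 30 fps imaging, phrases of 1–3 bouts of ~0.7 s motifs,
    peri-song event ramps peaking 1.5 s before phrase onset, 55 ms
    song-event onset jitter, 0.112 s calcium rise / 1.25 s decay, and
    respiratory cycles of 0.38 s (quiet, 58 % expiratory duty) vs 0.18 s
    (song).
    """

    # imaging
    fps: float = 30.0
    noise_sd: float = 1.0  # fluorescence white-noise SD, a.u.
    drift_amplitude: float = 0.5  # slow baseline drift, a.u.
    drift_period_s: float = 60.0
    event_amplitude: float = 10.0  # kernel peak in noise-SD units
    tau_decay: float = 1.25  # s (GCaMP6s)
    rise_time: float = 0.112  # s, onset-to-peak

    # timeline
    n_phrases: int = 3
    bouts_per_phrase: tuple[int, ...] = (2, 3, 1)
    motifs_per_bout: int = 2
    syllables_per_motif: int = 4
    syllable_duration: float = 0.12
    syllable_gap: float = 0.05
    n_intro_notes: int = 3
    intro_duration: float = 0.06
    intro_gap: float = 0.12
    inter_bout_gap: float = 1.0  # < 2 s: same phrase
    inter_phrase_gap: float = 22.0  # > 2 s and long enough for baseline
    lead_in_s: float = 12.0
    tail_s: float = 12.0

    # neuron classes and event statistics
    n_per_class: dict = field(
        default_factory=lambda: {"peri_song": 40, "pan_song": 40, "song": 40}
    )
    event_refractory: float = 0.25  # s, min separation of one neuron's events
    peri_peak_rate: float = 0.45  # events/s at the ramp peak
    peri_peak_time: float = -1.5  # s before phrase onset
    peri_ramp_sd: float = 1.0  # s, Gaussian ramp width
    peri_cutoff: float = 0.25  # s, ramp support ends this close to onset/offset
    post_peak_rate: float = 0.35
    post_peak_time: float = 0.5  # s after phrase offset
    gap_rate: float = 0.1  # events/s in within-phrase silent gaps
    motif_participation: float = 0.7  # P(>=1 event per motif) for song-locked units
    onset_jitter_sd: float = 0.055  # s
    song_phase_band: tuple[float, float] = (0.25, 0.75)  # motif fraction for locked events

    # multiunit
    mu_baseline_rate: float = 20.0  # spikes/s
    mu_song_rate: float = 120.0
    mu_step_time: float = -1.5  # s before phrase onset, ramp start
    mu_offset_decay: float = 0.4  # s after phrase offset, ramp back
    mu_fs: float = 25_000.0
    mu_noise_sd: float = 1.0  # voltage units
    mu_spike_amplitude: float = 8.0  # negative peak in noise-SD units

    # single units (gamma-renewal ISI shape per epoch; high shape = regular)
    su_rate: float = 60.0  # spikes/s in every epoch
    su_shapes: dict = field(
        default_factory=lambda: {
            "spontaneous": 8.0,
            "pre_song": 0.7,
            "song": 0.5,
            "post_song": 0.7,
        }
    )

    # respiration
    resp_fs: float = 22_050.0
    quiet_cycle_s: float = 0.38
    quiet_cycle_sd: float = 0.04
    song_cycle_s: float = 0.18
    song_cycle_sd: float = 0.03
    duty: float = 0.58  # expiratory fraction
    quiet_pressure_amp: float = 1.0
    song_pressure_amp: float = 3.0


@dataclass(frozen=True)
class PlantedNeuron:
    neuron_id: int
    neuron_class: str  # peri_song | pan_song | song
    event_times: np.ndarray  # planted event onset times, s
    event_labels: tuple[str, ...]  # "peri" or "song" per planted event


@dataclass
class GroundTruth:
    """Everything needed to score recovery of planted structure."""

    seed: int
    config: GeneratorConfig
    timeline: SongTimeline | None = None
    phrase_bounds: list[tuple[float, float]] = field(default_factory=list)
    motif_onsets: list[tuple[float, float]] = field(default_factory=list)  # (onset, dur)
    neurons: list[PlantedNeuron] = field(default_factory=list)
    kernel_tau_rise: float | None = None
    kernel_rise_time: float | None = None
    mu_spike_times: np.ndarray | None = None
    pressure_cycles: list[tuple[str, float, float, float]] = field(default_factory=list)
    pressure_markers: list[tuple[float, float]] = field(default_factory=list)  # per phrase


# ---------------------------------------------------------------------------
# Calcium kernel


def kernel_rise_time(tau_rise: float, tau_decay: float) -> float:
    """Onset-to-peak time of the difference-of-exponentials kernel."""
    return float(np.log(tau_decay / tau_rise) / (1.0 / tau_rise - 1.0 / tau_decay))


def solve_tau_rise(rise_time: float, tau_decay: float) -> float:
    """Rise time constant giving the requested onset-to-peak interval."""
    return float(
        brentq(lambda tr: kernel_rise_time(tr, tau_decay) - rise_time, 1e-4, tau_decay * 0.999)
    )


def calcium_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference of exponentials normalized to unit peak; zero for t < 0."""
    t = np.maximum(np.asarray(t, dtype=float), 0.0)
    k = np.where(t > 0, np.exp(-t / tau_decay) - np.exp(-t / tau_rise), 0.0)
    tp = kernel_rise_time(tau_rise, tau_decay)
    peak = np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)
    return k / peak


# ---------------------------------------------------------------------------
# Timeline


def gen_timeline(config: GeneratorConfig, seed: int) -> tuple[SongTimeline, GroundTruth]:
    """Emit a directed-song timeline with recorded true phrase boundaries."""
    truth = GroundTruth(seed=seed, config=config)
    sylls: list[SyllableInterval] = []
    motif_dur = (
        config.syllables_per_motif * config.syllable_duration
        + (config.syllables_per_motif - 1) * config.syllable_gap
    )
    t = config.lead_in_s
    bouts_seq = config.bouts_per_phrase
    for p in range(config.n_phrases):
        phrase_start = t
        for j in range(config.n_intro_notes):
            sylls.append(SyllableInterval(t, t + config.intro_duration, "intro_note"))
            t += config.intro_duration + config.intro_gap
        n_bouts = bouts_seq[p % len(bouts_seq)]
        for b in range(n_bouts):
            for m in range(config.motifs_per_bout):
                truth.motif_onsets.append((t, motif_dur))
                for s in range(config.syllables_per_motif):
                    sylls.append(
                        SyllableInterval(t, t + config.syllable_duration, f"motif_syllable:{s}")
                    )
                    t += config.syllable_duration + config.syllable_gap
                # inter-motif gap equals the syllable gap: motifs run on as one bout
            if b + 1 < n_bouts:
                t = sylls[-1].offset + config.inter_bout_gap
        phrase_end = sylls[-1].offset
        if phrase_end <= phrase_start:
            raise ValueError("infeasible schedule: empty phrase")
        truth.phrase_bounds.append((phrase_start, phrase_end))
        t = phrase_end + config.inter_phrase_gap
    trial_end = sylls[-1].offset + config.tail_s
    timeline = SongTimeline(sylls, trial_start=0.0, trial_end=trial_end)
    for (a0, b0), (a1, b1) in zip(truth.phrase_bounds, truth.phrase_bounds[1:]):
        if a1 <= b0:
            raise ValueError("infeasible schedule: phrases overlap")
    truth.timeline = timeline
    return timeline, truth


# ---------------------------------------------------------------------------
# Planted calcium events


def _thinned_poisson(
    rng: np.random.Generator, lo: float, hi: float, rate_fn, rate_max: float
) -> np.ndarray:
    """Inhomogeneous Poisson samples on [lo, hi) by thinning."""
    if hi <= lo or rate_max <= 0:
        return np.zeros(0)
    n = rng.poisson(rate_max * (hi - lo))
    cand = np.sort(rng.uniform(lo, hi, size=n))
    keep = rng.uniform(0, rate_max, size=n) < rate_fn(cand)
    return cand[keep]


def _peri_event_times(
    rng: np.random.Generator, truth: GroundTruth, config: GeneratorConfig
) -> np.ndarray:
    """Sparse peri-song events: pre-onset ramp, post-offset bump, gap activity."""
    times = []
    for onset, offset in truth.phrase_bounds:
        # pre-onset Gaussian ramp peaking at peri_peak_time before onset
        def pre_rate(t, onset=onset):
            rel = t - onset
            return config.peri_peak_rate * np.exp(
                -0.5 * ((rel - config.peri_peak_time) / config.peri_ramp_sd) ** 2
            )

        times.append(
            _thinned_poisson(
                rng, onset - 5.0, onset - config.peri_cutoff, pre_rate, config.peri_peak_rate
            )
        )

        def post_rate(t, offset=offset):
            rel = t - offset
            return config.post_peak_rate * np.exp(
                -0.5 * ((rel - config.post_peak_time) / config.peri_ramp_sd) ** 2
            )

        times.append(
            _thinned_poisson(
                rng, offset + config.peri_cutoff, offset + 5.0, post_rate, config.post_peak_rate
            )
        )
    # within-phrase silent gaps (between bouts)
    if truth.timeline is not None and config.gap_rate > 0:
        for p in truth.timeline.phrases:
            for b0, b1 in zip(p.bouts, p.bouts[1:]):
                lo, hi = b0.offset + 0.1, b1.onset - 0.1
                times.append(
                    _thinned_poisson(rng, lo, hi, lambda t: np.full_like(t, config.gap_rate),
                                     config.gap_rate)
                )
    all_t = np.sort(np.concatenate(times)) if times else np.zeros(0)
    return all_t


def _song_event_times(
    rng: np.random.Generator, truth: GroundTruth, config: GeneratorConfig
) -> np.ndarray:
    """Motif-locked events: fixed per-neuron phase + Gaussian jitter."""
    phase = rng.uniform(*config.song_phase_band)
    times = []
    for onset, dur in truth.motif_onsets:
        if rng.uniform() >= config.motif_participation:
            continue
        t = onset + phase * dur + rng.normal(0.0, config.onset_jitter_sd)
        times.append(t)
    return np.sort(np.asarray(times))


def _enforce_refractory(
    times: np.ndarray, labels: tuple[str, ...], refractory: float
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Drop events closer than ``refractory`` to their predecessor.

    Calcium transients are burst events of finite width; closer spacings
    are unresolvable at the imaging frame rate and do not occur in the
    emulated data.
    """
    if times.size <= 1 or refractory <= 0:
        return times, labels
    keep = [0]
    for i in range(1, times.size):
        if times[i] - times[keep[-1]] >= refractory:
            keep.append(i)
    keep = np.asarray(keep)
    return times[keep], tuple(labels[i] for i in keep)


def gen_neuron_events(truth: GroundTruth, config: GeneratorConfig, seed: int) -> GroundTruth:
    """Plant per-neuron event times for the three neuron classes."""
    neurons = []
    nid = 0
    for cls, n in config.n_per_class.items():
        for i in range(n):
            rng = _rng(seed, _EVENTS, nid)
            if cls == "peri_song":
                t = _peri_event_times(rng, truth, config)
                labels = ("peri",) * t.size
            elif cls == "song":
                t = _song_event_times(rng, truth, config)
                labels = ("song",) * t.size
            elif cls == "pan_song":
                tp = _peri_event_times(rng, truth, config)
                ts = _song_event_times(rng, truth, config)
                t = np.concatenate([tp, ts])
                labels = tuple(
                    lab for _, lab in sorted(
                        [(x, "peri") for x in tp] + [(x, "song") for x in ts]
                    )
                )
                t = np.sort(t)
            else:
                raise ValueError(f"unknown neuron class {cls!r}")
            t, labels = _enforce_refractory(t, labels, config.event_refractory)
            neurons.append(PlantedNeuron(nid, cls, t, labels))
            nid += 1
    truth.neurons = neurons
    return truth


# ---------------------------------------------------------------------------
# Fluorescence


def gen_fluorescence(
    neuron: PlantedNeuron,
    truth: GroundTruth,
    config: GeneratorConfig,
    seed: int,
    noise_sd: float | None = None,
    drift_amplitude: float | None = None,
) -> FluorescenceTrace:
    """Render one neuron's planted events into a noisy fluorescence trace.

    trace = sum_events A * kernel(t − t_event) + slow sinusoidal drift +
    white Gaussian noise.  Noise and drift can be overridden (e.g. zero
    for noise-free round-trip tests).
    """
    rng = _rng(seed, _FLUOR, neuron.neuron_id)
    noise_sd = config.noise_sd if noise_sd is None else noise_sd
    drift_amp = config.drift_amplitude if drift_amplitude is None else drift_amplitude
    tau_rise = solve_tau_rise(config.rise_time, config.tau_decay)
    truth.kernel_tau_rise = tau_rise
    truth.kernel_rise_time = kernel_rise_time(tau_rise, config.tau_decay)
    duration = truth.timeline.trial_end
    n_frames = int(np.ceil(duration * config.fps))
    t = np.arange(n_frames) / config.fps
    clean = np.zeros(n_frames)
    amp = config.event_amplitude * config.noise_sd
    for te in neuron.event_times:
        clean += amp * calcium_kernel(t - te, tau_rise, config.tau_decay)
    drift = drift_amp * np.sin(2 * np.pi * t / config.drift_period_s + rng.uniform(0, 2 * np.pi))
    noise = rng.normal(0.0, noise_sd, size=n_frames) if noise_sd > 0 else 0.0
    raw = clean + drift + noise
    return FluorescenceTrace(frame_times=t, raw=raw, neuron_id=neuron.neuron_id)


def gen_movie(
    traces: list[FluorescenceTrace],
    config: GeneratorConfig,
    seed: int,
    shape: tuple[int, int] = (48, 48),
    footprint_sd: float = 1.6,
    background_level: float = 20.0,
    background_noise: float = 0.2,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Render traces as a movie of 2-D Gaussian somata plus noisy background.

    Returns (movie, roi_masks); masks threshold each footprint at half
    maximum.  Neuron centers are laid out on a jittered grid.
    """
    rng = _rng(seed, _MOVIE)
    h, w = shape
    n = len(traces)
    n_frames = len(traces[0].frame_times)
    side = int(np.ceil(np.sqrt(n)))
    margin = 6
    xs = np.linspace(margin, w - margin, side)
    ys = np.linspace(margin, h - margin, side)
    centers = [(ys[i // side], xs[i % side]) for i in range(n)]
    yy, xx = np.mgrid[0:h, 0:w]
    footprints = []
    masks = []
    for cy, cx in centers:
        fp = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * footprint_sd**2))
        footprints.append(fp)
        masks.append(fp > 0.5)
    movie = np.full((n_frames, h, w), background_level, dtype=float)
    movie += rng.normal(0.0, background_noise, size=movie.shape)
    for tr, fp in zip(traces, footprints):
        movie += tr.raw[:, None, None] * fp[None, :, :]
    return movie, masks


# ---------------------------------------------------------------------------
# Spike trains


def mu_rate_profile(t: np.ndarray, truth: GroundTruth, config: GeneratorConfig) -> np.ndarray:
    """Multiunit rate: baseline, pre-song ramp from the step time, song plateau."""
    t = np.asarray(t, dtype=float)
    rate = np.full(t.shape, config.mu_baseline_rate)
    for onset, offset in truth.phrase_bounds:
        ramp = (t >= onset + config.mu_step_time) & (t < onset)
        frac = (t[ramp] - (onset + config.mu_step_time)) / (-config.mu_step_time)
        rate[ramp] = config.mu_baseline_rate + frac * (
            config.mu_song_rate - config.mu_baseline_rate
        )
        rate[(t >= onset) & (t < offset)] = config.mu_song_rate
        decay = (t >= offset) & (t < offset + config.mu_offset_decay)
        frac = 1.0 - (t[decay] - offset) / config.mu_offset_decay
        rate[decay] = config.mu_baseline_rate + frac * (
            config.mu_song_rate - config.mu_baseline_rate
        )
    return rate


def gen_mu_spiketrain(truth: GroundTruth, config: GeneratorConfig, seed: int) -> np.ndarray:
    """Inhomogeneous Poisson multiunit spike times over the whole trial."""
    rng = _rng(seed, _SPIKES, 0)
    spikes = _thinned_poisson(
        rng, 0.0, truth.timeline.trial_end,
        lambda t: mu_rate_profile(t, truth, config), config.mu_song_rate,
    )
    truth.mu_spike_times = spikes
    return spikes


def gen_mu_voltage(
    spike_times: np.ndarray, duration: float, config: GeneratorConfig, seed: int
) -> np.ndarray:
    """Embed biphasic spike shapes in Gaussian noise at the recording rate."""
    rng = _rng(seed, _SPIKES, 1)
    fs = config.mu_fs
    n = int(np.ceil(duration * fs))
    v = rng.normal(0.0, config.mu_noise_sd, size=n)
    # biphasic template: sharp negative trough then smaller positive rebound
    tt = np.arange(int(0.002 * fs)) / fs
    template = -np.exp(-0.5 * ((tt - 0.0004) / 0.00012) ** 2) + 0.4 * np.exp(
        -0.5 * ((tt - 0.0009) / 0.00025) ** 2
    )
    template *= config.mu_spike_amplitude * config.mu_noise_sd
    trough = int(round(0.0004 * fs))  # align the template trough to the spike time
    for ts in spike_times:
        i = int(round(ts * fs)) - trough
        j = min(i + template.size, n)
        if 0 <= i < n:
            v[i:j] += template[: j - i]
    return v


def gen_su_spiketrain(
    epoch_windows: dict[str, list[tuple[float, float]]],
    config: GeneratorConfig,
    seed: int,
    unit_id: int = 0,
) -> np.ndarray:
    """Gamma-renewal single-unit spikes with per-epoch ISI shape.

    High shape gives regular (tonic) firing, low shape irregular/bursty
    firing; the mean rate is the same in every epoch.
    """
    rng = _rng(seed, _SPIKES, 2, unit_id)
    spikes = []
    for epoch, windows in epoch_windows.items():
        shape = config.su_shapes[epoch]
        scale = 1.0 / (shape * config.su_rate)  # mean ISI = 1/rate
        for a, b in windows:
            t = a + rng.gamma(shape, scale)
            while t < b:
                spikes.append(t)
                t += rng.gamma(shape, scale)
    return np.sort(np.asarray(spikes))


# ---------------------------------------------------------------------------
# Pressure


def gen_pressure(truth: GroundTruth, config: GeneratorConfig, seed: int) -> PressureTrace:
    """Concatenated respiratory cycles rendered as half-sine pressure waves.

    Quiet cycles (~0.38 s) run outside song; song-length cycles (~0.18 s)
    with larger amplitude run between phrase onset and offset.  True cycle
    boundaries and the song onset/offset markers are recorded in the
    ground truth.
    """
    rng = _rng(seed, _PRESSURE)
    timeline = truth.timeline
    fs = config.resp_fs
    duration = timeline.trial_end
    n = int(np.ceil(duration * fs))
    x = np.zeros(n)
    t = 0.0
    cycles = []

    def draw(mean, sd):
        if sd == 0:
            return mean
        d = rng.normal(mean, sd)
        while d < 0.05:
            d = rng.normal(mean, sd)
        return d

    def in_song(time: float) -> bool:
        return any(a <= time < b for a, b in truth.phrase_bounds)

    while t < duration:
        song = in_song(t)
        dur = draw(config.song_cycle_s, config.song_cycle_sd) if song else draw(
            config.quiet_cycle_s, config.quiet_cycle_sd
        )
        amp = config.song_pressure_amp if song else config.quiet_pressure_amp
        d_in = (1.0 - config.duty) * dur
        d_ex = config.duty * dur
        # flow balance: inspiration is deeper and shorter so the net
        # airflow over one cycle vanishes (as in real air-sac recordings)
        a_in = amp * d_ex / d_in
        i0 = int(round(t * fs))
        i1 = int(round((t + d_in) * fs))
        i2 = int(round((t + dur) * fs))
        tt_in = np.arange(i0, min(i1, n)) / fs - t
        x[i0 : min(i1, n)] = -a_in * np.sin(np.pi * tt_in / d_in)
        tt_ex = np.arange(min(i1, n), min(i2, n)) / fs - (t + d_in)
        x[min(i1, n) : min(i2, n)] = amp * np.sin(np.pi * tt_ex / d_ex)
        cycles.append(("song" if song else "quiet", t, d_in, d_ex))
        t += dur
    truth.pressure_cycles = cycles

    markers = []
    for first_on, last_off in truth.phrase_bounds:
        onset_marker = max(c[1] for c in cycles if c[1] < first_on)
        offset_marker = None
        for _, start, d_in, d_ex in cycles:
            if start <= last_off < start + d_in + d_ex:
                offset_marker = start + d_in + d_ex
                break
        if offset_marker is None:
            after = [c for c in cycles if c[1] + c[2] + c[3] > last_off]
            offset_marker = after[0][1] + after[0][2] + after[0][3]
        markers.append((onset_marker, offset_marker))
    truth.pressure_markers = markers
    return PressureTrace(samples=x, fs=fs)
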