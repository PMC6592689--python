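"""Phrase index, neuron classes, rate traces, and population statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periseq import behavior, population, synth
from periseq.calcium import CalciumEvent, FluorescenceTrace
from periseq.population import (
    NeuronSummary,
    classify_neuron,
    event_rate_trace,
    event_snr,
    interval_fluorescence,
    label_events,
    onset_prediction,
    perievent_histogram,
    phrase_index,
    summarize_neuron,
)


def ev(onset, neuron_id=0, label=None):
    return CalciumEvent(neuron_id, onset, onset + 0.1, 5.0, 5.0, epoch_label=label)


class TestPhraseIndex:
    @pytest.mark.parametrize(
        "n_song, n_peri, expected",
        [(5, 0, 1.0), (0, 5, -1.0), (3, 1, 0.5), (1, 1, 0.0)],
    )
    def test_values(self, n_song, n_peri, expected):
        assert phrase_index(n_song, n_peri) == pytest.approx(expected)

    @pytest.mark.parametrize("n_song, n_peri", [(0, 0), (1, 0), (0, 1)])
    def test_sparse_neurons_excluded(self, n_song, n_peri):
        assert phrase_index(n_song, n_peri) is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            phrase_index(-1, 2)

    @given(st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_and_bounded(self, a, b):
        pi = phrase_index(a, b)
        if pi is None:
            assert a + b < 2
        else:
            assert -1.0 <= pi <= 1.0
            assert phrase_index(b, a) == pytest.approx(-pi)


class TestClassification:
    @pytest.mark.parametrize(
        "pi, cls",
        [(-1.0, "peri_song"), (1.0, "song"), (0.07, "pan_song"), (None, "excluded")],
    )
    def test_class_boundaries(self, pi, cls):
        s = NeuronSummary(0, 0, 0, phrase_index=pi)
        assert classify_neuron(s).neuron_class == cls

    def test_pan_song_band_query(self):
        inside = classify_neuron(NeuronSummary(0, 51, 49, phrase_index=0.02))
        outside = classify_neuron(NeuronSummary(1, 8, 2, phrase_index=0.6))
        assert population.in_pan_song_band(inside)
        assert not population.in_pan_song_band(outside)

    def test_event_labels_drive_summary(self):
        events = [ev(0, label="song")] * 3 + [ev(0, label="peri_pre")] + [
            ev(0, label="baseline")
        ]
        s = summarize_neuron(0, events)
        assert (s.n_song_events, s.n_peri_events, s.n_other_events) == (3, 1, 1)
        assert s.phrase_index == pytest.approx(0.5)


class TestLabelEvents:
    def test_onset_frame_governs(self, session):
        timeline, _, mask = session
        p = timeline.phrases[0]
        # onset 170 ms before song with rise extending past onset: still peri
        e = CalciumEvent(0, p.onset - 0.17, p.onset + 0.1, 5.0, 5.0)
        (labeled,) = label_events([e], mask)
        assert labeled.epoch_label == "peri_pre"

    def test_gap_events_count_as_peri(self, session):
        timeline, _, mask = session
        p = next(p for p in timeline.phrases if len(p.bouts) > 1)
        gap_mid = 0.5 * (p.bouts[0].offset + p.bouts[1].onset)
        (labeled,) = label_events([ev(gap_mid)], mask)
        assert labeled.epoch_label == "peri_gap"
        assert labeled.epoch_label in behavior.PERI_LABELS


class TestEventRateTrace:
    def test_unsmoothed_trace_conserves_counts(self):
        rng = np.random.default_rng(3)
        events = rng.uniform(-5, 5, 200)
        rt = event_rate_trace(events, [0.0])
        assert np.sum(rt.rate) * rt.bin_width == pytest.approx(200)

    def test_uniform_events_give_flat_rate(self):
        events = np.arange(10) * 0.1 + 1.0 + 0.05  # 10 events in [1, 2) s
        rt = event_rate_trace(events, [0.0])
        span = (rt.rel_times > 1.0) & (rt.rel_times < 2.0)
        assert rt.rate[span] == pytest.approx(10.0)

    def test_smoothing_nearly_preserves_integral(self):
        rng = np.random.default_rng(4)
        events = rng.uniform(-5, 5, 500)
        rt = event_rate_trace(events, [0.0])
        raw_int = np.sum(rt.rate) * rt.bin_width
        smooth_int = np.sum(rt.rate_smooth) * rt.bin_width
        assert abs(smooth_int - raw_int) / raw_int < 0.05

    def test_smoothing_never_crosses_the_alignment_point(self):
        # all events after t=0: smoothed pre-onset rate must stay exactly zero
        events = np.full(50, 0.3)
        rt = event_rate_trace(events, [0.0])
        assert not rt.rate_smooth[rt.rel_times < 0].any()

    def test_empty_alignments(self):
        rt = event_rate_trace(np.array([1.0]), np.array([]))
        assert rt.n_trials == 0 and not rt.rate.any()

    def test_planted_ramp_peak_recovered(self, config):
        from dataclasses import replace

        cfg = replace(config, n_phrases=25)
        _, truth = synth.gen_timeline(cfg, 11)
        truth = synth.gen_neuron_events(truth, cfg, 11)
        onsets = np.array([a for a, _ in truth.phrase_bounds])
        events = np.concatenate(
            [n.event_times for n in truth.neurons if n.neuron_class == "peri_song"]
        )
        rt = event_rate_trace(events, onsets)
        pre = rt.rel_times < 0
        peak_t = rt.rel_times[pre][np.argmax(rt.rate_smooth[pre])]
        assert abs(peak_t - config.peri_peak_time) <= 0.3


class TestPerieventHistogram:
    def test_event_vs_neuron_mode(self):
        onsets = np.array([0.55, 0.58])
        ids = np.array([7, 7])
        _, ev_counts = perievent_histogram(onsets, [0.0], neuron_ids=ids)
        _, n_counts = perievent_histogram(onsets, [0.0], neuron_ids=ids, mode="neurons")
        assert ev_counts.sum() == 2 and n_counts.sum() == 1

    def test_matches_bruteforce_binning(self):
        rng = np.random.default_rng(9)
        onsets = rng.uniform(-5, 5, 300)
        centers, counts = perievent_histogram(onsets, [0.0])
        brute = [
            np.sum((onsets >= c - 0.1) & (onsets < c + 0.1)) for c in centers
        ]
        assert counts == pytest.approx(brute)

    def test_empty_input_all_zero(self):
        _, counts = perievent_histogram(np.array([]), [0.0])
        assert not counts.any()


class TestOnsetPrediction:
    def test_step_crossing_located(self):
        t = np.arange(-5, 5, 0.1) + 0.05
        rate = np.where(t >= -2.0, 10.0, 0.0)
        rt = population.RateTrace("phrase_onset", t, rate, rate, 0.1, 1.0, 1)
        op = onset_prediction(rt)
        assert op.crossing_time == pytest.approx(-2.0, abs=0.1)

    def test_constant_rate_undefined(self):
        t = np.arange(-5, 5, 0.1) + 0.05
        rate = np.full(t.size, 3.0)
        rt = population.RateTrace("phrase_onset", t, rate, rate, 0.1, 1.0, 1)
        assert onset_prediction(rt).crossing_time is None

    def test_crossing_precedes_planted_onset(self, config):
        from dataclasses import replace

        cfg = replace(config, n_phrases=25)
        _, truth = synth.gen_timeline(cfg, 13)
        truth = synth.gen_neuron_events(truth, cfg, 13)
        events = np.concatenate(
            [
                n.event_times
                for n in truth.neurons
                if n.neuron_class in ("peri_song", "pan_song")
            ]
        )
        n_prec = 0
        for t0, _ in truth.phrase_bounds:
            op = onset_prediction(event_rate_trace(events, [t0]))
            n_prec += op.crossing_time is not None and op.crossing_time < 0
        assert n_prec / len(truth.phrase_bounds) >= 0.95


class TestSnrAndIntervals:
    def test_snr_arithmetic(self):
        assert event_snr([50.0], 5.0) == pytest.approx(10.0)
        assert event_snr([40.0, 60.0], 10.0) == pytest.approx(5.0)
        with pytest.raises(ValueError):
            event_snr([1.0], 0.0)

    def test_equal_amplitude_classes_not_separable(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(21)
        a = [event_snr(rng.normal(50, 5, 5), 5.0) for _ in range(40)]
        b = [event_snr(rng.normal(50, 5, 5), 5.0) for _ in range(40)]
        assert ttest_ind(a, b).pvalue > 0.05

    def test_interval_fluorescence_normalized_to_song(self, session):
        timeline, _, mask = session
        f = np.where(mask.labels == "song", 10.0, 2.69)
        tr = FluorescenceTrace(frame_times=mask.times, raw=f)
        out = interval_fluorescence(tr, mask)
        assert out["song"] == pytest.approx(1.0)
        assert out["peri_pre"] == pytest.approx(0.269)

    def test_constant_trace_all_ones(self, session):
        _, _, mask = session
        tr = FluorescenceTrace(frame_times=mask.times, raw=np.full(mask.times.size, 7.0))
        out = interval_fluorescence(tr, mask)
        for v in out.values():
            assert v == pytest.approx(1.0)


class TestActiveFraction:
    def test_fraction_arithmetic(self, session):
        timeline, _, mask = session
        p = timeline.phrases[0]
        mid = 0.5 * (p.bouts[0].onset + p.bouts[0].offset)
        events = {i: [ev(mid, i, "song")] for i in range(6)}
        events.update({i: [] for i in range(6, 10)})
        frac = population.active_fraction(events, [p], mask, epoch="song")
        assert frac == pytest.approx([60.0])

    def test_no_events_gives_zero(self, session):
        timeline, _, mask = session
        events = {i: [] for i in range(5)}
        frac = population.active_fraction(events, timeline.phrases, mask)
        assert frac == pytest.approx(np.zeros(len(timeline.phrases)))
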