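"""Baseline estimation, PAVA deconvolution, and event detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import LinearConstraint, minimize

from periseq import calcium, synth
from periseq.calcium import (
    FluorescenceTrace,
    deconvolve_pava,
    detect_events,
    estimate_baseline_noise,
    extract_roi_traces,
    normalize_trace,
)


def qp_oracle(y, gamma):
    """Brute-force constrained quadratic solve of the deconvolution problem."""
    n = y.size
    A = np.zeros((n, n))
    A[0, 0] = 1.0
    for t in range(1, n):
        A[t, t] = 1.0
        A[t, t - 1] = -gamma
    res = minimize(
        lambda c: np.sum((y - c) ** 2),
        np.maximum(y, 0.0),
        jac=lambda c: 2 * (c - y),
        constraints=[LinearConstraint(A, 0.0, np.inf)],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    return res.fun


class TestDeconvolvePava:
    def test_zero_input_zero_output(self, gamma):
        d = deconvolve_pava(np.zeros(50), gamma)
        assert not d.inferred.any() and not d.drive.any()

    def test_exact_ar1_response_is_fixed_point(self, gamma):
        y = 5.0 * gamma ** np.arange(40)
        d = deconvolve_pava(y, gamma)
        assert d.inferred == pytest.approx(y)
        assert d.drive[0] == pytest.approx(5.0)
        assert d.drive[1:] == pytest.approx(np.zeros(39), abs=1e-9)

    def test_matches_qp_oracle_on_random_inputs(self, gamma):
        rng = np.random.default_rng(42)
        for _ in range(100):
            y = rng.normal(0, 1, 20) + np.maximum(0, rng.normal(0, 2, 20))
            mine = deconvolve_pava(y, gamma).objective(y)
            assert mine <= qp_oracle(y, gamma) + 1e-6

    @given(st.floats(-0.5, 1.5))
    @settings(max_examples=20, deadline=None)
    def test_gamma_domain_enforced(self, g):
        y = np.ones(5)
        if 0.0 < g < 1.0:
            deconvolve_pava(y, g)
        else:
            with pytest.raises(ValueError):
                deconvolve_pava(y, g)

    def test_constraints_hold_on_long_noisy_trace(self, gamma):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 5000)
        d = deconvolve_pava(y, gamma)
        assert (d.inferred >= 0).all()
        assert (d.inferred[1:] - gamma * d.inferred[:-1] >= -1e-9).all()


class TestNormalize:
    def test_peak_maps_to_one_and_scale_invariance(self, gamma):
        y = np.zeros(30)
        y[10] = 7.0
        d = deconvolve_pava(y, gamma)
        n1 = normalize_trace(d)
        assert n1.max() == pytest.approx(1.0)
        d2 = deconvolve_pava(3.7 * y, gamma)
        assert normalize_trace(d2) == pytest.approx(n1)

    def test_all_zero_stays_zero(self, gamma):
        d = deconvolve_pava(np.zeros(10), gamma)
        assert not normalize_trace(d).any()


class TestBaselineNoise:
    def test_pure_gaussian_noise(self):
        biases, sds, fracs = [], [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t = np.arange(3000) / 30.0
            tr = FluorescenceTrace(frame_times=t, raw=rng.normal(0, 1, t.size))
            tr = estimate_baseline_noise(tr)
            biases.append(np.mean(tr.baseline))
            sds.append(tr.noise_sd)
            fracs.append(tr.active_mask.mean())
        assert abs(np.mean(biases)) < 0.2
        assert 0.85 < np.mean(sds) < 1.15
        assert np.mean(fracs) < 0.02

    def test_constant_trace_sigma_floor(self):
        t = np.arange(600) / 30.0
        tr = FluorescenceTrace(frame_times=t, raw=np.full(t.size, 4.2))
        tr = estimate_baseline_noise(tr)
        assert tr.baseline == pytest.approx(np.full(t.size, 4.2))
        assert 0 < tr.noise_sd < 1e-4

    def test_planted_transients_marked_active(self, gamma):
        rng = np.random.default_rng(1)
        t = np.arange(3000) / 30.0
        clean = np.zeros(t.size)
        events = [20.0, 50.0, 80.0]
        tau_r = synth.solve_tau_rise(0.112, 1.25)
        for te in events:
            clean += 10.0 * synth.calcium_kernel(t - te, tau_r, 1.25)
        tr = FluorescenceTrace(frame_times=t, raw=clean + rng.normal(0, 1, t.size))
        tr = estimate_baseline_noise(tr)
        assert abs(tr.noise_sd - 1.0) < 0.15
        for te in events:
            i = int(te * 30) + 2
            assert tr.active_mask[i]


class TestDetectEvents:
    def test_noise_only_rarely_fires(self, gamma):
        n_with_events = 0
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            t = np.arange(300) / 30.0
            tr = FluorescenceTrace(frame_times=t, raw=rng.normal(0, 1, 300))
            tr = estimate_baseline_noise(tr)
            d = deconvolve_pava(tr.corrected - tr.baseline, gamma)
            n_with_events += bool(detect_events(tr, d))
        assert n_with_events / 40 <= 0.05

    def test_single_planted_kernel(self, gamma):
        t = np.arange(600) / 30.0
        tau_r = synth.solve_tau_rise(0.112, 1.25)
        tr = FluorescenceTrace(
            frame_times=t, raw=10.0 * synth.calcium_kernel(t - 5.0, tau_r, 1.25)
        )
        tr.baseline = np.zeros(t.size)
        tr.noise_sd = 1.0
        d = deconvolve_pava(tr.corrected, gamma)
        events = detect_events(tr, d)
        assert len(events) == 1
        assert abs(events[0].onset_time - 5.0) <= 2 / 30.0
        assert abs(events[0].rise_time - 0.112) <= 1 / 30.0

    def test_close_pair_split_by_drive(self, gamma):
        t = np.arange(600) / 30.0
        tau_r = synth.solve_tau_rise(0.112, 1.25)
        raw = 10.0 * synth.calcium_kernel(t - 5.0, tau_r, 1.25)
        raw += 10.0 * synth.calcium_kernel(t - 5.5, tau_r, 1.25)
        tr = FluorescenceTrace(frame_times=t, raw=raw)
        tr.baseline = np.zeros(t.size)
        tr.noise_sd = 1.0
        events = detect_events(tr, deconvolve_pava(tr.corrected, gamma))
        assert len(events) == 2
        assert abs(events[1].onset_time - 5.5) <= 2 / 30.0

    def test_raising_threshold_never_adds_events(self, gamma, session, config):
        _, truth, _ = session
        neu = truth.neurons[10]
        tr = synth.gen_fluorescence(neu, truth, config, seed=5)
        tr = estimate_baseline_noise(tr)
        d = deconvolve_pava(tr.corrected - tr.baseline, gamma)
        counts = [len(detect_events(tr, d, k=k)) for k in (2.0, 3.0, 4.0, 6.0)]
        assert counts == sorted(counts, reverse=True)

    def test_requires_noise_estimate(self, gamma):
        tr = FluorescenceTrace(frame_times=np.arange(10) / 30, raw=np.zeros(10))
        with pytest.raises(ValueError, match="estimate_baseline_noise"):
            detect_events(tr, deconvolve_pava(np.zeros(10), 0.9))


class TestExtractRoiTraces:
    def test_uniform_movie_cancels(self):
        movie = np.full((5, 20, 20), 3.0)
        mask = np.zeros((20, 20), bool)
        mask[8:12, 8:12] = True
        (tr,) = extract_roi_traces(movie, [mask])
        assert tr.raw == pytest.approx(np.full(5, 3.0))
        assert tr.corrected == pytest.approx(np.zeros(5))

    def test_ring_background_subtraction(self):
        movie = np.full((3, 30, 30), 4.0)
        mask = np.zeros((30, 30), bool)
        mask[12:18, 12:18] = True
        movie[:, mask] = 10.0
        (tr,) = extract_roi_traces(movie, [mask])
        assert tr.corrected == pytest.approx(np.full(3, 6.0))

    def test_movie_round_trip_correlates_with_planted(self, config, session):
        _, truth, _ = session
        neurons = truth.neurons[:4]
        traces = [
            synth.gen_fluorescence(n, truth, config, seed=5, drift_amplitude=0.0)
            for n in neurons
        ]
        short = [
            FluorescenceTrace(frame_times=t.frame_times[:900], raw=t.raw[:900],
                              neuron_id=t.neuron_id)
            for t in traces
        ]
        movie, masks = synth.gen_movie(short, config, seed=5)
        extracted = extract_roi_traces(movie, masks)
        for planted, got in zip(short, extracted):
            r = np.corrcoef(planted.raw, got.corrected)[0, 1]
            assert r > 0.99
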