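"""Ground-truth generator and forward model."""

import numpy as np
import pytest

import cortune as c
from cortune.synth import (
    GroundTruthNeuron,
    calcium_kernel,
    quantize_threshold,
)


def make_neuron(**kwargs):
    base = dict(
        position_um=(100.0, 100.0),
        cf_khz=16.0,
        threshold_db=30.0,
        slope_db_per_octave=10.0,
        amplitude=1.0,
        response_type="onset",
        f0=100.0,
    )
    base.update(kwargs)
    return GroundTruthNeuron(**base)


class TestGenerateGroundTruth:
    def test_hearing_loss_preset_low_frequency_mass(self, tp_grid):
        pop = c.generate_ground_truth(500, "ahl_b6_2p5mo", tp_grid, seed=1)
        frac = np.mean(pop.cf_khz <= 16)
        assert frac == pytest.approx(0.86, abs=0.05)

    def test_protected_preset_high_frequency_thresholds(self, tp_grid):
        pop = c.generate_ground_truth(500, "ahl_plus_b6", tp_grid, seed=1)
        th64 = pop.thresholds_db[pop.cf_khz == 64]
        assert len(th64) > 50
        assert th64.mean() == pytest.approx(34, abs=5)
        th32 = pop.thresholds_db[pop.cf_khz == 32]
        assert th32.mean() == pytest.approx(32, abs=5)

    def test_empty_population(self, tp_grid):
        pop = c.generate_ground_truth(0, "uniform", tp_grid, seed=0)
        assert len(pop) == 0

    def test_unknown_preset_and_negative_n(self, tp_grid):
        with pytest.raises(ValueError, match="unknown preset"):
            c.generate_ground_truth(10, "nope", tp_grid, seed=0)
        with pytest.raises(ValueError):
            c.generate_ground_truth(-1, "uniform", tp_grid, seed=0)

    def test_deterministic_given_seed(self, tp_grid):
        a = c.generate_ground_truth(50, "uniform", tp_grid, seed=9)
        b = c.generate_ground_truth(50, "uniform", tp_grid, seed=9)
        assert a.to_records() == b.to_records()

    def test_tonotopic_axis_orders_cf_by_x(self, tp_grid):
        pop = c.generate_ground_truth(800, "uniform", tp_grid, seed=4)
        x = pop.positions_um[:, 0]
        cf = pop.cf_khz
        # mean x position increases with CF class along the axis
        means = [x[cf == f].mean() for f in (4, 8, 16, 32, 64)]
        assert np.all(np.diff(means) > 0)

    def test_threshold_quantization_grid(self, tp_grid):
        assert quantize_threshold(34, tp_grid.levels_db) == 30
        assert quantize_threshold(44, tp_grid.levels_db) == 50
        assert quantize_threshold(15, tp_grid.levels_db) == 10
        assert quantize_threshold(105, tp_grid.levels_db) == 110


class TestMeanResponse:
    def test_formula_arithmetic(self):
        n = make_neuron(cf_khz=16, threshold_db=30, slope_db_per_octave=10, amplitude=1.0)
        # theta(32) = 30 + 10*1 = 40; (50-40)/40 = 0.25
        assert c.mean_response(n, 32, 50) == pytest.approx(0.25)

    def test_boundary_exclusive(self):
        n = make_neuron()
        theta = n.threshold_db
        assert c.mean_response(n, n.cf_khz, theta) == 0.0

    def test_saturation(self):
        n = make_neuron(amplitude=0.8)
        assert c.mean_response(n, n.cf_khz, n.threshold_db + 40) == pytest.approx(0.8)
        assert c.mean_response(n, n.cf_khz, n.threshold_db + 60) == pytest.approx(0.8)

    def test_octave_symmetry(self):
        n = make_neuron(cf_khz=16)
        for d in (0.5, 1, 1.7):
            up = c.mean_response(n, 16 * 2**d, 90)
            down = c.mean_response(n, 16 * 2**-d, 90)
            assert up == pytest.approx(down)

    def test_nondecreasing_in_level_and_peaked_at_cf(self):
        n = make_neuron()
        resp = [c.mean_response(n, n.cf_khz, lv) for lv in range(0, 111, 5)]
        assert np.all(np.diff(resp) >= 0)
        at70 = [c.mean_response(n, f, 70) for f in (4, 8, 16, 32, 64)]
        assert np.argmax(at70) == 2  # cf = 16

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            c.mean_response(make_neuron(), 0.0, 70)


class TestSynthesizeSession:
    def test_noiseless_amplitude_matches_closed_form_kernel(self):
        # single-condition grid: no preceding trial, no bleed
        grid = c.build_stimulus_grid([8], [70], 1, 15.0, 75, 15)
        n = make_neuron(cf_khz=8, threshold_db=10, amplitude=0.6)
        pop = c.GroundTruthPopulation([n], "uniform", field_size_um=1000.0)
        noise = c.NoiseConfig(trace_sigma=0.0, drift_amplitude=0.0, neuropil_gain=0.0, seed=0)
        sess = c.synthesize_session(pop, grid, noise)
        dff = sess.roi_traces[0] / n.f0 - 1.0
        onset = grid.onset_frame
        recovered = dff[onset + 5 : onset + 10].mean()
        # independent closed form: double exponential, unit peak
        t = np.arange(75) / 15.0
        k = np.exp(-t / noise.decay_s) - np.exp(-t / noise.rise_s)
        k /= k.max()
        expected = c.mean_response(n, 8, 70) * k[5:10].mean()
        assert recovered == pytest.approx(expected, rel=1e-6)

    def test_same_seed_byte_identical(self, tp_grid):
        pop = c.generate_ground_truth(10, "uniform", tp_grid, seed=1)
        noise = c.NoiseConfig(seed=5)
        a = c.synthesize_session(pop, tp_grid, noise)
        b = c.synthesize_session(pop, tp_grid, noise)
        assert np.array_equal(a.roi_traces, b.roi_traces)
        assert np.array_equal(a.neuropil_traces, b.neuropil_traces)
        assert np.array_equal(a.log.onset_frames, b.log.onset_frames)
        assert np.array_equal(a.log.frequencies_khz, b.log.frequencies_khz)

    def test_noisy_condition_means_within_3se_of_clean(self, tp_grid):
        # noise only (drift and neuropil off): exact normalization recovers
        # the implanted per-condition amplitude within Monte-Carlo error
        pop = c.generate_ground_truth(40, "uniform", tp_grid, seed=8)
        noise = c.NoiseConfig(trace_sigma=2.0, drift_amplitude=0.0, neuropil_gain=0.0, seed=9)
        sess = c.synthesize_session(pop, tp_grid, noise)
        f0 = np.array([n.f0 for n in pop.neurons])[:, None]
        dff = sess.roi_traces / f0 - 1.0
        noisy = c.unmix_trials(dff, sess.log, tp_grid)
        clean = c.unmix_trials(sess.clean_dff, sess.log, tp_grid)
        on = tp_grid.onset_frame
        win = slice(on + 5, on + 10)
        err = noisy.values[:, win].mean(axis=1) - clean.values[:, win].mean(axis=1)
        mean_err = err.mean(axis=-1)
        se = err.std(axis=-1, ddof=1) / np.sqrt(tp_grid.n_repeats)
        ok = np.abs(mean_err) <= 3 * se
        assert ok.mean() > 0.97  # ~3-sigma coverage over 40 x 20 conditions

    def test_silent_population_has_no_stimulus_signal(self, tp_grid):
        pop = c.generate_ground_truth(20, "uniform", tp_grid, seed=3)
        silent = c.GroundTruthPopulation(
            [c.GroundTruthNeuron(
                position_um=n.position_um, cf_khz=n.cf_khz, threshold_db=n.threshold_db,
                slope_db_per_octave=n.slope_db_per_octave, amplitude=n.amplitude,
                response_type="silent", f0=n.f0,
            ) for n in pop.neurons],
            "uniform", pop.field_size_um,
        )
        sess = c.synthesize_session(silent, tp_grid, c.NoiseConfig(seed=4))
        assert np.all(sess.clean_dff == 0)

    def test_empty_population_returns_empty_traces(self, tp_grid):
        pop = c.GroundTruthPopulation([], "uniform", 1000.0)
        sess = c.synthesize_session(pop, tp_grid, c.NoiseConfig(seed=0))
        assert sess.roi_traces.shape[0] == 0
        assert len(sess.log) == tp_grid.n_trials


class TestSynthesizeWidefield:
    def test_single_neuron_peak_pixel_at_its_position(self, wf_grid):
        n = make_neuron(position_um=(700.0, 300.0), cf_khz=8, threshold_db=10)
        pop = c.GroundTruthPopulation([n], "uniform", 1000.0)
        noise = c.NoiseConfig(trace_sigma=0.0, drift_amplitude=0.0, seed=0)
        wf = c.synthesize_widefield(pop, wf_grid, 20, noise, global_sigma_dff=0.0)
        peak = wf.movie.max(axis=1)
        best = np.argmax(peak)
        assert np.hypot(*(wf.pixel_positions_um[best] - (700, 300))) < 60
        # determinism
        wf2 = c.synthesize_widefield(pop, wf_grid, 20, noise, global_sigma_dff=0.0)
        assert np.array_equal(wf.movie, wf2.movie)

    def test_near_total_loss_preset_silent_at_high_frequency(self, wf_grid):
        pop = c.generate_ground_truth(300, "ahl_b6_6mo", wf_grid, seed=6)
        noise = c.NoiseConfig(trace_sigma=0.0, drift_amplitude=0.0, seed=7)
        wf = c.synthesize_widefield(pop, wf_grid, 16, noise, global_sigma_dff=0.0)
        t = c.unmix_trials(wf.movie, wf.log, wf_grid)
        fi64 = wf_grid.freq_index(64)
        ai90 = wf_grid.level_index(90)
        on = wf_grid.onset_frame
        # 64 kHz sits >= 2 octaves from any preset CF with a sub-90 dB
        # threshold, so the tone window carries no implanted signal at all
        resp = t.values[:, on : on + 15, fi64, ai90]
        base = t.values[:, on - 15 : on, fi64, ai90]
        assert np.all(resp.mean(axis=1) - base.mean(axis=1) < 1e-6)

    def test_zero_size_pixel_grid_rejected(self, wf_grid):
        pop = c.generate_ground_truth(5, "uniform", wf_grid, seed=0)
        with pytest.raises(ValueError):
            c.synthesize_widefield(pop, wf_grid, 0, c.NoiseConfig(seed=0))


def test_calcium_kernel_unit_peak_and_shape():
    k = calcium_kernel(100, 15.0, 0.18, 1.5)
    assert k.max() == pytest.approx(1.0)
    assert k[0] == pytest.approx(0.0)
    peak = np.argmax(k)
    assert np.all(np.diff(k[peak:]) <= 1e-12)  # monotone decay after the peak
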