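"""Responsiveness classification and tuning metrics."""

import numpy as np
import pytest

import cortune as c
from cortune.grid import TrialTensor
from cortune.tuning import (
    PhaseAmplitudes,
    classify_neurons,
    omnibus_phase_pvalues,
    phase_amplitudes,
    population_summaries,
    significant_conditions,
    tuning_metrics,
)


def null_pa(grid, n, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    shape = (n, grid.n_frequencies, grid.n_levels, grid.n_repeats)
    return PhaseAmplitudes(
        baseline=rng.normal(0, scale, shape),
        onset=rng.normal(0, scale, shape),
        offset=rng.normal(0, scale, shape),
        grid=grid,
    )


class TestPhaseAmplitudes:
    def test_known_window_means(self, tp_grid):
        shape = (1, tp_grid.trial_frames, 5, 4, 10)
        v = np.zeros(shape)
        on = tp_grid.onset_frame
        off = on + tp_grid.tone_frames
        v[0, on - tp_grid.baseline_frames : on] = 0.1
        v[0, on + 5 : on + 10] = 0.7
        v[0, off + 5 : off + 10] += 0.2  # overlaps nothing: off+5 > on+9
        t = TrialTensor(v, tp_grid, is_dff=True)
        pa = phase_amplitudes(t)
        assert pa.baseline[0, 0, 0, 0] == pytest.approx(0.1)
        assert pa.onset[0, 0, 0, 0] == pytest.approx(0.7)
        assert pa.offset[0, 0, 0, 0] == pytest.approx(0.2)

    def test_zero_tensor(self, tp_grid):
        t = TrialTensor(np.zeros((2, 75, 5, 4, 10)), tp_grid, is_dff=True)
        pa = phase_amplitudes(t)
        assert not pa.baseline.any() and not pa.onset.any() and not pa.offset.any()

    def test_matches_brute_force_window_means(self, tp_grid):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((3, 75, 5, 4, 10))
        pa = phase_amplitudes(TrialTensor(v, tp_grid, is_dff=True))
        on, tone, b = tp_grid.onset_frame, tp_grid.tone_frames, tp_grid.baseline_frames
        np.testing.assert_allclose(pa.baseline, v[:, on - b : on].mean(axis=1))
        np.testing.assert_allclose(pa.onset, v[:, on + 5 : on + 10].mean(axis=1))
        np.testing.assert_allclose(
            pa.offset, v[:, on + tone + 5 : on + tone + 10].mean(axis=1)
        )


class TestOmnibus:
    def test_matches_statsmodels_type2_anova(self, tp_grid):
        import pandas as pd
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        pa = null_pa(tp_grid, 4, seed=2)
        pa.onset[1] += 0.3  # one clearly responsive neuron
        mine = omnibus_phase_pvalues(pa)

        F, A, R = 5, 4, 10
        phase = np.repeat(np.arange(3), F * A * R)
        freq = np.tile(np.repeat(np.arange(F), A * R), 3)
        lev = np.tile(np.repeat(np.arange(A), R), 3 * F)
        for i in range(4):
            y = np.concatenate(
                [pa.baseline[i].ravel(), pa.onset[i].ravel(), pa.offset[i].ravel()]
            )
            df = pd.DataFrame(dict(y=y, phase=phase, freq=freq, lev=lev))
            fit = smf.ols(
                "y ~ C(phase) + C(freq) + C(lev) + C(freq):C(lev):C(phase)", df
            ).fit()
            ref = anova_lm(fit, typ=2).loc["C(phase)", "PR(>F)"]
            assert mine[i] == pytest.approx(ref, rel=1e-8)

    def test_null_rate_near_alpha(self, tp_grid):
        pa = null_pa(tp_grid, 10000, seed=3)
        rate = np.mean(omnibus_phase_pvalues(pa) < 0.01)
        assert rate == pytest.approx(0.01, abs=0.004)

    def test_null_pvalues_uniform(self, tp_grid):
        from scipy import stats

        pa = null_pa(tp_grid, 5000, seed=13)
        ks = stats.kstest(omnibus_phase_pvalues(pa), "uniform")
        assert ks.pvalue > 0.01


class TestClassifyNeurons:
    def _pa_with_effects(self, grid, onset_eff, offset_eff, seed=0, n=1):
        pa = null_pa(grid, n, seed=seed, scale=0.05)
        pa.onset += onset_eff
        pa.offset += offset_eff
        return pa

    def test_onset_neuron(self, tp_grid):
        pa = self._pa_with_effects(tp_grid, onset_eff=0.5, offset_eff=0.15, seed=4)
        # offset amplitude below onset (decay), well above baseline
        assert classify_neurons(pa)[0] == "onset"

    def test_offset_neuron(self, tp_grid):
        pa = self._pa_with_effects(tp_grid, onset_eff=0.0, offset_eff=0.5, seed=5)
        assert classify_neurons(pa)[0] == "offset"

    def test_onset_offset_neuron(self, tp_grid):
        pa = self._pa_with_effects(tp_grid, onset_eff=0.4, offset_eff=0.9, seed=6)
        assert classify_neurons(pa)[0] == "onset_offset"

    def test_null_neurons_rarely_flagged(self, tp_grid):
        pa = null_pa(tp_grid, 2000, seed=7)
        frac = np.mean(classify_neurons(pa) != "none")
        assert frac <= 0.015  # at or just below the 1% omnibus level


class TestSignificantConditions:
    def test_identical_onset_and_baseline_empty_mask(self, tp_grid):
        rng = np.random.default_rng(8)
        shape = (1, 5, 4, 10)
        base = rng.standard_normal(shape)
        pa = PhaseAmplitudes(base, base.copy(), rng.standard_normal(shape), tp_grid)
        assert not significant_conditions(pa).any()

    def test_single_implanted_condition_flagged(self, tp_grid):
        pa = null_pa(tp_grid, 1, seed=9, scale=0.05)
        pa.onset[0, 2, 3] += 1.0  # (16 kHz, 90 dB)
        mask = significant_conditions(pa)[0]
        assert mask[2, 3]
        # FDR 0.2 tolerates occasional false discoveries alongside the hit
        assert mask.sum() <= 2

    def test_bh_is_applied_per_neuron_across_conditions(self, tp_grid):
        from cortune.stats import benjamini_hochberg, paired_ttest_pvalues

        pa = null_pa(tp_grid, 3, seed=10, scale=0.3)
        pa.onset[:, :2] += 0.4
        mask = significant_conditions(pa, q=0.2)
        p = paired_ttest_pvalues(pa.onset, pa.baseline, axis=-1, alternative="greater")
        diff = (pa.onset - pa.baseline).mean(axis=-1)
        for i in range(3):
            reject, _ = benjamini_hochberg(np.nan_to_num(p[i].ravel(), nan=1.0), 0.2)
            oracle = reject.reshape(5, 4) & (diff[i] > 0)
            np.testing.assert_array_equal(mask[i], oracle)


class TestTuningMetrics:
    def _mask(self, grid, true_freqs, level_db=70.0):
        mask = np.zeros((5, 4), dtype=bool)
        ai = grid.level_index(level_db)
        for f in true_freqs:
            mask[grid.freq_index(f), ai] = True
        return mask

    def test_bandwidth_two_octaves(self, tp_grid):
        mask = self._mask(tp_grid, [8, 16, 32])
        res = tuning_metrics(np.ones((5, 4)), mask, tp_grid)
        assert res.bandwidth_octaves == pytest.approx(2.0)  # log2(32/8)

    def test_single_frequency_bandwidth_zero(self, tp_grid):
        res = tuning_metrics(np.ones((5, 4)), self._mask(tp_grid, [16]), tp_grid)
        assert res.bandwidth_octaves == 0.0
        assert not res.bandwidth_excluded

    def test_noncontiguous_response_excluded(self, tp_grid):
        res = tuning_metrics(np.ones((5, 4)), self._mask(tp_grid, [4, 16]), tp_grid)
        assert res.bandwidth_excluded
        assert res.bandwidth_octaves is None

    def test_best_frequency_over_all_levels(self, tp_grid):
        amps = np.zeros((5, 4))
        mask = np.zeros((5, 4), dtype=bool)
        amps[4, 3] = 0.9  # (64 kHz, 90 dB) global max
        amps[2, 1] = 0.5
        mask[4, 3] = mask[2, 1] = True
        res = tuning_metrics(amps, mask, tp_grid)
        assert res.best_frequency_khz == 64.0

    def test_characteristic_frequency_at_lowest_significant_level(self, tp_grid):
        amps = np.zeros((5, 4))
        mask = np.zeros((5, 4), dtype=bool)
        ai50 = tp_grid.level_index(50)
        amps[1, ai50], amps[2, ai50] = 0.3, 0.5  # 0.3@8, 0.5@16 at 50 dB
        mask[1, ai50] = mask[2, ai50] = True
        amps[2, 3] = 0.9
        mask[2, 3] = True
        res = tuning_metrics(amps, mask, tp_grid)
        assert res.characteristic_frequency_khz == 16.0

    def test_cf_amplitude_tie_breaks_to_lower_frequency(self, tp_grid):
        amps = np.zeros((5, 4))
        mask = np.zeros((5, 4), dtype=bool)
        amps[1, 0] = amps[3, 0] = 0.4
        mask[1, 0] = mask[3, 0] = True
        res = tuning_metrics(amps, mask, tp_grid)
        assert res.characteristic_frequency_khz == 8.0

    def test_empty_mask_yields_explicit_nulls(self, tp_grid):
        res = tuning_metrics(np.ones((5, 4)), np.zeros((5, 4), bool), tp_grid)
        assert res.best_frequency_khz is None
        assert res.characteristic_frequency_khz is None
        assert res.bandwidth_octaves is None

    def test_bf_equals_cf_when_max_at_lowest_significant_level(self, tp_grid):
        rng = np.random.default_rng(11)
        for _ in range(50):
            amps = rng.uniform(0, 1, (5, 4))
            mask = rng.uniform(size=(5, 4)) < 0.4
            if not mask.any():
                continue
            res = tuning_metrics(amps, mask, tp_grid)
            lowest = int(np.argmax(mask.any(axis=0)))
            masked = np.where(mask, amps, -np.inf)
            if np.unravel_index(np.argmax(masked), masked.shape)[1] == lowest:
                assert res.best_frequency_khz == res.characteristic_frequency_khz


class TestPopulationSummaries:
    def test_counting(self):
        out = population_summaries(["onset", "offset", "onset_offset", "none"])
        assert out["responsive_fraction"] == 0.75
        assert out["offset_fraction"] == 0.5

    def test_all_none(self):
        out = population_summaries(["none"] * 5)
        assert out == {"responsive_fraction": 0.0, "offset_fraction": 0.0}

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(12)
        labels = rng.choice(["none", "onset", "offset", "onset_offset"], size=200)
        out = population_summaries(labels)
        resp = sum(l != "none" for l in labels) / 200
        off = sum(l in ("offset", "onset_offset") for l in labels) / 200
        assert out["responsive_fraction"] == pytest.approx(resp)
        assert out["offset_fraction"] == pytest.approx(off)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            population_summaries([])


class TestRecovery:
    def test_cf_recovery_on_low_noise_session(self, low_noise_session):
        import pandas as pd

        s = low_noise_session
        tab = c.analyze_tuning(s["tensor"], s["population"].positions_um)
        truth = pd.DataFrame(s["population"].to_records())
        m = tab.join(truth, rsuffix="_true")
        sel = m[m.response_class.isin(["onset", "onset_offset"]) & m.cf_khz.notna()]
        assert len(sel) > 50
        assert (sel.cf_khz == sel.cf_khz_true).mean() >= 0.9

    def test_implanted_response_types_recovered(self, low_noise_session):
        import pandas as pd

        s = low_noise_session
        tab = c.analyze_tuning(s["tensor"], s["population"].positions_um)
        truth = pd.DataFrame(s["population"].to_records())
        m = tab.join(truth, rsuffix="_true")
        # responsive onset-type neurons with audible thresholds are detected
        audible = m[(m.response_type == "onset") & (m.threshold_db < 90)]
        assert (audible.response_class != "none").mean() >= 0.9
        silent = m[m.response_type == "silent"]
        assert (silent.response_class == "none").mean() >= 0.95
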