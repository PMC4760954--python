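"""Template regression decomposition and PD/NPD value-effect regressions."""

import numpy as np
import pytest

import seqsel
from seqsel.datatypes import Target, TrialRecord
from seqsel.regression_decomp import (
    DecompCoefs,
    build_templates,
    decomposition_onset,
    fit_decomposition,
    grid_windows,
    presaccadic_normalized_activity,
    value_effect_regression,
)
from seqsel.synth import (
    BehaviorParams,
    GroundTruthNeuron,
    LatencyPlan,
    make_block_schedule,
    make_gamble_set,
    rate_timecourse,
    simulate_choices_rts,
    simulate_spikes,
)


class TestFitDecomposition:
    def _templates(self, rng, n_cond=4, n_steps=6):
        return rng.uniform(5, 30, size=(n_cond, n_steps)), np.arange(n_steps, dtype=float)

    def test_exact_linear_combination_machine_precision(self, rng):
        templates, times = self._templates(rng)
        ci = rng.integers(0, 4, 40)
        ni = (ci + 1 + rng.integers(0, 3, 40)) % 4
        y = 0.7 * templates[ci] + 0.3 * templates[ni]
        coefs = fit_decomposition(y, ci, ni, templates, times)
        np.testing.assert_allclose(coefs.b1, 0.7, atol=1e-10)
        np.testing.assert_allclose(coefs.b2, 0.3, atol=1e-10)

    def test_noisy_recovery_within_tolerance(self, rng):
        templates, times = self._templates(rng)
        ci = rng.integers(0, 4, 400)
        ni = (ci + 1 + rng.integers(0, 3, 400)) % 4
        y = 0.7 * templates[ci] + 0.3 * templates[ni] + rng.normal(0, 0.3, (400, 6))
        coefs = fit_decomposition(y, ci, ni, templates, times)
        assert np.max(np.abs(coefs.b1 - 0.7)) < 0.05
        assert np.max(np.abs(coefs.b2 - 0.3)) < 0.05

    def test_identical_templates_masked(self, rng):
        templates, times = self._templates(rng)
        ci = rng.integers(0, 4, 40)
        y = templates[ci].copy()
        coefs = fit_decomposition(y, ci, ci.copy(), templates, times)
        assert np.all(coefs.masked)

    def test_swap_equivariance(self, rng):
        templates, times = self._templates(rng)
        ci = rng.integers(0, 4, 80)
        ni = (ci + 2) % 4
        y = 0.9 * templates[ci] + 0.1 * templates[ni] + rng.normal(0, 0.2, (80, 6))
        a = fit_decomposition(y, ci, ni, templates, times)
        b = fit_decomposition(y, ni, ci, templates, times)
        np.testing.assert_allclose(a.b1, b.b2, atol=1e-10)
        np.testing.assert_allclose(a.b2, b.b1, atol=1e-10)

    def test_too_few_trials_rejected(self, rng):
        templates, times = self._templates(rng)
        with pytest.raises(ValueError, match=">= 10"):
            fit_decomposition(np.zeros((5, 6)), np.zeros(5, int), np.ones(5, int),
                              templates, times)


class TestTemplates:
    def _constant_unit_session(self):
        trials, spikes = [], {}
        tid = 1
        for rep in range(6):
            for d in (45.0, 135.0, 225.0, 315.0):
                for g in range(1, 8):
                    t0 = 4000.0 * tid
                    trials.append(TrialRecord(
                        trial_id=tid, block_id=1, trial_type="no_choice",
                        targets=(Target(d, g),), chosen_index=0, t_fix_on=t0,
                        t_target_on=t0 + 700.0, t_saccade_on=t0 + 950.0,
                        t_outcome=t0 + 1500.0, t_reward=t0 + 1800.0,
                        reward_delivered=1.0,
                    ))
                    # metronomic 1 ms spikes: exactly 20 per 20 ms window
                    spikes[tid] = np.arange(t0 + 600.0, t0 + 1100.0, 1.0) + 0.5
                    tid += 1
        return seqsel.NeuronData(1, spikes), trials

    def test_constant_rate_unit_gives_flat_templates(self):
        n, trials = self._constant_unit_session()
        psi = np.linspace(0, 1, 7)
        bank = build_templates(n, trials, psi)
        np.testing.assert_allclose(bank.dir_templates, 1000.0)
        np.testing.assert_allclose(bank.val_templates, 1000.0)

    def test_templates_deterministic(self, tiny_session):
        n = tiny_session["neurons"][0]
        psi = tiny_session["bp"].psi
        a = build_templates(n, tiny_session["trials"], psi)
        b = build_templates(n, tiny_session["trials"], psi)
        np.testing.assert_array_equal(a.dir_templates, b.dir_templates)
        np.testing.assert_array_equal(a.val_templates, b.val_templates)

    def test_missing_direction_rejected(self, tiny_session):
        psi = tiny_session["bp"].psi
        trials = [
            t for t in tiny_session["trials"]
            if not (t.trial_type == "no_choice" and t.targets[0].direction == 45.0)
        ]
        with pytest.raises(ValueError, match="45"):
            build_templates(tiny_session["neurons"][0], trials, psi)

    def test_templates_match_generator_rates(self):
        # template means track the noise-free generator rate within
        # Poisson standard error at 100 trials per condition
        gambles = make_gamble_set()
        bp = BehaviorParams()
        lp = LatencyPlan()
        unit = seqsel.sample_population(1, 2)[0]
        trials = []
        tid = 1
        rng = np.random.default_rng(0)
        for rep in range(100):
            for d in (45.0, 225.0):
                t0 = 4000.0 * tid
                trials.append(TrialRecord(
                    trial_id=tid, block_id=1, trial_type="no_choice",
                    targets=(Target(d, 4),), chosen_index=0, t_fix_on=t0,
                    t_target_on=t0 + 700.0, t_saccade_on=t0 + 950.0,
                    t_outcome=t0 + 1500.0, t_reward=t0 + 1800.0,
                    reward_delivered=1.0,
                ))
                tid += 1
        neurons = simulate_spikes(trials, [unit], bp, lp, 0)
        starts, centers = grid_windows()
        for d in (45.0, 225.0):
            sub = [t for t in trials if t.targets[0].direction == d]
            from seqsel.rates import window_mean_rates

            rates = np.stack([
                window_mean_rates(neurons[0], sub, "saccade_on", (lo, lo + 20.0))
                for lo in starts
            ], axis=1).mean(axis=0)
            t, r = rate_timecourse(unit, sub[0], bp, lp)
            rel = t - sub[0].t_saccade_on
            expected = np.array([r[(rel >= lo) & (rel < lo + 20.0)].mean() for lo in starts])
            se = np.sqrt(np.maximum(expected, 1.0) / 0.02) / np.sqrt(len(sub))
            assert np.all(np.abs(rates - expected) < 4.5 * se + 1e-9)


class TestOnset:
    def _coefs(self, b1, b2, times):
        return DecompCoefs(times=times, b1=b1, b2=b2,
                           masked=np.zeros(times.size, bool))

    def test_onset_detects_planted_divergence(self, rng):
        times = np.arange(-200.0, 10.0, 10.0)
        coefs = []
        for _ in range(30):
            b1 = rng.normal(0.5, 0.05, times.size)
            b2 = rng.normal(0.5, 0.05, times.size)
            b1[times >= -100.0] += 0.3
            coefs.append(self._coefs(b1, b2, times))
        onset = decomposition_onset(coefs)
        assert onset is not None and -110.0 <= onset <= -80.0

    def test_no_divergence_no_onset(self, rng):
        times = np.arange(-200.0, 10.0, 10.0)
        coefs = [
            self._coefs(rng.normal(0.5, 0.05, times.size),
                        rng.normal(0.5, 0.05, times.size), times)
            for _ in range(20)
        ]
        assert decomposition_onset(coefs) is None


class TestValueEffect:
    def test_value_blind_units_give_null_slopes(self):
        # units with direction tuning but no value terms
        hits = 0
        runs = 6
        for seed in range(runs):
            rng = np.random.default_rng(100 + seed)
            units = []
            for i in range(12):
                pd = (45.0, 135.0, 225.0, 315.0)[i % 4] + rng.uniform(-10, 10)
                units.append(GroundTruthNeuron(
                    b0=rng.uniform(8, 15), b1=0.0, b2=rng.uniform(20, 30), b3=0.0,
                    s=0.8, t=0.5, w=2.0, p=np.radians(pd % 360),
                    beta_pd=0.0, beta_npd=0.0, vis_amp=rng.uniform(4, 8),
                    model_class="g",
                ))
            s = seqsel.make_session(n_blocks=10, n_units=12, seed=seed, units=units)
            norm = presaccadic_normalized_activity(s["neurons"], s["trials"])
            pds = np.array([u.snapped_pd_deg for u in units])
            fit = value_effect_regression(
                norm, pds, s["trials"], s["bp"].psi, "no_choice_PD"
            )
            hits += fit.p_value > 0.05
        assert hits >= 0.5 * runs  # slope indistinguishable from zero mostly

    def test_flat_npd_no_choice_pattern(self, default_session):
        s = default_session
        pds = np.array([u.snapped_pd_deg for u in s["units"]])
        norm = presaccadic_normalized_activity(s["neurons"], s["trials"])
        pd_fit = value_effect_regression(norm, pds, s["trials"], s["bp"].psi, "no_choice_PD")
        npd_fit = value_effect_regression(norm, pds, s["trials"], s["bp"].psi, "no_choice_NPD")
        assert pd_fit.slope > 0 and pd_fit.p_value < 0.01
        assert abs(npd_fit.slope) < 0.15 * pd_fit.slope

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError, match="mode"):
            value_effect_regression(np.zeros((2, 2)), np.array([45.0, 45.0]), [],
                                    np.linspace(0, 1, 7), "bogus")
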