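"""Ground-truth generator: task design, behavior model, spiking."""

import numpy as np
import pytest
from scipy import stats

import seqsel
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


class TestGambleSet:
    def test_seven_distinct_options(self):
        g = make_gamble_set()
        assert len(g) == 7
        assert len({x.id for x in g}) == 7

    def test_contains_9_unit_20pct_gamble_with_ev_2_6(self):
        g = {(x.max_reward, x.p_max): x for x in make_gamble_set()}
        assert (9.0, 0.2) in g
        assert np.isclose(g[(9.0, 0.2)].expected_value, 2.6)

    def test_min_reward_always_one_unit(self):
        assert all(x.min_reward == 1.0 for x in make_gamble_set())

    def test_default_psi_monotone_with_seven_levels(self):
        psi = seqsel.default_subjective_values()
        assert np.all(np.diff(psi) > 0)
        assert psi[0] == 0.0 and psi[-1] == 1.0


class TestBlockSchedule:
    def test_block_composition(self):
        trials = make_block_schedule(0)
        assert len(trials) == 28
        assert sum(t.trial_type == "choice" for t in trials) == 21
        assert sum(t.trial_type == "no_choice" for t in trials) == 7

    def test_all_pairs_and_singles_covered(self):
        trials = make_block_schedule(1)
        pairs = {
            frozenset(tg.gamble_id for tg in t.targets)
            for t in trials
            if t.trial_type == "choice"
        }
        singles = {t.targets[0].gamble_id for t in trials if t.trial_type == "no_choice"}
        assert len(pairs) == 21
        assert singles == set(range(1, 8))

    def test_same_seed_same_schedule(self):
        a = make_block_schedule(42)
        b = make_block_schedule(42)
        assert a == b


class TestChoicesAndRTs:
    def test_noiseless_limit_picks_higher_value(self):
        g = make_gamble_set()
        bp = BehaviorParams(sigma_d=1e-9)
        trials = simulate_choices_rts(make_block_schedule(0), g, bp, 0)
        for t in trials:
            if t.trial_type == "choice":
                psis = [bp.psi_of(tg.gamble_id) for tg in t.targets]
                assert t.chosen_index == int(np.argmax(psis))

    def test_equal_values_split_fifty_fifty(self):
        g = make_gamble_set()
        psi = np.full(7, 0.5)
        bp = BehaviorParams(psi=psi, sigma_d=0.15)
        sched = []
        for b in range(96):
            sched.extend(make_block_schedule(b, block_id=b + 1, trial_id_start=28 * b + 1))
        trials = simulate_choices_rts(sched, g, bp, 1)
        picks = [t.chosen_index for t in trials if t.trial_type == "choice"]
        frac = np.mean(picks)
        n = len(picks)  # 2016 choice trials
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_choice_curve_matches_probit_oracle(self):
        # P(choose first) = Phi(dpsi / (sigma_d * sqrt(2))) for per-option noise
        sigma = 0.15
        rng = np.random.default_rng(5)
        for dpsi in (0.1, 0.3):
            n = 4000
            noisy0 = dpsi + rng.normal(0, sigma, n)
            noisy1 = rng.normal(0, sigma, n)
            frac = np.mean(noisy0 > noisy1)
            pred = stats.norm.cdf(dpsi / (sigma * np.sqrt(2)))
            assert abs(frac - pred) < 3 * np.sqrt(pred * (1 - pred) / n)

    def test_rt_decreases_with_value_drive(self):
        g = make_gamble_set()
        bp = BehaviorParams(rt_noise_sd=1e-6)
        trials = simulate_choices_rts(make_block_schedule(0), g, bp, 0)
        nc = [(bp.psi_of(t.targets[0].gamble_id), t.rt) for t in trials
              if t.trial_type == "no_choice"]
        nc.sort()
        rts = [rt for _, rt in nc]
        assert rts[0] > rts[-1]


def _homog_unit(b0=20.0):
    return GroundTruthNeuron(
        b0=b0, b1=0.0, b2=0.0, b3=0.0, s=0.5, t=0.5, w=2.0, p=0.0,
        beta_pd=0.0, beta_npd=0.0, vis_amp=0.0, model_class="const",
    )


class TestSpiking:
    def test_degenerate_model_is_homogeneous_poisson(self):
        g = make_gamble_set()
        bp = BehaviorParams()
        trials = simulate_choices_rts(make_block_schedule(0), g, bp, 0)
        # high rate so the trial window is >> the mean ISI and boundary
        # truncation of long intervals is negligible at this sample size
        neurons = simulate_spikes(trials, [_homog_unit(b0=100.0)], bp, LatencyPlan(), 0)
        isis = np.concatenate(
            [np.diff(v) for v in neurons[0].spike_times.values() if v.size > 1]
        )
        isis = np.random.default_rng(0).choice(isis, size=1500, replace=False)
        ks = stats.kstest(isis, "expon", args=(0, 1000.0 / 100.0))
        assert ks.pvalue > 0.01

    def test_rate_linearity_in_weights(self):
        g = make_gamble_set()
        bp = BehaviorParams()
        trials = simulate_choices_rts(make_block_schedule(0), g, bp, 0)
        u = GroundTruthNeuron(
            b0=10.0, b1=30.0, b2=12.0, b3=5.0, s=0.8, t=0.5, w=2.0,
            p=np.radians(45.0), beta_pd=10.0, beta_npd=-5.0, vis_amp=6.0,
            model_class="fgh",
        )
        u2 = GroundTruthNeuron(
            b0=10.0, b1=60.0, b2=24.0, b3=10.0, s=0.8, t=0.5, w=2.0,
            p=np.radians(45.0), beta_pd=20.0, beta_npd=-10.0, vis_amp=12.0,
            model_class="fgh",
        )
        for tr in trials[:5]:
            _, r1 = rate_timecourse(u, tr, bp, LatencyPlan())
            _, r2 = rate_timecourse(u2, tr, bp, LatencyPlan())
            np.testing.assert_allclose(r2 - 10.0, 2.0 * (r1 - 10.0), atol=1e-9)

    def test_condition_rates_diverge_only_after_direction_latency(self):
        # noise-free generator traces: PD-chosen vs NPD-chosen diagonal
        # trials differ no earlier than saccade - L_dir
        g = make_gamble_set()
        bp = BehaviorParams()
        lp = LatencyPlan()
        u = seqsel.sample_population(1, 0)[0]
        from seqsel.datatypes import Target, TrialRecord

        def diag_trial(chosen_dir, tid):
            other = (chosen_dir + 180.0) % 360.0
            return TrialRecord(
                trial_id=tid, block_id=1, trial_type="choice",
                targets=(Target(chosen_dir, 4), Target(other, 4)),
                chosen_index=0, t_fix_on=0.0, t_target_on=700.0,
                t_saccade_on=950.0, t_outcome=1500.0, t_reward=1800.0,
                reward_delivered=1.0,
            )

        pd = u.snapped_pd_deg
        t1, r_pd = rate_timecourse(u, diag_trial(pd, 1), bp, lp)
        t2, r_npd = rate_timecourse(u, diag_trial((pd + 180) % 360, 2), bp, lp)
        rel = t1 - 950.0  # ms re saccade
        diff = np.abs(r_pd - r_npd)
        assert np.all(diff[rel < -lp.L_dir - 1] < 1e-9)
        assert diff[np.argmin(np.abs(rel - (-lp.L_dir + lp.rise_tau)))] > 1.0

    def test_value_flat_for_npd_only_no_choice_trials(self):
        g = make_gamble_set()
        bp = BehaviorParams()
        lp = LatencyPlan()
        u = seqsel.sample_population(1, 0)[0]
        from seqsel.datatypes import Target, TrialRecord

        npd = (u.snapped_pd_deg + 180.0) % 360.0
        rates = []
        for gid in (1, 7):
            tr = TrialRecord(
                trial_id=gid, block_id=1, trial_type="no_choice",
                targets=(Target(npd, gid),), chosen_index=0, t_fix_on=0.0,
                t_target_on=700.0, t_saccade_on=950.0, t_outcome=1500.0,
                t_reward=1800.0, reward_delivered=1.0,
            )
            t, r = rate_timecourse(u, tr, bp, lp)
            rates.append(r[np.argmin(np.abs((t - 950.0) - (-10.0)))])
        # value modulation at most the tiny leak through the circular tail
        assert abs(rates[1] - rates[0]) < 0.1 * u.b1 * (u.fval(1.0) - u.fval(0.0))

    def test_spike_counts_match_rate_traces(self):
        g = make_gamble_set()
        bp = BehaviorParams()
        lp = LatencyPlan()
        u = seqsel.sample_population(1, 3)[0]
        sched = []
        for b in range(4):
            sched.extend(make_block_schedule(b, block_id=b + 1, trial_id_start=28 * b + 1))
        trials = simulate_choices_rts(sched, g, bp, 7)
        neurons = simulate_spikes(trials, [u], bp, lp, 9)
        # chi-square on per-trial totals vs the integral of the rate trace
        obs, exp = [], []
        for tr in trials:
            _, r = rate_timecourse(u, tr, bp, lp)
            obs.append(neurons[0].spike_times[tr.trial_id].size)
            exp.append(r.sum() * 1e-3)
        obs, exp = np.array(obs, float), np.array(exp)
        chi2 = np.sum((obs - exp) ** 2 / exp)
        # dof = n trials; generous bound
        assert chi2 < stats.chi2.ppf(0.999, len(obs))

    def test_reproducible_with_same_seed(self):
        a = seqsel.make_session(n_blocks=1, n_units=2, seed=5)
        b = seqsel.make_session(n_blocks=1, n_units=2, seed=5)
        assert a["trials"] == b["trials"]
        for na, nb in zip(a["neurons"], b["neurons"]):
            for tid in na.spike_times:
                np.testing.assert_array_equal(na.spike_times[tid], nb.spike_times[tid])

    def test_latency_plan_requires_value_before_action(self):
        with pytest.raises(ValueError, match="L_value > L_dir"):
            LatencyPlan(L_value=50.0, L_dir=60.0)
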