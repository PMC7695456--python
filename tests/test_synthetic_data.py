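import dataclasses

import numpy as np
import pytest

from optodetect.behavior import CATCH, score_trials
from optodetect.psychometrics import psychometric
from optodetect.synthetic_data import (
    PsychTruth,
    SimConfig,
    generate_behavior,
    generate_trial_sequence,
    plant_target_activations,
    simulate_session,
)
from optodetect.thresholds import ACTIVATED
from optodetect.traces import (
    artefact_exclusion_mask,
    extract_trial_responses,
    session_neuropil_coefficients,
)


def _max_run_length(types):
    best = run = 1
    for a, b in zip(types, types[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


class TestConfigValidation:
    def test_ratios_must_sum_to_one(self):
        cfg = SimConfig(trial_type_set=(0, 5), trial_ratios=(0.5, 0.4))
        with pytest.raises(ValueError, match="sum to 1"):
            cfg.validate()

    def test_probabilities_bounded(self):
        cfg = SimConfig(p_target_activation=1.2)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_neuropil_coeff_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(neuropil_coeff_true=0.2).validate()

    def test_psych_truth_validated(self):
        with pytest.raises(ValueError):
            SimConfig(psych_truth=PsychTruth(1.0, -1.0, 0.0, 0.0)).validate()


class TestTrialSequence:
    def test_exact_counts_largest_remainder(self, small_config):
        seq = generate_trial_sequence(small_config, seed=0)
        types = [t for t, _ in seq]
        assert len(types) == small_config.n_trials
        counts = {tt: types.count(tt) for tt in small_config.trial_type_set}
        exact = {
            tt: r * small_config.n_trials
            for tt, r in zip(small_config.trial_type_set, small_config.trial_ratios)
        }
        for tt in counts:
            assert abs(counts[tt] - exact[tt]) < 1.0  # largest-remainder rounding

    def test_warmup_block(self, small_config):
        seq = generate_trial_sequence(small_config, seed=1)
        head = [t for t, _ in seq[: small_config.warmup_trials]]
        assert head == [small_config.easiest_type] * small_config.warmup_trials

    def test_run_length_constraint(self, small_config):
        seq = generate_trial_sequence(small_config, seed=2)
        types = [t for t, _ in seq[small_config.warmup_trials :]]
        assert _max_run_length(types) <= small_config.max_run_length

    def test_no_run_extends_warmup(self, small_config):
        for seed in range(5):
            seq = generate_trial_sequence(small_config, seed=seed)
            types = [t for t, _ in seq]
            w = small_config.warmup_trials
            assert types[w] != small_config.easiest_type  # warm-up run cannot continue

    def test_determinism(self, small_config):
        a = generate_trial_sequence(small_config, seed=7)
        b = generate_trial_sequence(small_config, seed=7)
        assert a == b

    def test_single_type_infeasible(self):
        cfg = SimConfig(
            trial_type_set=(5,), trial_ratios=(1.0,), n_trials=24, warmup_trials=0
        )
        with pytest.raises(ValueError, match="run-length"):
            generate_trial_sequence(cfg, seed=0)

    def test_too_few_trials_rejected(self):
        cfg = SimConfig(trial_type_set=(5,), trial_ratios=(1.0,), n_trials=4, warmup_trials=0)
        with pytest.raises(ValueError):
            generate_trial_sequence(cfg, seed=0)

    def test_onset_gaps_within_jitter(self, small_config):
        seq = generate_trial_sequence(small_config, seed=3)
        gaps = np.diff([o for _, o in seq])
        lo = small_config.iti_mean_s - small_config.iti_jitter_s
        hi = small_config.iti_mean_s + small_config.iti_jitter_s
        assert np.all(gaps >= lo) and np.all(gaps <= hi)


class TestBehaviorGeneration:
    def _sequence(self, trial_type, n, start=10.0, gap=10.0):
        return [(trial_type, start + i * gap) for i in range(n)]

    def test_saturated_curve_licks_always(self):
        truth = PsychTruth(m=np.log(5.0), w=1.0, lam=0.0, gamma=0.0)
        seq = self._sequence(50, 400)
        recs = generate_behavior(seq, truth, seed=0, x_true=np.full(400, 1e6))
        rate = np.mean([r.lick_times_s.size > 0 for r in recs])
        assert rate > 0.99

    def test_catch_rate_is_guess_rate(self):
        truth = PsychTruth(m=np.log(21.0), w=1.35, lam=0.05, gamma=0.15)
        seq = self._sequence(CATCH, 2000)
        recs = generate_behavior(seq, truth, seed=1, x_true=np.zeros(2000))
        rate = np.mean([r.lick_times_s.size > 0 for r in recs])
        se = np.sqrt(0.15 * 0.85 / 2000)
        assert abs(rate - 0.15) < 4 * se

    def test_monte_carlo_matches_psi(self):
        # empirical lick rates vs the psi evaluator, 2000 trials per level
        truth = PsychTruth(m=np.log(21.0), w=1.35, lam=0.05, gamma=0.1)
        for x in (5.0, 21.0, 60.0):
            seq = self._sequence(100, 2000)
            recs = generate_behavior(seq, truth, seed=int(x), x_true=np.full(2000, x))
            rate = np.mean([r.lick_times_s.size > 0 for r in recs])
            p = psychometric(x, truth.m, truth.w, truth.lam, truth.gamma)
            se = np.sqrt(p * (1 - p) / 2000)
            assert abs(rate - p) < 4 * se

    def test_reaction_times_within_window(self):
        truth = PsychTruth(m=np.log(2.0), w=0.5, lam=0.0, gamma=0.0)
        seq = self._sequence(50, 300)
        recs = generate_behavior(seq, truth, seed=2, x_true=np.full(300, 1e5))
        scored = score_trials(recs)
        rts = [t.reaction_time_s for t in scored if t.outcome == "hit"]
        assert len(rts) > 290
        assert all(0.15 < rt <= 1.15 for rt in rts)


class TestPlantedActivations:
    def test_counts_bounded_by_zones(self, small_config):
        seq = generate_trial_sequence(small_config, seed=4)
        rng = np.random.default_rng(0)
        activated, n_act = plant_target_activations(seq, small_config, rng)
        for (tt, _), zones, n in zip(seq, activated, n_act):
            assert n == zones.size
            assert n <= (0 if tt == CATCH else tt)

    def test_expected_count_binomial(self, small_config):
        seq = [(50, 10.0 * i) for i in range(1, 1001)]
        rng = np.random.default_rng(1)
        _, n_act = plant_target_activations(seq, small_config, rng)
        p = small_config.p_target_activation
        se = np.sqrt(50 * p * (1 - p) / 1000)
        assert abs(n_act.mean() - 50 * p) <= 3 * se


class TestFullSession:
    def test_determinism_bit_identical(self, small_config):
        a = simulate_session(small_config)
        b = simulate_session(dataclasses.replace(small_config))
        assert [t.trial_type for t in a.trials] == [t.trial_type for t in b.trials]
        np.testing.assert_array_equal(a.f_roi, b.f_roi)
        np.testing.assert_array_equal(a.f_neuropil, b.f_neuropil)
        np.testing.assert_array_equal(a.centroids_um, b.centroids_um)
        for x, y in zip(a.trials, b.trials):
            np.testing.assert_array_equal(x.lick_times_s, y.lick_times_s)

    def test_neuropil_coefficient_recovery(self, session):
        c = session_neuropil_coefficients(session.f_roi[:30], session.f_neuropil[:30])
        assert np.mean(c) == pytest.approx(session.config.neuropil_coeff_true, abs=0.05)

    def test_deterministic_targets_all_cross_threshold(self):
        # p_target_activation = 1, huge transients, tiny noise:
        # every target crosses any finite activation threshold on every go trial
        cfg = SimConfig(
            n_neurons=40,
            trial_type_set=(0, 10),
            trial_ratios=(0.5, 0.5),
            n_trials=30,
            warmup_trials=0,
            p_target_activation=1.0,
            transient_amplitude_sd_units=100.0,
            transient_tau_s=2.0,
            noise_sd=1.0,
            suppression_base=0.0,
            suppression_slope=0.0,
            frac_lick_modulated=0.0,
            spont_event_rate_hz=0.0,
            seed=5,
        )
        s = simulate_session(cfg)
        onsets = np.array([t.onset_s for t in s.trials])
        mask = artefact_exclusion_mask(onsets, s.volume_times_s)
        resp = extract_trial_responses(s.f_roi, s.volume_times_s, onsets, mask)
        scored = score_trials(s.trials)
        go = [i for i, t in enumerate(scored) if t.trial_type == 10]
        cr = [i for i, t in enumerate(scored) if t.outcome == "correct_reject"]
        tgt = s.ground_truth.target_mask(10, cfg.n_neurons)
        from optodetect.thresholds import classify_responses, compute_thresholds

        ts = compute_thresholds(resp[:, cr], 3.0, 3.0)  # harshest in-sweep threshold
        cls, _ = classify_responses(resp, ts)
        assert np.all(cls[np.flatnonzero(tgt)][:, go] == ACTIVATED)

    def test_ground_truth_consistency(self, session):
        gt = session.ground_truth
        for rec, zones in zip(session.trials, gt.per_trial_activated_zones):
            limit = 0 if rec.trial_type == CATCH else rec.trial_type
            assert zones.size <= limit
        tm = gt.target_mask(25, session.config.n_neurons)
        assert tm.sum() == 25

    def test_target_labels_match_geometry(self, session):
        from optodetect.targets import classify_rois

        gt = session.ground_truth
        for tt in session.config.go_types:
            geometric = classify_rois(session.centroids_um, gt.zone_coords_um[:tt])
            np.testing.assert_array_equal(
                geometric, gt.target_mask(tt, session.config.n_neurons)
            )

    def test_traces_cover_all_trials(self, session):
        last = max(t.onset_s for t in session.trials)
        assert session.volume_times_s[0] <= session.trials[0].onset_s - 1.0
        assert session.volume_times_s[-1] >= last + 5.0
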