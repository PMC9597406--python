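"""The synthetic gait-trial generator and its ground-truth contracts."""

import numpy as np
import pandas as pd
import pytest

from gaitcosts.ccp import identify_transitions
from gaitcosts.costs import TrialCosts
from gaitcosts.emg import MUSCLES, compute_activation_table, compute_envelope
from gaitcosts.exceptions import ConfigurationError
from gaitcosts.gait_events import detect_strides
from gaitcosts.synthetic import (
    default_profiles,
    generate_cohort,
    generate_trial,
    simulate_choice,
)


class TestGenerateTrial:
    def test_equal_seeds_are_bit_identical(self, profile):
        a = generate_trial(profile, 12, duration=90.0, seed=5)
        b = generate_trial(profile, 12, duration=90.0, seed=5)
        pd.testing.assert_frame_equal(a.emg, b.emg)
        np.testing.assert_array_equal(a.grf, b.grf)
        pd.testing.assert_frame_equal(a.breaths, b.breaths)

    def test_different_seeds_differ(self, profile):
        a = generate_trial(profile, 12, duration=90.0, seed=5)
        b = generate_trial(profile, 12, duration=90.0, seed=6)
        assert not np.array_equal(a.emg.to_numpy(), b.emg.to_numpy())

    def test_zero_gain_profile_gives_zero_emg(self, profile):
        from dataclasses import replace

        zero = replace(
            profile, baseline_gains=pd.Series(0.0, index=list(MUSCLES))
        )
        rec = generate_trial(zero, "crouch", duration=90.0, seed=1)
        np.testing.assert_array_equal(rec.emg.to_numpy(), 0.0)

    def test_short_duration_rejected(self, profile):
        with pytest.raises(ConfigurationError):
            generate_trial(profile, 0, duration=60.0, seed=1)

    def test_unknown_condition_rejected(self, profile):
        with pytest.raises(ConfigurationError):
            generate_trial(profile, "downhill", duration=90.0, seed=1)

    def test_recording_invariants(self, profile):
        rec = generate_trial(profile, 18, duration=120.0, seed=2)
        assert len(rec.emg) == len(rec.grf)
        assert (rec.grf >= 0).all()
        t = rec.breaths["time_s"].to_numpy()
        assert (np.diff(t) > 0).all() and t[0] >= 0 and t[-1] <= rec.duration
        # >= 6 stance phases in the record
        assert rec.truth.contact_times.size >= 6
        # swing-phase force is exactly zero
        fs = rec.sampling_rate
        mid_swing = rec.truth.contact_times[:-1] + 0.9 * np.diff(rec.truth.contact_times)
        assert all(rec.grf[int(ts * fs)] == 0.0 for ts in mid_swing)

    def test_condition_gain_structure(self, profile):
        g0 = profile.gains_for(0)
        g24 = profile.gains_for(24)
        np.testing.assert_allclose(g24 / g0, 1 + profile.incline_slope * 24)
        gc = profile.gains_for("crouch")
        np.testing.assert_allclose(gc / g0, profile.crouch_gains)


class TestStrideRecovery:
    @pytest.mark.parametrize("frac", [0.01, 0.02, 0.05, 0.2])
    def test_any_threshold_recovers_scheduled_contacts(self, profile, frac):
        # swing force is exactly zero, so every relative threshold in
        # (0, 20%] finds each stance onset, delayed only by the half-sine
        # rise to the threshold plus one sample of quantization
        rec = generate_trial(profile, 6, duration=120.0, seed=3)
        sw = detect_strides(rec.grf, rec.sampling_rate, threshold_fraction=frac)
        sched = rec.truth.contact_times
        assert sw.n_strides == sched.size - 1
        latency = rec.truth.stance_duration / np.pi * np.arcsin(frac)
        err = sw.contact_times - sched - latency
        assert np.abs(err).max() < 2.0 / rec.sampling_rate


class TestNoiseFreeRecovery:
    def test_gain_ratio_recovered_exactly_with_sine_carrier(self, profile):
        # all stochastic terms off (deterministic carrier, no stride-time
        # jitter): the envelope is analytically proportional to the gain,
        # so the normalized activation ratio between 24% and 0% equals the
        # gain ratio 1 + 0.05*24 = 2.2 essentially exactly. With jitter on,
        # the fixed-duration stance burst over a varying stride time adds a
        # few percent of between-trial spread (covered at cohort level in
        # the recovery tests).
        from dataclasses import replace

        quiet = replace(profile, stride_time_cv=0.0)
        kw = dict(duration=90.0, carrier="sine")
        rec0 = generate_trial(quiet, 0, seed=21, **kw)
        rec24 = generate_trial(quiet, 24, seed=22, **kw)

        def activation(rec, baseline=None):
            sw = detect_strides(rec.grf, rec.sampling_rate)
            envs = {
                m: compute_envelope(rec.emg[m].to_numpy(), rec.sampling_rate, muscle=m)
                for m in MUSCLES
            }
            return compute_activation_table(envs, sw, baseline=baseline)

        base = activation(rec0)
        ratio = activation(rec24, baseline=base).mean_A()
        np.testing.assert_allclose(ratio.to_numpy(), 2.2, rtol=1e-3)


class TestGenerateCohort:
    def test_trial_counts(self):
        profiles = default_profiles(4, seed=9)
        cohort = generate_cohort(profiles, duration=90.0, seed=9)
        assert len(cohort) == 4
        for trials in cohort.values():
            assert len(trials) == 7  # 2 crouch + 5 inclines
            crouch = [k for k in trials if k.startswith("crouch")]
            assert sorted(crouch) == ["crouch_final", "crouch_initial"]

    def test_cohort_determinism(self):
        profiles = default_profiles(2, seed=3)
        c1 = generate_cohort(profiles, duration=90.0, seed=3)
        c2 = generate_cohort(profiles, duration=90.0, seed=3)
        pid = profiles[0].participant_id
        pd.testing.assert_frame_equal(
            c1[pid]["incline_12"].emg, c2[pid]["incline_12"].emg
        )
        np.testing.assert_array_equal(
            c1[pid]["crouch_final"].grf, c2[pid]["crouch_final"].grf
        )

    def test_duplicate_ids_rejected(self):
        p = default_profiles(1, seed=0)
        with pytest.raises(ConfigurationError, match="duplicate"):
            generate_cohort([p[0], p[0]], duration=90.0, seed=0)

    def test_default_profiles_satisfy_invariants(self):
        for p in default_profiles(10, seed=11):
            assert p.mass > 0 and 0.7 <= p.rer <= 1.1
            assert (p.baseline_gains > 0).all()
            assert p.crouch_gains["RF"] > 1 and p.crouch_gains["VM"] > 1
            assert min(p.vo2_baseline, p.vo2_crouch, p.vo2_per_grade) > 0


def _cost_map(met_by_cond, a2_by_cond):
    return {
        cond: TrialCosts(
            c_met_p=met_by_cond[cond], c_a2=a2_by_cond[cond],
            c_a_max=1.0, c_a_vol=1.0, condition=cond, participant_id="sim",
        )
        for cond in met_by_cond
    }


class TestSimulateChoice:
    # crouch: moderate metabolic cost, high activation cost; incline:
    # metabolic cost rises with grade, activation rises more slowly
    met = {"crouch": 7.8, "incline_0": 4.3, "incline_6": 6.2, "incline_12": 8.1,
           "incline_18": 10.1, "incline_24": 12.0}
    a2 = {"crouch": 4.8, "incline_0": 1.0, "incline_6": 1.9, "incline_12": 3.0,
          "incline_18": 4.3, "incline_24": 6.0}

    def test_pure_metabolic_agent_minimizes_power(self):
        seq = simulate_choice(_cost_map(self.met, self.a2), weights=(1.0, 0.0))
        for g in (0, 6, 12, 18, 24):
            expected = "crouch" if self.met["crouch"] < self.met[f"incline_{g}"] else "incline"
            assert seq.choices[g] == expected

    def test_pure_activation_agent_minimizes_a2(self):
        seq = simulate_choice(_cost_map(self.met, self.a2), weights=(0.0, 1.0))
        for g in (0, 6, 12, 18, 24):
            expected = "crouch" if self.a2["crouch"] < self.a2[f"incline_{g}"] else "incline"
            assert seq.choices[g] == expected

    def test_transition_grade_monotone_in_activation_weight(self):
        # as the activation weight grows the agent tolerates more metabolic
        # cost to protect activation, so the crouch transition moves upward
        posts = []
        for w_act in np.linspace(0.0, 3.0, 16):
            seq = simulate_choice(_cost_map(self.met, self.a2), weights=(1.0, w_act))
            tr = identify_transitions(seq)
            posts.append(np.inf if tr.post_transition_grade is None
                         else tr.post_transition_grade)
        assert all(b >= a for a, b in zip(posts, posts[1:]))

    def test_ties_select_incline(self):
        met = dict(self.met, crouch=self.met["incline_12"])
        a2 = dict(self.a2, crouch=self.a2["incline_12"])
        seq = simulate_choice(_cost_map(met, a2), weights=(1.0, 1.0))
        assert seq.choices[12] == "incline"

    def test_missing_condition_rejected(self):
        met = dict(self.met)
        a2 = dict(self.a2)
        met.pop("incline_18"), a2.pop("incline_18")
        with pytest.raises(ConfigurationError, match="incline_18"):
            simulate_choice(_cost_map(met, a2))

    def test_degenerate_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_choice(_cost_map(self.met, self.a2), weights=(0.0, 0.0))
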