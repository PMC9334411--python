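"""Trial sequences, syllables, the spherical forward model, the simulator,
behaviour generation, and the demographics fixture."""

from collections import Counter

import numpy as np
import pytest
from scipy import signal as sig
from scipy.special import eval_legendre, lpmv

from oddballerp.iohub import MIRROR_PAIRS, SCALP_CHANNELS
from oddballerp.preprocess import epoch_and_baseline
from oddballerp.synthdata import (
    VOWEL_FORMANTS,
    default_ground_truth,
    make_lead_field,
    make_subject_table_fixture,
    make_trial_sequence,
    scan_constraint_violations,
    simulate_behavior,
    simulate_subject_eeg,
    sphere_dipole_potential,
    synthesize_syllable,
)


class TestTrialSequence:
    def test_exact_counts(self):
        seq = make_trial_sequence(800, (0.8, 0.1, 0.1), seed=0)
        counts = Counter(seq.codes)
        assert counts == {"standard": 640, "deviant1": 80, "deviant2": 80}

    def test_total_duration_rounds_to_19_minutes(self):
        seq = make_trial_sequence(800, isi_ms=1400.0, seed=1)
        assert round(seq.duration_minutes()) == 19

    @pytest.mark.parametrize("seed", range(10))
    def test_constraint_by_brute_force_scan(self, seed):
        seq = make_trial_sequence(800, (0.8, 0.1, 0.1), 3, seed=seed)
        assert scan_constraint_violations(seq.codes, 3) == 0

    def test_constraint_parameter_respected(self):
        seq = make_trial_sequence(100, (0.8, 0.1, 0.1), 4, seed=2)
        assert scan_constraint_violations(seq.codes, 4) == 0

    def test_infeasible_constraint_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            make_trial_sequence(100, (0.5, 0.25, 0.25), 3, seed=0)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            make_trial_sequence(801, (0.8, 0.1, 0.1), seed=0)

    def test_onsets_follow_isi(self):
        seq = make_trial_sequence(10, (0.8, 0.1, 0.1), seed=3, isi_ms=1400.0)
        onsets = seq.onset_samples(1000.0)
        assert onsets[0] == 0
        assert np.all(np.diff(onsets) == 1400)

    def test_sequences_vary_with_seed(self):
        a = make_trial_sequence(800, seed=0).codes
        b = make_trial_sequence(800, seed=1).codes
        assert a != b


class TestSyllables:
    def test_formant_peaks(self):
        # spectral peaks must land at the vowel formants within one Welch bin
        for vowel, (f1, f2) in VOWEL_FORMANTS.items():
            s = synthesize_syllable(vowel, "k")
            f, p = sig.welch(s.samples[int(0.05 * s.rate):], fs=s.rate, nperseg=2048)
            binw = f[1] - f[0]
            lo = (f > 100) & (f < (700 if vowel == "i" else 1000))
            hi = (f > (1500 if vowel == "i" else 900)) & (f < 3000)
            assert abs(f[lo][np.argmax(p[lo])] - f1) <= binw
            assert abs(f[hi][np.argmax(p[hi])] - f2) <= binw

    def test_duration_and_rms(self):
        s = synthesize_syllable("a", "t", duration_ms=300, rate=44100)
        assert len(s.samples) == 13230
        assert s.rms == pytest.approx(0.1, rel=1e-9)

    def test_bit_identical_given_seed(self):
        a = synthesize_syllable("i", "t", seed=4).samples
        b = synthesize_syllable("i", "t", seed=4).samples
        assert np.array_equal(a, b)

    def test_consonants_differ(self):
        a = synthesize_syllable("i", "k").samples
        b = synthesize_syllable("i", "t").samples
        assert not np.allclose(a, b)

    def test_unknown_tokens_rejected(self):
        with pytest.raises(ValueError):
            synthesize_syllable("o", "k")
        with pytest.raises(ValueError):
            synthesize_syllable("a", "b")


class TestSpherePotential:
    def test_central_dipole_closed_form(self, rng):
        # only the n=1 term survives: V = 3 (q . r_hat) / (4 pi sigma R^2)
        dirs = rng.standard_normal((20, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        q = np.array([2e-9, -1e-9, 3e-9])
        v = sphere_dipole_potential(np.zeros(3), q, dirs, radius=0.09, sigma=0.33)
        expect = 3.0 * (dirs @ q) / (4 * np.pi * 0.33 * 0.09**2)
        np.testing.assert_allclose(v, expect, rtol=1e-12)

    def test_series_against_scipy_legendre_oracle(self, rng):
        # independent evaluation with scipy's Legendre functions
        pos = np.array([0.03, 0.02, 0.04])
        q = np.array([1e-9, 2e-9, -1e-9])
        dirs = rng.standard_normal((15, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        R, sigma = 0.09, 0.33
        b = np.linalg.norm(pos)
        rq = pos / b
        c = dirs @ rq
        s = np.sqrt(1 - c**2)
        tvec = dirs - c[:, None] * rq
        tvec /= np.linalg.norm(tvec, axis=1, keepdims=True)
        q_rad = q @ rq
        q_tan = tvec @ q
        f = b / R
        v_oracle = np.zeros(len(dirs))
        for n in range(1, 120 + 1):
            pn = eval_legendre(n, c)
            # P_n^1(x) = -sqrt(1-x^2) dP_n/dx with the Condon-Shortley phase
            dpn = -lpmv(1, n, c) / np.where(s > 0, s, 1.0)
            v_oracle += f ** (n - 1) * (2 * n + 1) / n * (n * pn * q_rad + s * dpn * q_tan)
        v_oracle /= 4 * np.pi * sigma * R**2
        v = sphere_dipole_potential(pos, q, dirs, radius=R, sigma=sigma)
        np.testing.assert_allclose(v, v_oracle, rtol=1e-9)

    def test_surface_integral_vanishes(self, rng):
        # the potential has no monopole term: its surface mean is zero
        n = 20000
        z = rng.uniform(-1, 1, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        r = np.sqrt(1 - z**2)
        dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        v = sphere_dipole_potential(
            np.array([0.0, 0.02, 0.04]), np.array([1e-9, -2e-9, 1e-9]), dirs
        )
        assert abs(v.mean()) < 3 * np.abs(v).max() / np.sqrt(n)

    def test_source_outside_sphere_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            sphere_dipole_potential(np.array([0.1, 0, 0]), np.ones(3), np.eye(3))


class TestLeadField:
    def test_mirror_symmetry(self, lead_field):
        perm = [SCALP_CHANNELS.index(MIRROR_PAIRS[c]) for c in lead_field.channel_labels]
        left = lead_field.gain[lead_field.roi_indices("left")]
        right = lead_field.gain[lead_field.roi_indices("right")]
        np.testing.assert_allclose(left[:, perm], right, atol=1e-6)

    def test_gain_finite_and_labels_consistent(self, lead_field):
        assert np.all(np.isfinite(lead_field.gain))
        assert len(lead_field.hemisphere_labels) == lead_field.n_sources
        assert set(lead_field.roi_labels) == {"auditory", "other"}

    def test_auditory_patch_counts(self, lead_field):
        assert len(lead_field.roi_indices("left")) == len(lead_field.roi_indices("right"))
        assert len(lead_field.roi_indices("left")) > 0


class TestSimulator:
    def test_zero_truth_gives_flat_recording(self, lead_field):
        seq = make_trial_sequence(10, seed=0)
        truth = default_ground_truth(noise_rms_uv=0.0, ci_artifact_uv=0.0)
        truth.blink_rate_hz = 0.0
        truth.components = {k: (0.0, v[1]) for k, v in truth.components.items()}
        rec = simulate_subject_eeg(seq, truth, lead_field, "NH", rate=500.0, seed=0,
                                   include_eog=False)
        assert np.allclose(rec.data, 0.0)
        assert len(rec.events) == 10

    def test_linearity_of_scalp_projection(self, lead_field):
        seq = make_trial_sequence(10, seed=1)
        base = default_ground_truth(noise_rms_uv=0.0, ci_artifact_uv=0.0)
        base.blink_rate_hz = 0.0
        double = default_ground_truth(noise_rms_uv=0.0, ci_artifact_uv=0.0)
        double.blink_rate_hz = 0.0
        double.components = {k: (2 * a, l) for k, (a, l) in base.components.items()}
        r1 = simulate_subject_eeg(seq, base, lead_field, "NH", rate=500.0, seed=0,
                                  include_eog=False)
        r2 = simulate_subject_eeg(seq, double, lead_field, "NH", rate=500.0, seed=0,
                                  include_eog=False)
        np.testing.assert_allclose(r2.data, 2 * r1.data, atol=1e-12)

    def test_noiseless_n1_latency_recovered(self, lead_field, config):
        # peak-scan oracle: single noiseless trial, N1 trough at its true latency
        seq = make_trial_sequence(10, seed=2)
        truth = default_ground_truth(noise_rms_uv=0.0, ci_artifact_uv=0.0)
        truth.blink_rate_hz = 0.0
        rec = simulate_subject_eeg(seq, truth, lead_field, "NH", rate=500.0, seed=0,
                                   include_eog=False)
        ep = epoch_and_baseline(rec, (-100, 400), (-100, 0))
        fc = [rec.channel_labels.index(c) for c in config.frontocentral_roi]
        series = ep.data[0, fc].mean(axis=0)
        lat = ep.times_ms[np.argmin(series)]
        true_lat = truth.components[("NH", ep.conditions[0], "n1")][1]
        assert abs(lat - true_lat) <= 1000.0 / 500.0  # one sample at 500 Hz

    def test_deterministic_given_seed(self, lead_field):
        seq = make_trial_sequence(10, seed=3)
        truth = default_ground_truth()
        a = simulate_subject_eeg(seq, truth, lead_field, "CI", rate=500.0, seed=9)
        b = simulate_subject_eeg(seq, truth, lead_field, "CI", rate=500.0, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_ci_artifact_only_on_ci_ear(self, lead_field):
        seq = make_trial_sequence(10, seed=4)
        truth = default_ground_truth(noise_rms_uv=0.0)
        truth.blink_rate_hz = 0.0
        ci = simulate_subject_eeg(seq, truth, lead_field, "CI", ci_side="left",
                                  rate=500.0, seed=0, include_eog=False)
        nh = simulate_subject_eeg(seq, truth, lead_field, "NH", ci_side="left",
                                  rate=500.0, seed=0, include_eog=False)
        t7_ci = ci.data[ci.channel_labels.index("T7")]
        t7_nh = nh.data[nh.channel_labels.index("T7")]
        assert np.abs(t7_ci).max() > np.abs(t7_nh).max() + 10.0

    def test_aliasing_rate_rejected(self, lead_field):
        seq = make_trial_sequence(10, seed=5)
        with pytest.raises(ValueError, match="sampling rate"):
            simulate_subject_eeg(seq, default_ground_truth(), lead_field, "NH", rate=80.0)


class TestBehaviorSimulation:
    def test_degenerate_rt_distribution(self):
        seq = make_trial_sequence(100, seed=0)
        truth = default_ground_truth()
        truth.hit_probability = {k: 1.0 for k in truth.hit_probability}
        truth.rt_params = {"CI": (300.0, np.log(1e-9), 1e-12), "NH": (300.0, np.log(1e-9), 1e-12)}
        truth.false_alarm_rate = 0.0
        resp = simulate_behavior(seq, truth, "CI", seed=0)
        rts = [r for (i, r), c in zip(resp, seq.codes) if c != "standard"]
        assert all(r == pytest.approx(300.0, abs=1.0) for r in rts)

    def test_zero_hit_probability(self):
        seq = make_trial_sequence(100, seed=1)
        truth = default_ground_truth()
        truth.hit_probability = {k: 0.0 for k in truth.hit_probability}
        truth.false_alarm_rate = 0.0
        resp = simulate_behavior(seq, truth, "NH", seed=0)
        assert all(r is None for _, r in resp)

    def test_hit_count_matches_binomial(self):
        # mean hits over many seeds must match n p within the binomial CI
        seq = make_trial_sequence(100, seed=2)  # 10 of each deviant
        truth = default_ground_truth()
        truth.hit_probability = {k: 0.9 for k in truth.hit_probability}
        truth.false_alarm_rate = 0.0
        n_dev = sum(1 for c in seq.codes if c != "standard")
        counts = []
        for s in range(300):
            resp = simulate_behavior(seq, truth, "CI", seed=s)
            counts.append(sum(r is not None for (i, r), c in zip(resp, seq.codes) if c != "standard"))
        mean = np.mean(counts)
        se = np.sqrt(n_dev * 0.9 * 0.1 / 300)
        assert abs(mean - n_dev * 0.9) < 4 * se


class TestSubjectTable:
    def test_row_count_and_sides(self):
        tbl = make_subject_table_fixture()
        assert len(tbl) == 19
        assert (tbl["ci_side"] == "right").sum() == 9
        assert (tbl["ci_side"] == "left").sum() == 10

    def test_age_range(self):
        tbl = make_subject_table_fixture()
        assert tbl["age_years"].min() == 37
        assert tbl["age_years"].max() == 66

    def test_pta_nh_within_inclusion_bound(self):
        assert make_subject_table_fixture()["pta_nh_db"].max() <= 30

    def test_two_left_handers(self):
        assert (make_subject_table_fixture()["handedness"] == "left").sum() == 2
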