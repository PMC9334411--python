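"""FIR design, filtering, resampling, epoching, rejection, ICA, cleaning,
and spherical-spline interpolation."""

import numpy as np
import pytest
from scipy import signal

from oddballerp.iohub import MONTAGE_1020, Recording, RunConfig, montage_positions
from oddballerp.preprocess import (
    Epochs,
    FirFilterSpec,
    cut_dummy_segments,
    design_fir,
    epoch_and_baseline,
    filter_recording,
    interpolate_channels,
    interpolation_matrix,
    reject_by_amplitude,
    resample,
    run_ica,
    score_artifact_components,
    stimulus_boxcar,
    two_stage_clean,
)
from oddballerp.synthdata import (
    default_ground_truth,
    make_trial_sequence,
    simulate_subject_eeg,
)


class TestFirDesign:
    def test_lowpass_unit_dc_gain(self):
        taps = design_fir(FirFilterSpec("lowpass", 40.0, 2.0), 500.0)
        assert taps.sum() == pytest.approx(1.0, abs=1e-6)
        assert len(taps) % 2 == 1

    def test_highpass_zero_dc_gain(self):
        taps = design_fir(FirFilterSpec("highpass", 0.5, 1.0), 500.0)
        assert taps.sum() == pytest.approx(0.0, abs=1e-6)

    def test_stopband_attenuation_oracle(self):
        # frequency-response oracle for the 40 Hz / 2 Hz transition design
        taps = design_fir(FirFilterSpec("lowpass", 40.0, 2.0), 500.0)
        w, h = signal.freqz(taps, worN=8192, fs=500.0)
        at_45 = 20 * np.log10(np.abs(h[np.argmin(np.abs(w - 45.0))]))
        assert at_45 <= -59.0

    def test_minus_6db_point_at_cutoff(self):
        taps = design_fir(FirFilterSpec("lowpass", 40.0, 2.0), 500.0)
        w, h = signal.freqz(taps, worN=16384, fs=500.0)
        g = 20 * np.log10(np.abs(h[np.argmin(np.abs(w - 40.0))]))
        assert g == pytest.approx(-6.0, abs=0.5)

    def test_transition_too_narrow(self):
        with pytest.raises(ValueError, match="taps"):
            design_fir(FirFilterSpec("highpass", 0.1, 0.0001), 500.0)


class TestFilterRecording:
    def _rec(self, data, rate=500.0, events=None):
        labels = [f"ch{i}" for i in range(data.shape[0])]
        rec = Recording(labels, rate, data, events or [])
        rec.channel_labels = labels
        return rec

    def test_dc_removed_by_highpass(self):
        rec = Recording(["Cz"], 500.0, np.full((1, 60000), 10.0))
        out = filter_recording(rec, [FirFilterSpec("highpass", 0.1, 0.2)])
        mid = out.data[0, 25000:35000]
        assert np.abs(mid).max() < 0.1

    def test_passband_sine_preserved(self):
        t = np.arange(120000) / 500.0
        rec = Recording(["Cz"], 500.0, 5 * np.sin(2 * np.pi * 0.5 * t)[None, :])
        out = filter_recording(rec, [FirFilterSpec("highpass", 0.1, 0.2)])
        mid = out.data[0, 40000:80000]
        assert np.abs(mid).max() == pytest.approx(5.0, rel=0.01)

    def test_events_unchanged(self):
        data = np.random.default_rng(0).standard_normal((2, 60000))
        rec = Recording(["Cz", "Pz"], 500.0, data, [(1234, "standard")])
        out = filter_recording(rec, [FirFilterSpec("lowpass", 40.0, 2.0)])
        assert out.events == [(1234, "standard")]

    def test_zero_net_delay(self):
        # an impulse stays centred after zero-phase filtering
        data = np.zeros((1, 30000))
        data[0, 15000] = 1.0
        rec = Recording(["Cz"], 500.0, data)
        out = filter_recording(rec, [FirFilterSpec("lowpass", 40.0, 2.0)])
        assert abs(int(np.argmax(out.data[0])) - 15000) <= 1

    def test_too_short_recording_rejected(self):
        rec = Recording(["Cz"], 500.0, np.zeros((1, 1000)))
        with pytest.raises(ValueError, match="too short"):
            filter_recording(rec, [FirFilterSpec("highpass", 0.1, 0.2)])


class TestResample:
    def test_sample_count_and_events(self):
        rec = Recording(["Cz"], 1000.0, np.zeros((1, 10000)), [(1000, "standard")])
        out = resample(rec, 500.0)
        assert out.n_samples == 5000
        assert out.events == [(500, "standard")]

    def test_passband_tone_amplitude(self):
        t = np.arange(20000) / 1000.0
        rec = Recording(["Cz"], 1000.0, 3 * np.sin(2 * np.pi * 10 * t)[None, :])
        out = resample(rec, 500.0)
        assert np.abs(out.data[0, 1000:-1000]).max() == pytest.approx(3.0, rel=0.01)

    def test_invalid_rate(self):
        rec = Recording(["Cz"], 1000.0, np.zeros((1, 100)))
        with pytest.raises(ValueError):
            resample(rec, -1.0)


class TestEpoching:
    def test_sample_count_and_baseline_zero(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((3, 5000))
        events = [(1000, "standard"), (2500, "deviant1")]
        rec = Recording(["Cz", "Pz", "Fz"], 500.0, data, events)
        ep = epoch_and_baseline(rec, (-100, 400), (-100, 0))
        assert ep.data.shape == (2, 3, 250)
        bmask = (ep.times_ms >= -100) & (ep.times_ms < 0)
        np.testing.assert_allclose(ep.data[:, :, bmask].mean(axis=2), 0.0, atol=1e-9)

    def test_constant_channel_zeroed(self):
        rec = Recording(["Cz"], 500.0, np.full((1, 2000), 5.0), [(1000, "standard")])
        ep = epoch_and_baseline(rec, (-100, 400), (-100, 0))
        np.testing.assert_allclose(ep.data, 0.0, atol=1e-9)

    def test_edge_events_dropped_with_bookkeeping(self):
        rec = Recording(
            ["Cz"], 500.0, np.zeros((1, 1000)),
            [(10, "standard"), (500, "deviant1"), (990, "deviant2")],
        )
        ep = epoch_and_baseline(rec, (-100, 400), (-100, 0))
        assert ep.n_trials == 1
        assert list(ep.conditions) == ["deviant1"]

    def test_condition_counts_preserved(self):
        seq = make_trial_sequence(100, seed=6)
        onsets = 300 + np.arange(100) * 400
        data = np.zeros((1, int(onsets[-1] + 500)))
        rec = Recording(["Cz"], 500.0, data, [(int(o), c) for o, c in zip(onsets, seq.codes)])
        ep = epoch_and_baseline(rec, (-100, 400), (-100, 0))
        assert ep.n_trials == 100
        vals, counts = np.unique(ep.conditions, return_counts=True)
        assert dict(zip(vals, counts)) == {"standard": 80, "deviant1": 10, "deviant2": 10}


class TestRejection:
    def test_outlier_segment_identified(self, rng):
        segs = rng.standard_normal((50, 4, 100))
        segs[17, 2] *= 100.0
        kept = reject_by_amplitude(segs, 4.0)
        # direct recomputation oracle
        sd = segs.std(axis=(0, 2))
        oracle = ~(np.abs(segs).max(axis=2) > 4.0 * sd[None, :]).any(axis=1)
        assert np.array_equal(kept, oracle)
        assert not kept[17]

    def test_identical_segments_all_kept(self):
        seg = np.sin(np.linspace(0, 10, 200))[None, :]
        segs = np.repeat(seg[None, :, :], 10, axis=0)
        assert reject_by_amplitude(segs, 4.0).all()

    def test_infinite_threshold_keeps_all(self, rng):
        segs = rng.standard_normal((20, 3, 50))
        assert reject_by_amplitude(segs, np.inf).all()

    def test_all_rejected_raises(self):
        segs = np.zeros((3, 1, 10))
        segs[:, 0, 5] = [100.0, 200.0, 300.0]
        with pytest.raises(ValueError, match="every segment"):
            reject_by_amplitude(segs, 0.01)

    def test_dummy_segmentation_shape(self, rng):
        data = rng.standard_normal((5, 10500))
        segs = cut_dummy_segments(data, 500.0, 2.0)
        assert segs.shape == (10, 5, 1000)


class TestIca:
    def _mixture(self, rng, n=30000):
        t = np.arange(n) / 500.0
        s = np.vstack([np.sin(2 * np.pi * 3 * t), rng.uniform(-1, 1, n)])
        a = np.array([[1.0, 0.4], [0.3, 1.0]])
        return a @ s, s

    def test_known_mixture_recovered(self, rng):
        x, s = self._mixture(rng)
        ica = run_ica(x, seed=1)
        rec = ica.sources(x)
        corr = np.abs(np.corrcoef(np.vstack([rec, s]))[:2, 2:])
        # each recovered component matches one true source
        assert corr.max(axis=1).min() > 0.95

    def test_unmixing_mixing_identity(self, rng):
        x, _ = self._mixture(rng)
        ica = run_ica(x, seed=2)
        np.testing.assert_allclose(
            ica.unmixing @ ica.mixing, np.eye(ica.n_components), atol=1e-6
        )

    def test_deterministic_given_seed(self, rng):
        x, _ = self._mixture(rng)
        a = run_ica(x, seed=3)
        b = run_ica(x, seed=3)
        np.testing.assert_array_equal(a.unmixing, b.unmixing)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="samples"):
            run_ica(rng.standard_normal((10, 1999)), seed=0)

    def test_removal_reconstructs_remainder(self, rng):
        x, _ = self._mixture(rng)
        ica = run_ica(x, seed=4)
        cleaned = ica.remove_components(x, set())
        np.testing.assert_allclose(cleaned, x, atol=1e-8)


class TestComponentScoring:
    def _synthetic_case(self, rng):
        """Known mixing of a CI-artifact template, a blink and brain noise."""
        rate, n = 500.0, 60000
        onsets = np.arange(200, n - 400, 700)
        box = stimulus_boxcar(n, rate, onsets, 300.0)
        blink = np.zeros(n)
        for b0 in rng.integers(0, n - 200, 25):
            blink[b0:b0 + 150] += np.hanning(150)
        brain = rng.standard_normal(n)
        labels = ["T7", "FC5", "Fp1", "Fz", "Cz", "Pz"]
        mix = np.zeros((6, 3))
        mix[0, 0], mix[1, 0] = 3.0, 1.5          # artifact on implant-side temporals
        mix[2, 1] = 2.5                            # blink frontal
        mix[:, 2] = rng.uniform(0.5, 1.0, 6)       # brain everywhere
        x = mix @ np.vstack([box - box.mean(), blink, brain])
        x += 0.05 * rng.standard_normal(x.shape)
        ica = run_ica(x, seed=5)
        ica.channel_labels = labels
        return ica, x, onsets, rate, blink

    def test_ci_artifact_component_scores_high(self, rng):
        ica, x, onsets, rate, blink = self._synthetic_case(rng)
        scores = score_artifact_components(
            ica, x, stim_onsets=onsets, rate=rate, implant_side="left", eog=blink
        )
        ci = scores["ci_artifact_score"]
        assert ci.max() > 0.8
        assert np.sort(ci)[-2] < 0.2  # remaining components look nothing like it
        assert np.all((ci >= 0) & (ci <= 1))

    def test_blink_component_has_highest_ocular_score(self, rng):
        ica, x, onsets, rate, blink = self._synthetic_case(rng)
        scores = score_artifact_components(
            ica, x, stim_onsets=onsets, rate=rate, implant_side="left", eog=blink
        )
        oc = scores["ocular_score"]
        ci = scores["ci_artifact_score"]
        assert np.argmax(oc) != np.argmax(ci)
        assert oc.max() > 0.8


class TestInterpolation:
    def _epochs_from_topography(self, topo, labels):
        data = topo[None, :, None] * np.ones((3, 1, 50))
        return Epochs(
            data, np.linspace(0, 98, 50), (0, 100), (0, 2),
            np.array(["standard"] * 3), list(labels), 500.0,
        )

    def test_constant_topography_reproduced(self):
        labels = list(MONTAGE_1020)
        ep = self._epochs_from_topography(np.full(30, 7.5), labels)
        out = interpolate_channels(ep, ["Cz"])
        np.testing.assert_allclose(
            out.data[:, labels.index("Cz")], 7.5, atol=1e-6
        )

    def test_leave_one_out_on_smooth_topography(self, rng):
        # low-order harmonic topographies: leave-one-out reconstruction
        # correlates > 0.95 with the true values across channels
        labels = list(MONTAGE_1020)
        pos = montage_positions(labels)
        for _ in range(3):
            c = rng.standard_normal(4)
            topo = pos @ c[:3] + c[3] * (3 * pos[:, 2] ** 2 - 1) / 2
            trues, preds = [], []
            for target in labels:
                good = [ch for ch in labels if ch != target]
                mat = interpolation_matrix(good, [target])
                gv = np.array([topo[labels.index(ch)] for ch in good])
                preds.append((mat @ gv).item())
                trues.append(topo[labels.index(target)])
            assert np.corrcoef(trues, preds)[0, 1] > 0.95

    def test_matches_mne_perrin_implementation(self):
        # independent oracle for the Perrin spline operator
        interp_mod = pytest.importorskip("mne.channels.interpolation")
        labels = list(MONTAGE_1020)
        good = [c for c in labels if c not in ("T7", "FC5")]
        mine = interpolation_matrix(good, ["T7", "FC5"])
        theirs = interp_mod._make_interpolation_matrix(
            montage_positions(good), montage_positions(["T7", "FC5"])
        )
        np.testing.assert_allclose(mine, theirs, atol=1e-4)

    def test_up_to_two_missing_channels_supported(self, lead_field):
        labels = list(lead_field.channel_labels)
        topo = lead_field.gain[1]
        ep = self._epochs_from_topography(topo, labels)
        out = interpolate_channels(ep, ["T7", "FC5"])  # implant-side pair
        assert np.all(np.isfinite(out.data))

    def test_unknown_channel_rejected(self, lead_field):
        labels = list(lead_field.channel_labels)
        ep = self._epochs_from_topography(lead_field.gain[0], labels)
        with pytest.raises(KeyError):
            interpolate_channels(ep, ["XX"])


@pytest.fixture(scope="module")
def cleaned():
    cfg = RunConfig()
    from oddballerp.synthdata import make_lead_field

    lf = make_lead_field()
    seq = make_trial_sequence(80, seed=11)
    truth = default_ground_truth("left", True)
    recs = {}
    for ear in ("CI", "NH"):
        rec = simulate_subject_eeg(seq, truth, lf, ear, "left", rate=500.0, seed=21)
        recs[ear] = rec
    ep_ci, ep_nh, report = two_stage_clean(recs["CI"], recs["NH"], cfg, ci_side="left")
    return recs, ep_ci, ep_nh, report, lf, seq, cfg


class TestTwoStageCleaning:

    def test_artifact_component_removed_at_stage1(self, cleaned):
        _, _, _, report, _, _, _ = cleaned
        assert len(report.stage1_removed) >= 1
        assert report.stage1_scores.max() > 0.5

    def test_artifact_template_power_reduced(self, cleaned):
        recs, ep_ci, _, _, _, _, cfg = cleaned
        dirty = epoch_and_baseline(recs["CI"], cfg.epoch_window_ms, cfg.baseline_ms)

        def temporal_power(ep):
            idx = [ep.channel_labels.index(c) for c in ("T7", "FC5", "CP5")]
            mask = (ep.times_ms >= 0) & (ep.times_ms < 300)
            m = ep.data[ep.kept][:, idx][:, :, mask].mean(axis=0)
            return float((m.mean(axis=1) ** 2).sum())

        didx = [dirty.channel_labels.index(c) for c in ep_ci.channel_labels]
        dirty_p = temporal_power(
            Epochs(dirty.data[:, didx], dirty.times_ms, dirty.window_ms,
                   dirty.baseline_ms, dirty.conditions, list(ep_ci.channel_labels), 500.0)
        )
        assert temporal_power(ep_ci) < 0.1 * dirty_p

    def test_event_timing_and_labels_untouched(self, cleaned):
        recs, ep_ci, _, _, _, seq, _ = cleaned
        assert list(ep_ci.conditions) == [c for _, c in recs["CI"].events]

    def test_provenance_counts_bounded(self, cleaned):
        _, ep_ci, _, report, _, _, _ = cleaned
        n_comp = len(ep_ci.channel_labels)
        assert len(report.stage1_removed) + len(report.stage2_removed) <= n_comp
        assert 0 <= report.segments_rejected <= report.segments_total

    def test_artifact_free_input_is_noop_at_stage1(self, lead_field):
        cfg = RunConfig()
        seq = make_trial_sequence(80, seed=12)
        truth = default_ground_truth("left", True, ci_artifact_uv=0.0)
        truth.blink_rate_hz = 0.0
        ci = simulate_subject_eeg(seq, truth, lead_field, "CI", "left", rate=500.0, seed=31)
        nh = simulate_subject_eeg(seq, truth, lead_field, "NH", "left", rate=500.0, seed=32)
        _, _, report = two_stage_clean(ci, nh, cfg, ci_side="left")
        assert report.stage1_removed == []
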