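"""End-to-end synthetic study: simulate every participant, run the
measurement pipeline, and assemble the tables the statistics battery eats.

The "light" measurement path simulates directly at the analysis rate
without ocular/implant artifacts (those stages are exercised separately by
the artifact-cleaning workflow) so that multi-subject studies stay cheap:
simulate -> epoch -> correct-trials-only averages -> ROI peaks -> dSPM ROI
peaks.  Ground-truth parameters per subject come from
:func:`oddballerp.synthdata.default_ground_truth`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import erp as erpmod
from . import source as srcmod
from .iohub import RunConfig
from .preprocess import epoch_and_baseline
from .synthdata import (
    GroundTruth,
    LeadField,
    default_ground_truth,
    make_lead_field,
    make_subject_table_fixture,
    make_trial_sequence,
    simulate_behavior,
    simulate_subject_eeg,
)

#: extended sensor epoch so the 300-900 ms P3b window is measurable
MEASUREMENT_WINDOW_MS = (-100.0, 950.0)
SOURCE_WINDOW_MS = (-200.0, 500.0)

#: subjective listening-effort generator means (0-5 scale)
EFFORT_MEANS = {"CI": 3.2, "NH": 1.8, "vocoded": 3.0, "original": 1.8}


@dataclass
class SubjectMeasurement:
    """Measured quantities for one subject x ear (or condition x side)."""

    score: bhv.BehavioralScore
    peaks: dict[tuple[str, str], erpmod.PeakMeasure]  # (condition, component)
    source_peak_value: float
    source_peak_latency_ms: float
    source_left: srcmod.RoiActivation
    source_right: srcmod.RoiActivation


def measure_subject_ear(
    seq,
    truth: GroundTruth,
    lf: LeadField,
    ear: str,
    ci_side: str,
    config: RunConfig,
    seed: int,
) -> SubjectMeasurement:
    """Simulate one subject x ear and run the light measurement path."""
    responses = simulate_behavior(seq, truth, ear, seed=seed)
    score = bhv.score_responses(seq, responses, config.response_window_ms)

    rec = simulate_subject_eeg(
        seq, truth, lf, ear, ci_side=ci_side, rate=config.analysis_rate,
        seed=seed + 1, frontocentral_roi=config.frontocentral_roi,
        parietal_roi=config.parietal_roi, include_eog=False,
    )
    ep = epoch_and_baseline(rec, MEASUREMENT_WINDOW_MS, config.baseline_ms)
    correct = erpmod.trial_correctness(
        np.array(seq.codes), responses, config.response_window_ms
    )

    peaks: dict[tuple[str, str], erpmod.PeakMeasure] = {}
    erps = {}
    for cond in ("standard", "deviant1", "deviant2"):
        try:
            erp, n = erpmod.subject_erp(ep, cond, correct)
        except ValueError:
            continue
        erps[cond] = erp
        fc = erpmod.roi_average(erp, ep.channel_labels, config.frontocentral_roi)
        pz = erpmod.roi_average(erp, ep.channel_labels, config.parietal_roi)
        peaks[(cond, "N1")] = erpmod.detect_peak(
            fc, ep.times_ms, "N1", config.n1_window_ms, n_trials=n
        )
        peaks[(cond, "P2")] = erpmod.detect_peak(
            fc, ep.times_ms, "P2", config.p2_window_ms, n_trials=n
        )
        peaks[(cond, "P3b")] = erpmod.detect_peak(
            pz, ep.times_ms, "P3b", config.p3b_window_ms, n_trials=n
        )

    # source analysis on the average across standard and deviant 1
    ep_src = epoch_and_baseline(rec, SOURCE_WINDOW_MS, config.baseline_ms)
    cov = srcmod.compute_noise_covariance(
        ep_src, config.noise_cov_window_ms, config.cov_shrinkage
    )
    inv = srcmod.make_inverse(lf, cov, config.snr)
    src_erp = np.mean([erps[c] for c in ("standard", "deviant1") if c in erps], axis=0)
    n_src = len(lf.channel_labels)
    est = srcmod.apply_dspm(
        inv, srcmod.average_reference(src_erp[:n_src]), ep.times_ms
    )
    left, right = srcmod.roi_activation(est, lf, config.n1_window_ms)
    peak_val = max(left.peak_value, right.peak_value)
    peak_lat = (left.peak_latency_ms + right.peak_latency_ms) / 2.0
    return SubjectMeasurement(score, peaks, peak_val, peak_lat, left, right)


def _effort(rng: np.random.Generator, key: str) -> float:
    return float(np.clip(rng.normal(EFFORT_MEANS[key], 0.7), 0.0, 5.0))


def simulate_study(
    config: RunConfig | None = None,
    seed: int = 0,
    n_trials: int | None = None,
    include_controls: bool = True,
    n_controls: int = 10,
    noise_rms_uv: float = 8.0,
) -> dict[str, pd.DataFrame]:
    """Simulate the whole cohort and return the statistics input tables.

    The 19 implanted participants come from the demographics fixture
    (implant side and proficiency group as printed); controls are
    normal-hearing listeners tested per side with original and vocoded
    syllables.  ``n_trials`` overrides the per-run trial count (default
    200, exact 80/10/10 composition) to bound runtime; all other
    parameters follow the run configuration.
    """
    config = (config or RunConfig()).validate()
    n_trials = n_trials or 200
    lf = make_lead_field()
    table = make_subject_table_fixture()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    beh_rows, peak_rows, src_rows = [], [], []
    for i, row in table.iterrows():
        sid, ci_side, group = row["id"], row["ci_side"], row["group"]
        truth = default_ground_truth(
            ci_side=ci_side, proficient=(group == "proficient"),
            noise_rms_uv=noise_rms_uv, ci_artifact_uv=0.0,
            rng=np.random.default_rng(ss.spawn(1)[0]),
        )
        truth.blink_rate_hz = 0.0
        for ear in ("CI", "NH"):
            sub_seed = int(np.random.default_rng(ss.spawn(1)[0]).integers(2**31 - 10))
            seq = make_trial_sequence(
                n_trials, config.probabilities, config.min_preceding_standards,
                seed=sub_seed, isi_ms=config.isi_ms,
            )
            m = measure_subject_ear(seq, truth, lf, ear, ci_side, config, sub_seed)
            for dev in ("deviant1", "deviant2"):
                beh_rows.append(
                    dict(
                        subject=sid, group=group, ci_side=ci_side, ear=ear,
                        deviant=dev, hit_rate=m.score.hit_rate.get(dev, np.nan),
                        mean_rt=m.score.mean_rt_ms.get(dev, np.nan),
                        effort=_effort(rng, ear),
                    )
                )
            for (cond, comp), pk in m.peaks.items():
                peak_rows.append(
                    dict(
                        subject=sid, group=group, ci_side=ci_side, ear=ear,
                        condition=cond, component=comp,
                        amplitude=pk.amplitude_uv, latency=pk.latency_ms,
                        n_trials=pk.n_trials,
                    )
                )
            for hemi, act in (("left", m.source_left), ("right", m.source_right)):
                src_rows.append(
                    dict(
                        subject=sid, group=group, ci_side=ci_side, ear=ear,
                        hemisphere=hemi, peak_value=act.peak_value,
                        peak_latency=act.peak_latency_ms,
                    )
                )

    tables = {
        "behavior": pd.DataFrame(beh_rows),
        "peaks": pd.DataFrame(peak_rows),
        "source": pd.DataFrame(src_rows),
        "subjects": table,
    }
    if include_controls:
        tables.update(
            _simulate_controls(config, ss, lf, n_controls, n_trials, noise_rms_uv)
        )
    return tables


def control_ground_truth(condition: str, side: str, noise_rms_uv: float = 8.0) -> GroundTruth:
    """Normal-hearing control truth for one stimulation side x condition.

    Vocoded stimulation carries a larger P2 and, for the left ear only, a
    right-dominant auditory asymmetry; original stimulation is symmetric.
    Hit rates are slightly higher for right-ear stimulation.
    """
    comps = {}
    p2_amp = 5.2 if condition == "vocoded" else 4.0
    for cond in ("standard", "deviant1", "deviant2"):
        comps[("NH", cond, "n1")] = (-5.0, 110.0)
        comps[("NH", cond, "p2")] = (p2_amp, 220.0)
    for dev in ("deviant1", "deviant2"):
        comps[("NH", dev, "p3b")] = (6.0, 550.0)
    if condition == "vocoded" and side == "left":
        gains = {"NH": (1.0, 1.6)}
    else:
        gains = {"NH": (1.2, 1.25)}
    hit1 = 0.94 if side == "right" else 0.90
    hits = {("NH", "deviant1"): hit1, ("NH", "deviant2"): hit1 - 0.04}
    rts = {"NH": (320.0, np.log(180.0), 0.35)}
    return GroundTruth(comps, gains, hits, rts, noise_rms_uv=noise_rms_uv,
                       ci_artifact_uv=0.0, blink_rate_hz=0.0)


def _simulate_controls(config, ss, lf, n_controls, n_trials, noise_rms_uv):
    rng = np.random.default_rng(ss.spawn(1)[0])
    beh_rows, peak_rows, src_rows = [], [], []
    for c in range(n_controls):
        sid = f"nh{c + 1:02d}"
        for condition in ("original", "vocoded"):
            for side in ("left", "right"):
                sub_seed = int(np.random.default_rng(ss.spawn(1)[0]).integers(2**31 - 10))
                seq = make_trial_sequence(
                    n_trials, config.probabilities, config.min_preceding_standards,
                    seed=sub_seed, isi_ms=config.isi_ms,
                )
                truth = control_ground_truth(condition, side, noise_rms_uv)
                m = measure_subject_ear(
                    seq, truth, lf, "NH", "none", config, sub_seed
                )
                for dev in ("deviant1", "deviant2"):
                    beh_rows.append(
                        dict(
                            subject=sid, condition=condition, side=side, deviant=dev,
                            hit_rate=m.score.hit_rate.get(dev, np.nan),
                            mean_rt=m.score.mean_rt_ms.get(dev, np.nan),
                            effort=_effort(rng, condition),
                        )
                    )
                for (cond, comp), pk in m.peaks.items():
                    if cond not in ("standard", "deviant1"):
                        continue
                    peak_rows.append(
                        dict(
                            subject=sid, condition=condition, side=side,
                            stimulus=cond, component=comp,
                            amplitude=pk.amplitude_uv, latency=pk.latency_ms,
                        )
                    )
                for hemi, act in (("left", m.source_left), ("right", m.source_right)):
                    src_rows.append(
                        dict(
                            subject=sid, condition=condition, side=side,
                            hemisphere=hemi, peak_value=act.peak_value,
                            peak_latency=act.peak_latency_ms,
                        )
                    )
    return {
        "control_behavior": pd.DataFrame(beh_rows),
        "control_peaks": pd.DataFrame(peak_rows),
        "control_source": pd.DataFrame(src_rows),
    }


# --------------------------------------------------------------------------
# Declared-effect-size power simulation for the asymmetry interaction
# --------------------------------------------------------------------------


def simulate_roi_peak_table(
    rng: np.random.Generator,
    n_left: int = 10,
    n_right: int = 9,
    gains_left_implanted: tuple[float, float] = (1.0, 1.6),
    gains_right_implanted: tuple[float, float] = (1.25, 1.05),
    between_sd: float = 0.25,
    within_sd: float = 0.15,
    base: float = 4.0,
) -> pd.DataFrame:
    """ROI peak values drawn at the generator's declared effect sizes.

    Models the CI-ear auditory asymmetry: left-implanted subjects carry a
    right-dominant hemisphere gain, right-implanted subjects a near-
    symmetric one, with multiplicative between-subject and within-subject
    (hemisphere-specific) lognormal variability.
    """
    rows = []
    for g, (n, gains) in (
        ("left", (n_left, gains_left_implanted)),
        ("right", (n_right, gains_right_implanted)),
    ):
        for s in range(n):
            subj_scale = float(np.exp(rng.normal(0.0, between_sd)))
            for hemi, gain in zip(("left", "right"), gains):
                val = base * subj_scale * gain * float(np.exp(rng.normal(0.0, within_sd)))
                rows.append(
                    dict(subject=f"{g}{s}", ci_side=g, hemisphere=hemi, peak_value=val)
                )
    return pd.DataFrame(rows)
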