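"""Synthetic study inputs: trial sequences, syllables, forward model, EEG.

No patient recordings are deposited for this paradigm, so everything the
real study measured is emulated here with known ground truth: the 80/10/10
two-deviant oddball sequence (each deviant preceded by at least three
standards), two-formant /ki/-/ka/-/ti/ syllables, a dipole-in-sphere lead
field with mirrored left/right auditory patches, 30-channel stimulus-locked
EEG with N1/P2/P3b components, 1/f background noise, ocular artifacts and a
stimulus-locked cochlear-implant artifact, and per-trial button presses.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iohub import (
    EOG_CHANNEL,
    HEAD_RADIUS_M,
    MONTAGE_1020,
    SCALP_CHANNELS,
    STIMULUS_CODES,
    AudioStimulus,
    Recording,
    montage_positions,
)
from .vocoder import rms_normalize

EARS = ("CI", "NH")
DEVIANTS = ("deviant1", "deviant2")
COMPONENTS = ("n1", "p2", "p3b")

# --------------------------------------------------------------------------
# Trial sequences
# --------------------------------------------------------------------------


@dataclass
class TrialSequence:
    """Ordered stimulus codes of one oddball block."""

    codes: list[str]
    isi_ms: float

    @property
    def n_trials(self) -> int:
        return len(self.codes)

    def onset_samples(self, rate: float) -> np.ndarray:
        """Stimulus-onset sample indices at ``rate`` (onset-to-onset ISI)."""
        step = self.isi_ms / 1000.0 * rate
        return np.round(np.arange(self.n_trials) * step).astype(int)

    def duration_minutes(self) -> float:
        return self.n_trials * self.isi_ms / 1000.0 / 60.0


def make_trial_sequence(
    n_trials: int = 800,
    probabilities: tuple[float, float, float] = (0.8, 0.1, 0.1),
    min_preceding_standards: int = 3,
    seed: int | np.random.Generator = 0,
    isi_ms: float = 1400.0,
) -> TrialSequence:
    """Pseudo-random oddball sequence with exact code counts.

    Counts are ``round(n_trials * p)`` exactly, and every deviant is
    immediately preceded by at least ``min_preceding_standards`` standards
    (the first deviant counts the start of the block).  The sequence is
    drawn uniformly over all valid sequences: a valid sequence decomposes
    uniquely into (a) a weak composition of the spare standards over the
    gaps around the deviants and (b) an order of the deviant identities,
    and both parts are sampled uniformly.
    """
    if abs(sum(probabilities) - 1.0) > 1e-12:
        raise ValueError("probabilities must sum to 1")
    if any(abs(n_trials * p - round(n_trials * p)) > 1e-9 for p in probabilities):
        raise ValueError("n_trials x probabilities must give integer counts")
    counts = [round(n_trials * p) for p in probabilities]
    n_std, n_dev1, n_dev2 = counts
    n_dev = n_dev1 + n_dev2
    k = min_preceding_standards
    spare = n_std - k * n_dev
    if spare < 0:
        raise ValueError(
            f"infeasible constraint: need {k * n_dev} standards, have {n_std}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # uniform weak composition of `spare` into n_dev + 1 gaps (stars and bars)
    n_gaps = n_dev + 1
    if n_dev == 0:
        return TrialSequence(["standard"] * n_std, isi_ms)
    bars = np.sort(rng.choice(spare + n_gaps - 1, size=n_gaps - 1, replace=False))
    extras = np.diff(np.concatenate(([-1], bars, [spare + n_gaps - 1]))) - 1

    identities = [str(d) for d in rng.permutation(["deviant1"] * n_dev1 + ["deviant2"] * n_dev2)]
    codes: list[str] = []
    for i, dev in enumerate(identities):
        codes.extend(["standard"] * (k + int(extras[i])))
        codes.append(dev)
    codes.extend(["standard"] * int(extras[-1]))
    assert len(codes) == n_trials
    return TrialSequence(codes, isi_ms)


def scan_constraint_violations(codes: list[str], min_preceding: int) -> int:
    """Brute-force count of deviants not preceded by enough standards."""
    bad = 0
    for i, c in enumerate(codes):
        if c != "standard":
            before = codes[max(0, i - min_preceding):i]
            if len(before) < min_preceding and i >= min_preceding:
                before = codes[i - min_preceding:i]
            if i < min_preceding or any(b != "standard" for b in before):
                bad += 1
    return bad


# --------------------------------------------------------------------------
# Syllable synthesis
# --------------------------------------------------------------------------

#: German vowel formants (F1, F2) in Hz
VOWEL_FORMANTS = {"a": (730.0, 1284.0), "i": (278.0, 2139.0)}
#: stop-burst centre frequency and F2 onset locus per consonant, Hz
CONSONANT_LOCI = {"k": (1400.0, None), "t": (4000.0, 1800.0)}


def _resonator_track(source: np.ndarray, freqs: np.ndarray, bw: float, rate: int) -> np.ndarray:
    """Two-pole resonator with a per-sample centre-frequency track."""
    r = np.exp(-np.pi * bw / rate)
    theta = 2 * np.pi * freqs / rate
    a1 = 2 * r * np.cos(theta)
    a2 = -r * r
    y = np.zeros_like(source)
    y1 = y2 = 0.0
    gain = (1 - r) * np.sqrt(1 - 2 * r * np.cos(2 * theta) + r * r)
    for n in range(len(source)):
        y[n] = gain[n] * source[n] + a1[n] * y1 + a2 * y2
        y2, y1 = y1, y[n]
    return y


def synthesize_syllable(
    vowel: str,
    consonant: str,
    duration_ms: float = 300.0,
    rate: int = 44100,
    seed: int = 0,
) -> AudioStimulus:
    """Two-formant source-filter synthesis of a stop-consonant syllable.

    A pitch-pulsed glottal source (f0 gliding 112->92 Hz) is filtered
    through resonators at (F1, F2); /a/ = (730, 1284) Hz, /i/ =
    (278, 2139) Hz.  The consonant is a 10 ms noise burst plus a 40 ms F2
    onset transition whose locus differs for /k/ (velar: locus at the vowel
    F2) versus /t/ (alveolar: locus near 1800 Hz, high burst).  Output is
    RMS-normalized; identical arguments and seed give identical waveforms.
    """
    if vowel not in VOWEL_FORMANTS:
        raise ValueError(f"unknown vowel {vowel!r}")
    if consonant not in CONSONANT_LOCI:
        raise ValueError(f"unknown consonant {consonant!r}")
    f1, f2 = VOWEL_FORMANTS[vowel]
    burst_hz, locus = CONSONANT_LOCI[consonant]
    if locus is None:
        locus = f2  # velar locus rides on the vowel's F2
    if rate < 2.2 * max(f2, burst_hz):
        raise ValueError("sampling rate too low for the highest formant")

    n = int(round(duration_ms / 1000.0 * rate))
    t = np.arange(n) / rate
    rng = np.random.default_rng(seed)

    # glottal source: band-limited pulse train with a falling pitch glide
    f0 = np.linspace(104.0, 88.0, n)
    phase = 2 * np.pi * np.cumsum(f0) / rate
    src = np.zeros(n)
    for h in range(1, int((rate / 2.2) / f0.max()) + 1):
        if h * f0.max() > min(6000.0, rate / 2.5):
            break
        src += np.sin(h * phase)  # flat pulse-train spectrum; resonators shape it
    src += 0.05 * rng.standard_normal(n)  # aspiration noise

    burst_len = int(0.010 * rate)
    trans_len = int(0.040 * rate)
    voiced = np.ones(n)
    voiced[:burst_len] = 0.0  # silence of the stop closure release
    src = src * voiced

    f2_track = np.full(n, f2)
    ramp = np.linspace(locus, f2, trans_len)
    f2_track[burst_len:burst_len + trans_len] = ramp[: max(0, n - burst_len)][:trans_len]

    out = _resonator_track(src, np.full(n, f1), 80.0, rate)
    out = out + _resonator_track(src, f2_track, 120.0, rate)

    burst = rng.standard_normal(burst_len)
    burst = _resonator_track(burst, np.full(burst_len, burst_hz), 600.0, rate)
    burst *= np.hanning(2 * burst_len)[burst_len:]
    out[:burst_len] += 2.0 * burst / max(1e-12, np.sqrt(np.mean(burst**2)))

    fade = int(0.015 * rate)
    out[-fade:] *= np.linspace(1, 0, fade)
    return rms_normalize(AudioStimulus(out, rate), 0.1)


# --------------------------------------------------------------------------
# Spherical-head forward model
# --------------------------------------------------------------------------


@dataclass
class LeadField:
    """Source-to-sensor gain matrix for fixed-orientation dipoles.

    ``gain`` is sources x channels in µV per nA·m; positions are metres in
    a head-centred frame (x right, y anterior, z superior), orientations
    are unit vectors (radial, the spherical stand-in for cortex-normal).
    """

    gain: np.ndarray
    source_positions: np.ndarray
    source_orientations: np.ndarray
    hemisphere_labels: np.ndarray  # "left" / "right" / "mid"
    roi_labels: np.ndarray  # "auditory" / "other"
    channel_labels: tuple[str, ...]
    head_radius_m: float = HEAD_RADIUS_M
    conductivity: float = 0.33

    @property
    def n_sources(self) -> int:
        return self.gain.shape[0]

    def roi_indices(self, hemisphere: str, roi: str = "auditory") -> np.ndarray:
        return np.flatnonzero(
            (self.hemisphere_labels == hemisphere) & (self.roi_labels == roi)
        )


def sphere_dipole_potential(
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
    electrode_dirs: np.ndarray,
    radius: float = HEAD_RADIUS_M,
    sigma: float = 0.33,
    n_terms: int = 120,
) -> np.ndarray:
    """Surface potential (V) of a current dipole in a homogeneous sphere.

    Legendre-series solution for a dipole (A·m) at ``dipole_pos`` (m, with
    |pos| < radius) observed at unit directions ``electrode_dirs`` on the
    sphere of ``radius`` with conductivity ``sigma`` (S/m):

        V = 1/(4 pi sigma R^2) * sum_n f^(n-1) (2n+1)/n
            [ n P_n(c) q_rad + sin(gamma) P'_n(c) q_tan ]

    where f is the fractional dipole eccentricity, c = cos(gamma) the angle
    between dipole and electrode, q_rad the moment component along the
    dipole position and q_tan the component toward the electrode.
    """
    b = float(np.linalg.norm(dipole_pos))
    if b >= radius:
        raise ValueError("source placed outside the sphere")
    e = np.asarray(electrode_dirs, float)
    e = e / np.linalg.norm(e, axis=1, keepdims=True)
    q = np.asarray(dipole_moment, float)

    if b < 1e-12:
        # central dipole: only the n=1 term survives
        return 3.0 * (e @ q) / (4 * np.pi * sigma * radius**2)

    rq = dipole_pos / b
    c = np.clip(e @ rq, -1.0, 1.0)
    s = np.sqrt(np.maximum(0.0, 1.0 - c * c))
    # tangential unit vector from the dipole toward each electrode
    tvec = e - c[:, None] * rq[None, :]
    tnorm = np.linalg.norm(tvec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tvec = np.where(tnorm[:, None] > 1e-12, tvec / np.maximum(tnorm, 1e-30)[:, None], 0.0)
    q_rad = float(q @ rq)
    q_tan = tvec @ q

    f = b / radius
    # Legendre P_n(c) and derivative P'_n(c) by recurrence
    p_nm1 = np.ones_like(c)  # P_0
    p_n = c.copy()  # P_1
    dp_n = np.ones_like(c)  # P'_1
    v = np.zeros_like(c)
    fpow = 1.0  # f^(n-1)
    for n in range(1, n_terms + 1):
        coef = fpow * (2 * n + 1) / n
        v += coef * (n * p_n * q_rad + s * dp_n * q_tan)
        # advance to P_{n+1}, P'_{n+1}
        p_np1 = ((2 * n + 1) * c * p_n - n * p_nm1) / (n + 1)
        dp_np1 = dp_n * c + (n + 1) * p_n
        p_nm1, p_n, dp_n = p_n, p_np1, dp_np1
        fpow *= f
    return v / (4 * np.pi * sigma * radius**2)


#: unit direction of the auditory patch centre (right hemisphere)
_AUDITORY_DIR = np.array([0.80, -0.12, 0.35])
_AUDITORY_DIR = _AUDITORY_DIR / np.linalg.norm(_AUDITORY_DIR)
#: midline parietal generator used for the P3b component
_PARIETAL_DIR = np.array([0.0, -0.55, 0.84])
_PARIETAL_DIR = _PARIETAL_DIR / np.linalg.norm(_PARIETAL_DIR)

SOURCE_RADIUS_M = 0.062  # uniform source depth (sphere eccentricity 0.69)


def make_lead_field(
    n_sources_per_hemisphere: int = 24,
    n_channels: int = 30,
    geometry_seed: int = 7,
    n_auditory: int = 6,
) -> LeadField:
    """Radial-dipole lead field on a homogeneous sphere, 10/20 electrodes.

    Sources sit on a shell of uniform depth; ``n_auditory`` sources per
    hemisphere form labelled "auditory" patches at mirrored temporal
    locations, the rest are mirrored pairs scattered over the upper shell,
    plus one midline parietal source.  Left/right patches are exactly
    mirror-symmetric about the mid-sagittal plane.
    """
    labels = SCALP_CHANNELS[:n_channels]
    if len(labels) != n_channels:
        raise ValueError("montage has fewer channels than requested")
    elec = montage_positions(labels)
    rng = np.random.default_rng(geometry_seed)

    def _patch(center: np.ndarray, n: int, spread: float) -> np.ndarray:
        dirs = center[None, :] + spread * rng.standard_normal((n, 3))
        dirs[0] = center
        return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)

    right_aud = _patch(_AUDITORY_DIR, n_auditory, 0.12)
    n_other = n_sources_per_hemisphere - n_auditory
    if n_other < 0:
        raise ValueError("n_auditory exceeds n_sources_per_hemisphere")
    other = rng.standard_normal((n_other, 3))
    other[:, 0] = np.abs(other[:, 0]) + 0.15  # keep clear of the midline
    other[:, 2] = np.abs(other[:, 2]) * 0.8 - 0.1
    other = other / np.linalg.norm(other, axis=1, keepdims=True)

    right_dirs = np.vstack([right_aud, other])
    left_dirs = right_dirs * np.array([-1.0, 1.0, 1.0])

    dirs = np.vstack([left_dirs, right_dirs, _PARIETAL_DIR[None, :]])
    positions = SOURCE_RADIUS_M * dirs
    # "cortex-normal" orientations: the supratemporal auditory plane faces
    # superiorly, so auditory sources get the tangential superior direction
    # (this is what makes the scalp N1 frontocentral-maximal); scattered
    # background sources and the parietal generator stay radial.
    orientations = dirs.copy()
    n_hemi = n_sources_per_hemisphere
    for s in list(range(n_auditory)) + list(range(n_hemi, n_hemi + n_auditory)):
        r = dirs[s]
        t = np.array([0.0, 0.0, 1.0]) - r[2] * r
        orientations[s] = t / np.linalg.norm(t)
    hemi = np.array(
        ["left"] * n_sources_per_hemisphere
        + ["right"] * n_sources_per_hemisphere
        + ["mid"]
    )
    roi = np.array(
        (["auditory"] * n_auditory + ["other"] * n_other) * 2 + ["other"]
    )

    gain = np.empty((len(positions), n_channels))
    for s in range(len(positions)):
        v = sphere_dipole_potential(
            positions[s], orientations[s] * 1e-9, elec * HEAD_RADIUS_M / HEAD_RADIUS_M
        )
        gain[s] = v * 1e6  # volts -> µV per nA·m
    if not np.all(np.isfinite(gain)):
        raise ValueError("non-finite lead field")
    return LeadField(gain, positions, orientations, hemi, roi, tuple(labels))


# --------------------------------------------------------------------------
# Ground truth and EEG simulation
# --------------------------------------------------------------------------

COMPONENT_WIDTHS_MS = {"n1": 40.0, "p2": 70.0, "p3b": 250.0}


@dataclass
class GroundTruth:
    """Everything the simulator injects, so recovery can be verified.

    ``components`` maps (ear, condition, component) to (scalp ROI amplitude
    µV, latency ms); ``hemisphere_gains`` maps ear to (left, right) source
    gain factors for the auditory patches; ``hit_probability`` maps (ear,
    deviant) to the true behavioural discriminability; ``rt_params`` maps
    ear to a shifted-lognormal (shift ms, mu, sigma).
    """

    components: dict[tuple[str, str, str], tuple[float, float]]
    hemisphere_gains: dict[str, tuple[float, float]]
    hit_probability: dict[tuple[str, str], float]
    rt_params: dict[str, tuple[float, float, float]]
    false_alarm_rate: float = 0.02
    noise_rms_uv: float = 8.0
    blink_rate_hz: float = 0.1
    blink_amplitude_uv: float = 120.0
    ci_artifact_uv: float = 40.0

    def validate(self) -> "GroundTruth":
        for (ear, cond, comp), (_, lat) in self.components.items():
            if comp not in COMPONENT_WIDTHS_MS:
                raise ValueError(f"unknown component {comp!r}")
        for p in self.hit_probability.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("hit probabilities must be in [0, 1]")
        return self


def default_ground_truth(
    ci_side: str = "left",
    proficient: bool = True,
    noise_rms_uv: float = 8.0,
    ci_artifact_uv: float = 40.0,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Study-typical ground truth for one simulated participant.

    Encodes the qualitative pattern the paradigm is built to detect: via
    the CI ear the N1 is smaller and ~20 ms later and the P2 smaller than
    via the NH ear; the P3b to the difficult deviant is large only in
    proficient users; auditory-cortex activity is stronger contralateral to
    the stimulated ear, with the asymmetry most pronounced for left-ear CI
    stimulation; responses are slower via the CI ear.

    With ``rng``, between-subject variability is drawn: amplitudes jitter
    by ~10%, latencies by a few ms, and the discriminability of the
    difficult deviant via the implant varies around the group mean with
    the P3b amplitude yoked to it (better discrimination, larger P3b) —
    the coupling the paradigm is designed to expose.
    """
    amp_j = (lambda: float(rng.normal(1.0, 0.10))) if rng is not None else (lambda: 1.0)
    lat_j = (lambda: float(rng.normal(0.0, 4.0))) if rng is not None else (lambda: 0.0)
    p2_mean = 0.70 if proficient else 0.20
    if rng is not None:
        p_dev2_ci = float(np.clip(rng.normal(p2_mean, 0.08), 0.05, 0.95))
    else:
        p_dev2_ci = p2_mean
    comps: dict[tuple[str, str, str], tuple[float, float]] = {}
    for ear in EARS:
        delay = 20.0 if ear == "CI" else 0.0
        shrink = 0.7 if ear == "CI" else 1.0
        n1_a, n1_l = -5.0 * shrink * amp_j(), 110.0 + delay + lat_j()
        p2_a, p2_l = 4.0 * shrink * amp_j(), 220.0 + delay / 2 + lat_j()
        for cond in STIMULUS_CODES:
            comps[(ear, cond, "n1")] = (n1_a, n1_l)
            comps[(ear, cond, "p2")] = (p2_a, p2_l)
        p3_d2 = 9.0 * p_dev2_ci  # discriminability drives the target P3b
        comps[(ear, "deviant1", "p3b")] = (6.0 * amp_j(), 550.0 + 2.5 * delay + lat_j())
        comps[(ear, "deviant2", "p3b")] = (
            (p3_d2 if ear == "CI" else 6.0 * amp_j()),
            580.0 + 2.5 * delay + lat_j(),
        )
    # contralateral dominance; left-side stimulation drives the asymmetry
    stim_side = {"CI": ci_side, "NH": ("right" if ci_side == "left" else "left")}
    gains = {}
    for ear in EARS:
        if stim_side[ear] == "left":
            gains[ear] = (1.0, 1.6)  # right auditory cortex dominant
        else:
            gains[ear] = (1.25, 1.05) if ear == "CI" else (1.5, 1.0)
    hits = {
        ("CI", "deviant1"): 0.91,
        ("NH", "deviant1"): 0.92,
        ("CI", "deviant2"): p_dev2_ci,
        ("NH", "deviant2"): 0.90,
    }
    rts = {"CI": (380.0, np.log(220.0), 0.35), "NH": (320.0, np.log(180.0), 0.35)}
    return GroundTruth(comps, gains, hits, rts, noise_rms_uv=noise_rms_uv,
                       ci_artifact_uv=ci_artifact_uv).validate()


def component_kernel(times_ms: np.ndarray, latency_ms: float, width_ms: float) -> np.ndarray:
    """Unit-peak half-cycle bump with compact support ``width_ms``."""
    tau = (times_ms - latency_ms) / width_ms
    out = np.where(np.abs(tau) <= 0.5, np.cos(np.pi * tau), 0.0)
    return out * np.exp(-0.5 * (tau / 0.5) ** 2)


def _one_over_f_noise(
    rng: np.random.Generator,
    n_ch: int,
    n_samp: int,
    rate: float,
    rms: float,
    mixing: np.ndarray | None = None,
) -> np.ndarray:
    """1/f-power background noise, optionally spatially mixed.

    ``mixing`` (channels x channels) imposes the inter-channel correlation
    of volume-conducted background activity; each output channel is scaled
    back to ``rms``.
    """
    freqs = np.fft.rfftfreq(n_samp, 1.0 / rate)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=1) * shape[None, :]
    noise = np.fft.irfft(spec, n=n_samp, axis=1)
    if mixing is not None:
        noise = mixing @ noise
    cur = np.sqrt(np.mean(noise**2, axis=1, keepdims=True))
    return noise / np.maximum(cur, 1e-30) * rms


def _spatial_mixing(labels: tuple[str, ...], length_rad: float = 0.8) -> np.ndarray:
    """Cholesky factor of a smooth angular-distance channel covariance."""
    pos = montage_positions(labels)
    ang = np.arccos(np.clip(pos @ pos.T, -1.0, 1.0))
    c = np.exp(-ang / length_rad) + 1e-6 * np.eye(len(labels))
    return np.linalg.cholesky(c)


def _angular_weights(labels: tuple[str, ...], center_dir: np.ndarray, scale: float) -> np.ndarray:
    pos = montage_positions(labels)
    c = pos @ (center_dir / np.linalg.norm(center_dir))
    ang = np.arccos(np.clip(c, -1, 1))
    return np.exp(-ang / scale)


def simulate_subject_eeg(
    seq: TrialSequence,
    truth: GroundTruth,
    lf: LeadField,
    ear: str,
    ci_side: str = "left",
    rate: float = 1000.0,
    seed: int = 0,
    frontocentral_roi: tuple[str, ...] = ("FCz", "FC1", "FC2", "Fz", "Cz"),
    parietal_roi: tuple[str, ...] = ("Pz", "P3", "P4", "CP1", "CP2"),
    stimulus_duration_ms: float = 300.0,
    pad_s: float = 2.0,
    include_eog: bool = True,
) -> Recording:
    """Continuous nose-referenced EEG for one subject and one stimulated ear.

    For each trial the N1/P2 (auditory patches, hemisphere-weighted) and
    P3b (midline parietal source, deviants only) kernels are projected
    through the lead field, scaled so that the noiseless scalp ROI mean
    peaks at the true amplitude.  1/f background noise, Poisson blinks and
    (for ear="CI") a stimulus-locked pedestal artifact over the
    implant-side temporal scalp are added, and stimulus events written.
    """
    if ear not in EARS:
        raise ValueError("ear must be 'CI' or 'NH'")
    min_width = min(COMPONENT_WIDTHS_MS.values())
    if rate < 4.0 * (1000.0 / min_width):
        raise ValueError("sampling rate below 4x the component bandwidth")
    truth.validate()
    for cond in set(seq.codes):
        if (ear, cond, "n1") not in truth.components:
            raise ValueError(f"ground truth missing condition {cond!r}")

    rng = np.random.default_rng(seed)
    labels = list(lf.channel_labels)
    n_ch = len(labels)
    pad = int(pad_s * rate)
    onsets = seq.onset_samples(rate) + pad
    n_samp = int(onsets[-1] + pad)
    data = np.zeros((n_ch, n_samp))

    # spatial patterns, normalized so the ROI mean of the pattern is 1
    gl, gr = truth.hemisphere_gains[ear]
    aud = gl * lf.gain[lf.roi_indices("left")].mean(axis=0) + gr * lf.gain[
        lf.roi_indices("right")
    ].mean(axis=0)
    fc_idx = [labels.index(c) for c in frontocentral_roi]
    pattern_aud = aud / aud[fc_idx].mean()
    par_src = np.flatnonzero(lf.hemisphere_labels == "mid")
    par = lf.gain[par_src].mean(axis=0) if len(par_src) else aud
    pz_idx = [labels.index(c) for c in parietal_roi]
    pattern_par = par / par[pz_idx].mean()

    # component kernels sampled once per (condition, component)
    span = int(1.2 * rate)  # kernels live within 1.2 s of onset
    ktimes = np.arange(span) / rate * 1000.0
    for cond in set(seq.codes):
        waves_aud = np.zeros(span)
        waves_par = np.zeros(span)
        for comp in COMPONENTS:
            key = (ear, cond, comp)
            if key not in truth.components:
                continue
            amp, lat = truth.components[key]
            if amp == 0.0:
                continue
            kern = amp * component_kernel(ktimes, lat, COMPONENT_WIDTHS_MS[comp])
            if comp == "p3b":
                waves_par += kern
            else:
                waves_aud += kern
        block = np.outer(pattern_aud, waves_aud) + np.outer(pattern_par, waves_par)
        for o in onsets[np.flatnonzero(np.array(seq.codes) == cond)]:
            stop = min(o + span, n_samp)
            data[:, o:stop] += block[:, : stop - o]

    if truth.noise_rms_uv > 0:
        data += _one_over_f_noise(
            rng, n_ch, n_samp, rate, truth.noise_rms_uv,
            mixing=_spatial_mixing(tuple(labels)),
        )

    # ocular artifacts: biphasic 300 ms blinks, frontal-dominant
    blink_w = _angular_weights(tuple(labels), np.array([0.0, 0.985, -0.08]), 0.45)
    blink_len = int(0.3 * rate)
    bt = np.arange(blink_len) / blink_len
    blink_kernel = np.sin(2 * np.pi * bt) * np.hanning(blink_len)
    n_blinks = rng.poisson(truth.blink_rate_hz * n_samp / rate)
    blink_starts = rng.integers(0, max(1, n_samp - blink_len), size=n_blinks)
    eog = np.zeros(n_samp)
    for b0 in blink_starts:
        seg = truth.blink_amplitude_uv * blink_kernel
        data[:, b0:b0 + blink_len] += np.outer(blink_w, seg)
        eog[b0:b0 + blink_len] += 1.5 * truth.blink_amplitude_uv * blink_kernel

    # stimulus-locked CI artifact on implant-side temporal channels
    if ear == "CI" and truth.ci_artifact_uv > 0:
        t_elec = "T7" if ci_side == "left" else "T8"
        ci_w = _angular_weights(tuple(labels), np.array(MONTAGE_1020[t_elec]), 0.4)
        ped_len = int(stimulus_duration_ms / 1000.0 * rate)
        ramp = int(0.005 * rate)
        pedestal = np.ones(ped_len)
        if ramp > 0:
            edge = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
            pedestal[:ramp] = edge
            pedestal[-ramp:] = edge[::-1]
        block = truth.ci_artifact_uv * np.outer(ci_w, pedestal)
        for o in onsets:
            stop = min(o + ped_len, n_samp)
            data[:, o:stop] += block[:, : stop - o]

    if include_eog:
        eog_noise = 0.3 * truth.noise_rms_uv * rng.standard_normal(n_samp)
        data = np.vstack([data, (eog + eog_noise)[None, :]])
        labels = labels + [EOG_CHANNEL]

    events = [(int(o), c) for o, c in zip(onsets, seq.codes)]
    return Recording(labels, rate, data, events, reference="nose").validate()


# --------------------------------------------------------------------------
# Behaviour
# --------------------------------------------------------------------------


def simulate_behavior(
    seq: TrialSequence,
    truth: GroundTruth,
    ear: str,
    seed: int = 0,
) -> list[tuple[int, float | None]]:
    """Per-trial button presses: (trial index, RT ms after onset) or None.

    Deviants are answered with the true hit probability, RT drawn from the
    ear's shifted lognormal truncated to [210, 1190] ms (inside the scoring
    window, so scored hit rates estimate the true probability).  Standards
    draw false alarms at the configured rate.
    """
    rng = np.random.default_rng(seed)
    shift, mu, sigma = truth.rt_params[ear]
    out: list[tuple[int, float | None]] = []
    for i, code in enumerate(seq.codes):
        if code == "standard":
            if rng.random() < truth.false_alarm_rate:
                out.append((i, float(rng.uniform(250, 1100))))
            else:
                out.append((i, None))
            continue
        if rng.random() < truth.hit_probability[(ear, code)]:
            rt = shift + float(rng.lognormal(mu, sigma))
            out.append((i, float(np.clip(rt, 210.0, 1190.0))))
        else:
            out.append((i, None))
    return out


# --------------------------------------------------------------------------
# Subject table (printed demographics of the 19 SSD CI users)
# --------------------------------------------------------------------------

_TABLE1_CSV = """\
id,age_years,handedness,ci_side,group,processor,etiology,duration_deafness_months,ci_use_months,pta_ci_db,pta_nh_db,freiburg_pct,olsa_quiet_pct,olsa_noise_db
vp03,51,right,right,non_proficient,CP910,Morbus meniere,19,24,32.5,19.75,75,96,-3.2
vp04,38,right,right,proficient,Opus,Sudden deafness,12,36,31.5,3.5,40,97,1.4
vp06,62,right,right,non_proficient,CP910,Cholesteatoma surgery,312,15,34.25,30,30,47,20.1
vp10,43,right,right,non_proficient,CP910,Sudden deafness,12,19,25.75,14.5,65,89,-0.7
vp11,63,right,right,proficient,CP910,Otitis media,18,12,34.25,14.75,10,23,
vp14,61,right,right,non_proficient,CP1000,Sudden deafness,7,11,24,15,65,90,-0.4
vp15,55,right,right,non_proficient,CP1000,Cogan 1 syndrome,3,10,22.5,10,95,99,-2.6
vp18,49,right,right,proficient,Sonnet,Otosclerosis,48,17,32.75,23.75,80,77,1.2
vp19,37,right,right,non_proficient,Sonnet,Unknown,26,19,38.5,29,30,91,-0.7
vp01,58,right,left,non_proficient,CP910,Sudden deafness,84,25,26,12,65,95,-0.7
vp02,56,left,left,proficient,CP910,Sudden deafness,30,12,36.5,4.25,10,7,
vp05,48,right,left,proficient,CP910,Sudden deafness,144,32,23.5,12,100,98,-1.1
vp07,55,right,left,non_proficient,CP910,Sudden deafness,432,20,43.5,8,55,64,4.3
vp08,53,left,left,proficient,CP910,Sudden deafness,5,32,33.75,15.75,50,79,2.4
vp09,57,right,left,non_proficient,CP910,Sudden deafness,21,10,31.25,11.5,55,92,-1.2
vp12,66,right,left,non_proficient,CP910,Unknown,120,15,29.5,30,70,94,0.5
vp13,63,right,left,proficient,CP1000,Stapes surgery,19,10,37,12.5,55,75,0.7
vp16,54,right,left,proficient,Sonnet,Acute hearing loss,10,14,28.75,16,80,100,-2.6
vp17,43,right,left,proficient,CP1000,Petrous bone fracture,2,11,22.5,6.25,55,78,6.1
"""


def make_subject_table_fixture() -> pd.DataFrame:
    """Demographics of the 19 SSD CI users, transcribed from print.

    One row per subject: age, handedness, implantation side, proficiency
    group, processor, etiology, months of deafness and of CI use, pure-tone
    averages for the CI and normal-hearing ear, and clinical speech scores.
    """
    tbl = pd.read_csv(io.StringIO(_TABLE1_CSV))
    if (tbl["age_years"] <= 0).any():
        raise ValueError("ages must be positive")
    if (tbl["pta_nh_db"] > 30).any():
        raise ValueError("included SSD subjects must have NH-ear PTA <= 30 dB")
    return tbl
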