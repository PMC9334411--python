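"""EEG conditioning chain for cochlear-implant oddball recordings.

Order of operations mirrors the acquisition pipeline: downsample to the
analysis rate, zero-phase Kaiser-window FIR band filtering (0.1-40 Hz),
epoching with baseline correction, amplitude-criterion rejection, a
two-stage ICA procedure that first strips the stimulus-locked electrical
CI artifact from the implant-ear data and then ocular/non-cerebral
components from the merged data, and spherical-spline interpolation of
channels removed over the implant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal
from sklearn.decomposition import FastICA

from .iohub import (
    EOG_CHANNEL,
    MONTAGE_1020,
    Recording,
    RunConfig,
    log,
    montage_positions,
)

# --------------------------------------------------------------------------
# FIR filtering
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FirFilterSpec:
    """Kaiser-window linear-phase FIR specification.

    beta = 5.653 corresponds to 60 dB stop-band attenuation with 0.001
    pass-band ripple; the -6 dB point of the designed filter sits at
    ``cutoff`` and the transition band spans ``transition_bw``.
    """

    kind: str  # "highpass" | "lowpass"
    cutoff: float
    transition_bw: float
    kaiser_beta: float = 5.653
    stopband_attenuation_db: float = 60.0
    passband_deviation: float = 0.001

    def validate(self) -> "FirFilterSpec":
        if self.kind not in ("highpass", "lowpass"):
            raise ValueError("kind must be 'highpass' or 'lowpass'")
        if self.cutoff <= 0 or self.transition_bw <= 0:
            raise ValueError("cutoff and transition_bw must be positive")
        return self


def design_fir(spec: FirFilterSpec, rate: float, max_taps: int = 200_001) -> np.ndarray:
    """Design the linear-phase (type I, odd-length) Kaiser FIR filter."""
    spec.validate()
    nyq = rate / 2.0
    if spec.cutoff + spec.transition_bw / 2 >= nyq:
        raise ValueError("cutoff plus transition does not fit below Nyquist")
    numtaps, _ = signal.kaiserord(
        spec.stopband_attenuation_db, spec.transition_bw / nyq
    )
    numtaps |= 1  # odd length -> integer group delay, type I
    if numtaps > max_taps:
        raise ValueError(
            f"transition too narrow at rate {rate}: needs {numtaps} taps"
        )
    taps = signal.firwin(
        numtaps,
        spec.cutoff,
        window=("kaiser", spec.kaiser_beta),
        pass_zero=(spec.kind == "lowpass"),
        fs=rate,
    )
    # pin the DC gain exactly (unit for lowpass, null for highpass); the
    # per-tap correction is ~1e-7 and invisible elsewhere in the response
    if spec.kind == "lowpass":
        taps /= taps.sum()
    else:
        taps -= taps.sum() / len(taps)
    return taps


def filter_recording(rec: Recording, specs: list[FirFilterSpec]) -> Recording:
    """Apply FIR filters with group-delay compensation; events unchanged."""
    out = rec.copy()
    for spec in specs:
        taps = design_fir(spec, rec.sampling_rate)
        if out.n_samples < 3 * len(taps):
            raise ValueError(
                f"recording of {out.n_samples} samples too short for a "
                f"{len(taps)}-tap filter (need 3x)"
            )
        # 'same' keeps the center of the odd-length kernel aligned: zero delay
        out.data = signal.fftconvolve(out.data, taps[None, :], mode="same", axes=1)
    return out.validate()


def resample(rec: Recording, new_rate: float) -> Recording:
    """Polyphase anti-aliased resampling; event indices rescaled."""
    if new_rate <= 0:
        raise ValueError("new_rate must be positive")
    if new_rate > rec.sampling_rate:
        raise ValueError("upsampling not supported in this pipeline")
    frac = Fraction(new_rate / rec.sampling_rate).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    ratio = new_rate / rec.sampling_rate
    events = [
        (int(np.rint(s * ratio)), code)  # round half to even
        for s, code in rec.events
    ]
    events = [(min(s, data.shape[1] - 1), c) for s, c in events]
    return Recording(list(rec.channel_labels), new_rate, data, events, rec.reference).validate()


# --------------------------------------------------------------------------
# Epoching
# --------------------------------------------------------------------------


@dataclass
class Epochs:
    """Trials x channels x samples around stimulus onset, in µV.

    ``times_ms`` is relative to onset; the sample window is half-open
    [onset + tmin, onset + tmax).  ``kept`` marks trials that survived
    rejection; nothing is ever deleted in place.
    """

    data: np.ndarray
    times_ms: np.ndarray
    window_ms: tuple[float, float]
    baseline_ms: tuple[float, float]
    conditions: np.ndarray
    channel_labels: list[str]
    sampling_rate: float
    kept: np.ndarray = field(default=None)  # type: ignore[assignment]
    trial_indices: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject: str = ""
    ear: str = ""

    def __post_init__(self) -> None:
        if self.kept is None:
            self.kept = np.ones(len(self.data), bool)
        if self.trial_indices is None:
            self.trial_indices = np.arange(len(self.data))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def pick(self, labels: list[str]) -> np.ndarray:
        idx = [self.channel_labels.index(c) for c in labels]
        return self.data[:, idx, :]


def epoch_and_baseline(
    rec: Recording,
    window_ms: tuple[float, float] = (-100.0, 400.0),
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
    codes: tuple[str, ...] = ("standard", "deviant1", "deviant2"),
) -> Epochs:
    """Cut stimulus-locked epochs and subtract the per-trial baseline mean.

    Events whose window does not fit inside the recording are dropped with
    a warning.  Baseline samples are the half-open interval
    [baseline_ms[0], baseline_ms[1]).
    """
    rate = rec.sampling_rate
    lo = int(round(window_ms[0] / 1000.0 * rate))
    hi = int(round(window_ms[1] / 1000.0 * rate))
    if not (baseline_ms[0] >= window_ms[0] and baseline_ms[1] <= window_ms[1]):
        raise ValueError("baseline must lie inside the epoch window")
    sel = [(i, s, c) for i, (s, c) in enumerate(rec.events) if c in codes]
    trials, conds, tidx = [], [], []
    for i, s, c in sel:
        if s + lo < 0 or s + hi > rec.n_samples:
            log.warning("dropping event %d (%s): too close to recording edge", i, c)
            continue
        trials.append(rec.data[:, s + lo:s + hi])
        conds.append(c)
        tidx.append(i)
    if not trials:
        raise ValueError("no epochable events")
    data = np.stack(trials)
    times = (np.arange(lo, hi) / rate) * 1000.0
    bmask = (times >= baseline_ms[0]) & (times < baseline_ms[1])
    data = data - data[:, :, bmask].mean(axis=2, keepdims=True)
    return Epochs(
        data,
        times,
        window_ms,
        baseline_ms,
        np.array(conds),
        list(rec.channel_labels),
        rate,
        trial_indices=np.array(tidx),
    )


# --------------------------------------------------------------------------
# Amplitude-criterion rejection
# --------------------------------------------------------------------------


def reject_by_amplitude(segments: np.ndarray, n_sd: float = 4.0) -> np.ndarray:
    """Kept mask for segments (trials x channels x samples).

    The SD is computed per channel over the samples of *all* segments; a
    segment is rejected when any channel's peak absolute amplitude exceeds
    ``n_sd`` times that channel's SD.
    """
    if segments.shape[0] < 2:
        raise ValueError("need at least 2 segments")
    sd = segments.std(axis=(0, 2))
    peaks = np.abs(segments).max(axis=2)  # trials x channels
    kept = ~(peaks > n_sd * sd[None, :]).any(axis=1)
    if not kept.any():
        raise ValueError("amplitude criterion rejected every segment")
    return kept


def cut_dummy_segments(data: np.ndarray, rate: float, length_s: float = 2.0) -> np.ndarray:
    """Non-overlapping dummy segments (segments x channels x samples)."""
    n = int(length_s * rate)
    n_seg = data.shape[1] // n
    return data[:, : n_seg * n].reshape(data.shape[0], n_seg, n).transpose(1, 0, 2)


# --------------------------------------------------------------------------
# ICA
# --------------------------------------------------------------------------


@dataclass
class IcaDecomposition:
    """Linear unmixing of channel data into components.

    ``unmixing`` is components x channels applied to mean-centred data;
    ``mixing`` maps component activations back to channels.  Components are
    ordered by explained channel variance.
    """

    unmixing: np.ndarray
    mixing: np.ndarray
    mean: np.ndarray
    channel_labels: list[str]
    seed: int
    component_scores: dict[str, np.ndarray] = field(default_factory=dict)
    removed: set[int] = field(default_factory=set)

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def sources(self, data: np.ndarray) -> np.ndarray:
        return self.unmixing @ (data - self.mean[:, None])

    def remove_components(self, data: np.ndarray, components: set[int]) -> np.ndarray:
        """Reconstruct channel data with the given components zeroed."""
        s = self.sources(data)
        keep = [k for k in range(self.n_components) if k not in components]
        return self.mixing[:, keep] @ s[keep] + self.mean[:, None]


def run_ica(
    data: np.ndarray | Epochs,
    seed: int = 97,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> IcaDecomposition:
    """Fit a FastICA decomposition, deterministic given the seed.

    ``data`` is channels x samples, or :class:`Epochs` (kept trials are
    concatenated along time).  The component count equals the numeric rank
    of the channel dimension; components are sorted by explained variance.
    """
    if isinstance(data, Epochs):
        labels = list(data.channel_labels)
        x = data.data[data.kept].transpose(1, 0, 2).reshape(len(labels), -1)
    else:
        labels = [f"ch{i}" for i in range(data.shape[0])]
        x = np.asarray(data, float)
    n_ch, n_samp = x.shape
    if n_samp <= 20 * n_ch**2:
        raise ValueError(
            f"need more than {20 * n_ch**2} samples for {n_ch} channels"
        )
    mean = x.mean(axis=1)
    xc = x - mean[:, None]
    sv = np.linalg.svd(xc, compute_uv=False)
    rank = int(np.sum(sv > sv[0] * max(n_ch, n_samp) * np.finfo(float).eps * 10))
    ica = FastICA(
        n_components=rank,
        whiten="unit-variance",
        random_state=seed,
        max_iter=max_iter,
        tol=tol,
    )
    s = ica.fit_transform(xc.T).T  # components x samples, unit variance
    mixing = ica.mixing_  # channels x components
    unmixing = ica.components_
    order = np.argsort(-np.sum(mixing**2, axis=0))
    return IcaDecomposition(
        unmixing[order], mixing[:, order], mean, labels, seed
    )


def _nearest_channels(labels: list[str], target: str, k: int = 3) -> list[int]:
    pos = montage_positions([c for c in labels if c in MONTAGE_1020])
    scalp = [c for c in labels if c in MONTAGE_1020]
    t = np.array(MONTAGE_1020[target])
    d = np.linalg.norm(pos - t[None, :], axis=1)
    near = [scalp[i] for i in np.argsort(d)[:k]]
    return [labels.index(c) for c in near]


def stimulus_boxcar(n_samples: int, rate: float, onsets: np.ndarray, duration_ms: float) -> np.ndarray:
    box = np.zeros(n_samples)
    span = int(duration_ms / 1000.0 * rate)
    for o in onsets:
        box[o:min(o + span, n_samples)] = 1.0
    return box


def score_artifact_components(
    ica: IcaDecomposition,
    data: np.ndarray,
    *,
    stim_onsets: np.ndarray | None = None,
    rate: float | None = None,
    stimulus_duration_ms: float = 300.0,
    implant_side: str | None = None,
    eog: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Score every component for CI-artifact and ocular likeness, in [0, 1].

    ci_artifact_score = |corr(activation, stimulus-on boxcar)| times the
    fraction of squared topography weight on the 3 electrodes nearest the
    implant-side temporal site.  ocular_score = |corr(activation, EOG)|.
    """
    s = ica.sources(data)
    scores: dict[str, np.ndarray] = {}
    if stim_onsets is not None:
        if rate is None or implant_side is None:
            raise ValueError("CI scoring needs rate and implant_side")
        box = stimulus_boxcar(data.shape[1], rate, stim_onsets, stimulus_duration_ms)
        t_elec = "T7" if implant_side == "left" else "T8"
        near = _nearest_channels(ica.channel_labels, t_elec)
        w2 = ica.mixing**2
        concentration = w2[near].sum(axis=0) / np.maximum(w2.sum(axis=0), 1e-30)
        temporal = np.abs(_safe_corr(s, box))
        scores["ci_artifact_score"] = temporal * concentration
    if eog is not None:
        scores["ocular_score"] = np.abs(_safe_corr(s, eog))
    elif stim_onsets is None:
        log.warning("no EOG reference available: ocular_score undefined")
    ica.component_scores.update(scores)
    return scores


def _safe_corr(components: np.ndarray, reference: np.ndarray) -> np.ndarray:
    c = components - components.mean(axis=1, keepdims=True)
    r = reference - reference.mean()
    denom = np.linalg.norm(c, axis=1) * np.linalg.norm(r)
    return (c @ r) / np.maximum(denom, 1e-30)


# --------------------------------------------------------------------------
# Spherical-spline channel interpolation
# --------------------------------------------------------------------------


def _perrin_g(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    """Perrin spline kernel g(cos) = 1/4pi sum (2n+1)/(n(n+1))^m P_n."""
    x = np.clip(cosang, -1.0, 1.0)
    p_nm1 = np.ones_like(x)
    p_n = x.copy()
    out = np.zeros_like(x)
    for n in range(1, n_terms + 1):
        out += (2 * n + 1) / (n * (n + 1.0)) ** m * p_n
        p_np1 = ((2 * n + 1) * x * p_n - n * p_nm1) / (n + 1)
        p_nm1, p_n = p_n, p_np1
    return out / (4 * np.pi)


def interpolate_channels(
    ep: Epochs,
    missing: list[str],
    reg: float = 1e-5,
    m: int = 4,
    n_terms: int = 50,
) -> Epochs:
    """Perrin spherical-spline reconstruction of missing scalp channels."""
    if not missing:
        return ep
    for c in missing:
        if c not in ep.channel_labels:
            raise KeyError(f"channel {c!r} not in the epochs")
        if c not in MONTAGE_1020:
            raise KeyError(f"channel {c!r} has no montage position")
    good = [c for c in ep.channel_labels if c in MONTAGE_1020 and c not in missing]
    if len(good) < 4:
        raise ValueError("need at least 4 good scalp channels")
    mat = _interp_matrix_data(
        montage_positions(good), montage_positions(missing), reg, m, n_terms
    )
    out = Epochs(
        ep.data.copy(), ep.times_ms, ep.window_ms, ep.baseline_ms, ep.conditions,
        list(ep.channel_labels), ep.sampling_rate, ep.kept.copy(),
        ep.trial_indices.copy(), ep.subject, ep.ear,
    )
    gidx = [ep.channel_labels.index(c) for c in good]
    bidx = [ep.channel_labels.index(c) for c in missing]
    gdata = out.data[:, gidx, :]
    out.data[:, bidx, :] = np.einsum("bg,tgs->tbs", mat, gdata)
    return out


def interpolation_matrix(
    good_labels: list[str],
    bad_labels: list[str],
    reg: float = 1e-5,
    m: int = 4,
    n_terms: int = 50,
) -> np.ndarray:
    """Linear map (n_bad x n_good) from good-channel data to bad sites."""
    return _interp_matrix_data(
        montage_positions(good_labels), montage_positions(bad_labels), reg, m, n_terms
    )


def _interp_matrix_data(
    good_pos: np.ndarray, bad_pos: np.ndarray, reg: float, m: int, n_terms: int
) -> np.ndarray:
    """Dense data-to-data interpolation operator for the Perrin spline.

    Solves [[G + reg I, 1], [1^T, 0]] [c; d] = [v; 0] for the spline
    coefficients of the good-channel values v, then evaluates
    v_bad = G_bg c + d.  Applying the solve to unit vectors yields the
    linear operator directly.
    """
    ng = len(good_pos)
    g_gg = _perrin_g(good_pos @ good_pos.T, m, n_terms) + reg * np.eye(ng)
    g_bg = _perrin_g(bad_pos @ good_pos.T, m, n_terms)
    a = np.zeros((ng + 1, ng + 1))
    a[:ng, :ng] = g_gg
    a[:ng, ng] = 1.0
    a[ng, :ng] = 1.0
    inv_cols = np.linalg.solve(a, np.vstack([np.eye(ng), np.zeros((1, ng))]))
    coeffs = inv_cols[:ng]  # ng x ng: data -> spline coefficients
    const = inv_cols[ng]  # data -> constant term
    return g_bg @ coeffs + const[None, :]


# --------------------------------------------------------------------------
# Two-stage artifact cleaning
# --------------------------------------------------------------------------


@dataclass
class CleaningReport:
    stage1_removed: list[int]
    stage1_scores: np.ndarray
    segments_total: int
    segments_rejected: int
    stage2_removed: list[int]
    stage2_scores: np.ndarray
    interpolated: list[str]

    def summary(self) -> str:
        return (
            f"stage1 CI components removed: {self.stage1_removed}; "
            f"dummy segments rejected: {self.segments_rejected}/{self.segments_total}; "
            f"stage2 ocular components removed: {self.stage2_removed}; "
            f"interpolated: {self.interpolated}"
        )


def two_stage_clean(
    ci_rec: Recording,
    nh_rec: Recording,
    config: RunConfig,
    ci_side: str = "left",
    missing_channels: list[str] | None = None,
) -> tuple[Epochs, Epochs, CleaningReport]:
    """The full two-stage ICA artifact procedure; returns cleaned epochs.

    Stage 1 fits an ICA on the epoched CI-ear data, scores components
    against the stimulus-on boxcar and implant-side topography, and removes
    CI-artifact components from the *continuous* CI-ear data.  The cleaned
    CI data and the NH data are then merged, cut into 2 s dummy segments,
    thresholded at ``config.reject_sd`` SDs, and a second ICA removes
    ocular components.  Finally the data are split back per ear, epoched,
    baseline-corrected, and any channels removed over the implant are
    interpolated.  Inputs must already be at the analysis rate and
    band-filtered.
    """
    missing_channels = missing_channels or []
    scalp = [c for c in ci_rec.channel_labels if c in MONTAGE_1020 and c not in missing_channels]
    has_eog = EOG_CHANNEL in ci_rec.channel_labels

    # --- stage 1: CI-artifact ICA on the implant-ear data
    ep_ci = epoch_and_baseline(ci_rec, config.epoch_window_ms, config.baseline_ms)
    ep_ci_scalp = Epochs(
        ep_ci.pick(scalp), ep_ci.times_ms, ep_ci.window_ms, ep_ci.baseline_ms,
        ep_ci.conditions, scalp, ep_ci.sampling_rate,
    )
    ica1 = run_ica(ep_ci_scalp, seed=config.ica_seed)
    ci_cont = np.array(ci_rec.pick(scalp))
    onsets = np.array([s for s, c in ci_rec.events if c != "response"])
    scores1 = score_artifact_components(
        ica1,
        ci_cont,
        stim_onsets=onsets,
        rate=ci_rec.sampling_rate,
        stimulus_duration_ms=config.stimulus_duration_ms,
        implant_side=ci_side,
    )["ci_artifact_score"]
    removed1 = {int(k) for k in np.flatnonzero(scores1 > config.ci_artifact_threshold)}
    ica1.removed = removed1
    ci_clean = ica1.remove_components(ci_cont, removed1)
    log.info("stage 1: removed %d CI-artifact components %s", len(removed1), sorted(removed1))

    # --- stage 2: merge, dummy segments, reject, ocular ICA
    nh_cont = np.array(nh_rec.pick(scalp))
    merged = np.concatenate([ci_clean, nh_cont], axis=1)
    eog_merged = None
    if has_eog:
        eog_merged = np.concatenate(
            [ci_rec.pick([EOG_CHANNEL])[0], nh_rec.pick([EOG_CHANNEL])[0]]
        )
    segs = cut_dummy_segments(merged, ci_rec.sampling_rate, 2.0)
    kept = reject_by_amplitude(segs, config.reject_sd)
    seg_data = segs[kept].transpose(1, 0, 2).reshape(len(scalp), -1)
    ica2 = run_ica(seg_data, seed=config.ica_seed + 1)
    if eog_merged is not None:
        eog_segs = cut_dummy_segments(eog_merged[None, :], ci_rec.sampling_rate, 2.0)
        eog_ref = eog_segs[kept][:, 0, :].reshape(-1)
        scores2 = score_artifact_components(ica2, seg_data, eog=eog_ref)["ocular_score"]
    else:
        frontal = [c for c in ("Fp1", "Fp2") if c in scalp]
        ref = np.array([merged[scalp.index(c)] for c in frontal]).mean(axis=0)
        ref_segs = cut_dummy_segments(ref[None, :], ci_rec.sampling_rate, 2.0)
        scores2 = score_artifact_components(
            ica2, seg_data, eog=ref_segs[kept][:, 0, :].reshape(-1)
        )["ocular_score"]
    removed2 = {int(k) for k in np.flatnonzero(scores2 > config.ocular_threshold)}
    ica2.removed = removed2
    cleaned_merged = ica2.remove_components(merged, removed2)
    log.info("stage 2: removed %d ocular components %s", len(removed2), sorted(removed2))

    # --- split back per ear, epoch, interpolate
    n_ci = ci_clean.shape[1]
    out_eps = []
    for rec, cont in ((ci_rec, cleaned_merged[:, :n_ci]), (nh_rec, cleaned_merged[:, n_ci:])):
        clean_rec = Recording(
            list(scalp), rec.sampling_rate, cont, list(rec.events), rec.reference
        )
        ep = epoch_and_baseline(clean_rec, config.epoch_window_ms, config.baseline_ms)
        ep.kept = reject_by_amplitude(ep.data, config.reject_sd)
        if missing_channels:
            full_labels = scalp + missing_channels
            filled = np.zeros((ep.n_trials, len(full_labels), ep.data.shape[2]))
            filled[:, : len(scalp)] = ep.data
            ep = Epochs(
                filled, ep.times_ms, ep.window_ms, ep.baseline_ms, ep.conditions,
                full_labels, ep.sampling_rate, ep.kept, ep.trial_indices,
            )
            ep = interpolate_channels(ep, missing_channels)
        out_eps.append(ep)

    report = CleaningReport(
        sorted(removed1), scores1, len(kept), int((~kept).sum()),
        sorted(removed2), scores2, list(missing_channels),
    )
    return out_eps[0], out_eps[1], report
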