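"""Minimum-norm inverse with dSPM noise normalization and ROI asymmetry.

The linear minimum-norm estimate W = R G' (G R G' + lambda^2 C)^-1 (fixed
dipole orientations, lambda^2 = 1/SNR^2, source covariance R a scaled
identity) is divided per source by the projected noise standard deviation
sqrt((W C W')_ss) — the dSPM statistic, dimensionless by construction.
Auditory-ROI time courses are means of absolute dSPM values; peak
magnitude and latency are read out in the N1 window per hemisphere, and
the asymmetry summarized as (right - left)/(right + left).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import Epochs
from .synthdata import LeadField


@dataclass
class NoiseCovariance:
    matrix: np.ndarray  # channels x channels, µV²
    n_samples: int
    window_ms: tuple[float, float]
    channel_labels: list[str]


def compute_noise_covariance(
    ep: Epochs,
    window_ms: tuple[float, float] = (-200.0, 0.0),
    shrinkage: float = 0.1,
) -> NoiseCovariance:
    """Empirical covariance of concatenated single-trial baselines.

    A shrinkage weight pulls the estimate toward its own diagonal, which
    keeps it positive definite when short baselines make it rank deficient.
    """
    mask = (ep.times_ms >= window_ms[0]) & (ep.times_ms < window_ms[1])
    if not mask.any():
        raise ValueError("epochs do not cover the covariance window")
    x = ep.data[ep.kept][:, :, mask]
    n_ch = x.shape[1]
    samples = x.transpose(1, 0, 2).reshape(n_ch, -1)
    if samples.shape[1] < n_ch + 1:
        raise ValueError("insufficient baseline samples for the covariance")
    samples = samples - samples.mean(axis=1, keepdims=True)
    c = samples @ samples.T / (samples.shape[1] - 1)
    c = (1.0 - shrinkage) * c + shrinkage * np.diag(np.diag(c))
    c = 0.5 * (c + c.T)
    return NoiseCovariance(c, samples.shape[1], window_ms, list(ep.channel_labels))


@dataclass
class InverseOperator:
    kernel: np.ndarray  # sources x channels
    lambda2: float
    source_scaling: float
    dspm_denominators: np.ndarray
    channel_labels: list[str]
    lead_field: LeadField


def _average_reference_gain(gain_src_by_ch: np.ndarray) -> np.ndarray:
    return gain_src_by_ch - gain_src_by_ch.mean(axis=1, keepdims=True)


def make_inverse(lf: LeadField, cov: NoiseCovariance, snr: float = 3.0) -> InverseOperator:
    """Regularized minimum-norm kernel with dSPM denominators.

    The gain matrix is re-referenced to the common average (matching the
    data contract of :func:`apply_dspm`); R = gamma I with gamma chosen so
    trace(G R G') = trace(lambda^2 C).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    order = [lf.channel_labels.index(c) for c in cov.channel_labels]
    g = _average_reference_gain(lf.gain[:, order]).T  # channels x sources
    lam2 = 1.0 / snr**2
    c = cov.matrix
    gamma = lam2 * np.trace(c) / np.trace(g @ g.T)
    gram = gamma * (g @ g.T) + lam2 * c
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("whitened Gram matrix is singular; regularize")
    kernel = gamma * g.T @ np.linalg.solve(gram, np.eye(len(c)))
    denom = np.sqrt(np.einsum("sc,cd,sd->s", kernel, c, kernel))
    if np.any(denom <= 0):
        raise np.linalg.LinAlgError("non-positive dSPM denominator")
    return InverseOperator(kernel, lam2, gamma, denom, list(cov.channel_labels), lf)


@dataclass
class SourceEstimate:
    values: np.ndarray  # sources x samples, absolute dSPM units
    times_ms: np.ndarray


def average_reference(data: np.ndarray) -> np.ndarray:
    return data - data.mean(axis=0, keepdims=True)


def apply_dspm(inv: InverseOperator, erp: np.ndarray, times_ms: np.ndarray) -> SourceEstimate:
    """Absolute dSPM values for an average-referenced sensor waveform.

    The average-reference contract is enforced: channel means must vanish
    at every sample.
    """
    scale = np.abs(erp).max() or 1.0
    if np.abs(erp.mean(axis=0)).max() > 1e-6 * scale:
        raise ValueError("input must be re-referenced to the common average")
    raw = inv.kernel @ erp
    return SourceEstimate(np.abs(raw) / inv.dspm_denominators[:, None], times_ms)


@dataclass
class RoiActivation:
    hemisphere: str
    peak_value: float
    peak_latency_ms: float
    timecourse: np.ndarray


def roi_activation(
    est: SourceEstimate,
    lf: LeadField,
    n1_window_ms: tuple[float, float] = (80.0, 160.0),
    roi: str = "auditory",
) -> tuple[RoiActivation, RoiActivation]:
    """Left and right ROI time courses with N1-window peaks.

    The ROI time course is the mean of absolute dSPM values over the ROI
    sources; exact ties in the peak scan resolve to the earlier latency.
    """
    out = []
    mask = (est.times_ms >= n1_window_ms[0]) & (est.times_ms <= n1_window_ms[1])
    if not mask.any():
        raise ValueError("N1 window outside the estimate support")
    for hemi in ("left", "right"):
        idx = lf.roi_indices(hemi, roi)
        if len(idx) == 0:
            raise KeyError(f"no {roi!r} sources in {hemi} hemisphere")
        tc = est.values[idx].mean(axis=0)
        seg = tc[mask]
        k = int(np.argmax(seg))
        out.append(
            RoiActivation(hemi, float(seg[k]), float(est.times_ms[mask][k]), tc)
        )
    return out[0], out[1]


def lateralization_index(left: RoiActivation, right: RoiActivation) -> float:
    """(right - left) / (right + left), in [-1, 1]."""
    l, r = left.peak_value, right.peak_value
    if l < 0 or r < 0:
        raise ValueError("peak values must be non-negative")
    if l + r == 0:
        raise ValueError("lateralization undefined: both peaks are zero")
    return (r - l) / (r + l)
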