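"""Subject and grand-average ERPs, ROI averaging, N1/P2/P3b peak measures.

Only correct trials enter the averages: hits for deviants and correct
rejections for standards.  Peaks are signed extrema inside the standard
latency bands (N1: 80-160 ms minimum; P2: 180-300 ms and P3b: 300-900 ms
maxima), ties and boundary peaks resolved toward the earlier latency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .preprocess import Epochs

ROI_DEFS = {
    "frontocentral": ("FCz", "FC1", "FC2", "Fz", "Cz"),
    "parietal": ("Pz", "P3", "P4", "CP1", "CP2"),
}

#: component -> (detector polarity, default window ms, measurement ROI)
COMPONENT_DEFS = {
    "N1": ("min", (80.0, 160.0), "frontocentral"),
    "P2": ("max", (180.0, 300.0), "frontocentral"),
    "P3b": ("max", (300.0, 900.0), "parietal"),
}


@dataclass
class PeakMeasure:
    component: str
    amplitude_uv: float
    latency_ms: float
    window_ms: tuple[float, float]
    roi: str
    n_trials: int = 0
    at_boundary: bool = False


def trial_correctness(
    conditions: np.ndarray,
    responses: list[tuple[int, float | None]],
    window_ms: tuple[float, float] = (200.0, 1200.0),
) -> np.ndarray:
    """Correct = hit for a deviant, correct rejection for a standard.

    ``responses`` holds (trial index, RT ms or None); a press counts as a
    hit inside the half-open window [window_ms[0], window_ms[1]).
    """
    rt = {i: r for i, r in responses}
    lo, hi = window_ms
    correct = np.zeros(len(conditions), bool)
    for i, cond in enumerate(conditions):
        r = rt.get(i)
        pressed = r is not None and lo <= r < hi
        correct[i] = pressed if cond != "standard" else r is None
    return correct


def subject_erp(
    ep: Epochs,
    condition: str,
    correct: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Average of kept, correct trials of one condition (channels x samples)."""
    sel = ep.kept & (ep.conditions == condition)
    if correct is not None:
        sel &= correct[ep.trial_indices]
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"no qualifying trials for condition {condition!r}")
    return ep.data[sel].mean(axis=0), n


def roi_average(erp: np.ndarray, channel_labels: list[str], roi_channels: tuple[str, ...]) -> np.ndarray:
    """Unweighted mean over the ROI channels."""
    try:
        idx = [channel_labels.index(c) for c in roi_channels]
    except ValueError as e:
        raise KeyError(f"ROI channel missing from data: {e}") from None
    return erp[idx].mean(axis=0)


def detect_peak(
    series: np.ndarray,
    times_ms: np.ndarray,
    component: str,
    window_ms: tuple[float, float] | None = None,
    roi: str | None = None,
    n_trials: int = 0,
) -> PeakMeasure:
    """Signed-extremum peak inside the component window.

    N1 takes the most negative sample, P2/P3b the most positive; exact
    ties resolve to the earlier latency (argmin/argmax convention).
    """
    if component not in COMPONENT_DEFS:
        raise ValueError(f"unknown component {component!r}")
    polarity, default_win, default_roi = COMPONENT_DEFS[component]
    lo, hi = window_ms or default_win
    mask = (times_ms >= lo) & (times_ms <= hi)
    if not mask.any():
        raise ValueError(f"window ({lo}, {hi}) ms outside the series support")
    seg = series[mask]
    t = times_ms[mask]
    k = int(np.argmin(seg) if polarity == "min" else np.argmax(seg))
    return PeakMeasure(
        component,
        float(seg[k]),
        float(t[k]),
        (lo, hi),
        roi or default_roi,
        n_trials,
        at_boundary=(k == 0 or k == len(seg) - 1),
    )


def grand_average(erps: list[np.ndarray], confidence: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted mean across subjects plus a per-sample t-based CI half-width."""
    shapes = {e.shape for e in erps}
    if len(shapes) != 1:
        raise ValueError("mismatched channel/time bases across subjects")
    stack = np.stack(erps)
    mean = stack.mean(axis=0)
    n = len(erps)
    if n < 2:
        return mean, np.zeros_like(mean)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = sps.t.ppf(0.5 + confidence / 2, df=n - 1)
    return mean, tcrit * sem


def smooth_for_plotting(series: np.ndarray, rate: float, cutoff_hz: float = 10.0) -> np.ndarray:
    """Low-pass for figures only; never used for measurement."""
    from scipy import signal

    sos = signal.butter(4, cutoff_hz / (rate / 2), output="sos")
    return signal.sosfiltfilt(sos, series)
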