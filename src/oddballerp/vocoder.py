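"""Four-band noise vocoder with Greenwood cochlear band spacing.

The vocoder degrades a syllable the way a cochlear implant degrades sound:
the signal is split into analysis bands whose boundaries are equally spaced
along the basilar membrane (Greenwood map), the temporal envelope of each
band is extracted by half-wave rectification and low-pass filtering, the
envelope modulates a noise carrier, and the modulated bands are summed.
All filters are Butterworth, applied forward-backward (zero phase).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .iohub import AudioStimulus


@dataclass(frozen=True)
class GreenwoodMap:
    """Greenwood frequency-position function F(x) = A (10^(a x) - k).

    Defaults are the standard human constants (A = 165.4 Hz, a = 0.06 /mm,
    k = 0.88) on a 35 mm basilar membrane, giving ~20.7 kHz at the base.
    """

    A: float = 165.4
    a: float = 0.06
    k: float = 0.88
    length_mm: float = 35.0

    def frequency(self, position_mm):
        """Characteristic frequency (Hz) at distance from the apex (mm)."""
        x = np.asarray(position_mm, float)
        if np.any(x < 0) or np.any(x > self.length_mm):
            raise ValueError("position outside [0, length_mm]")
        return self.A * (10.0 ** (self.a * x) - self.k)

    def position(self, frequency_hz):
        """Inverse map: distance from the apex (mm) for a frequency (Hz)."""
        f = np.asarray(frequency_hz, float)
        if np.any(f <= self.A * (1.0 - self.k) - 1e-12) or np.any(f <= -self.A * self.k):
            raise ValueError("frequency below the map's minimum")
        return np.log10(f / self.A + self.k) / self.a


@dataclass(frozen=True)
class VocoderSpec:
    """Noise-vocoder parameters.

    ``band_filter_order`` / ``envelope_filter_order`` are the orders of the
    designed Butterworth filters; each is applied forward-backward, which
    squares the magnitude response without adding delay.
    """

    n_bands: int = 4
    f_lo: float = 200.0
    f_hi: float = 20000.0
    band_filter_order: int = 12
    envelope_cutoff: float = 250.0
    envelope_filter_order: int = 4
    carrier: str = "noise"
    refilter_carrier: bool = True

    def validate(self, rate: float | None = None) -> "VocoderSpec":
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError("need 0 < f_lo < f_hi")
        if self.band_filter_order % 2 or self.band_filter_order <= 0:
            raise ValueError("band_filter_order must be even and positive")
        if self.envelope_filter_order % 2 or self.envelope_filter_order <= 0:
            raise ValueError("envelope_filter_order must be even and positive")
        if rate is not None:
            if self.f_hi > rate / 2:
                raise ValueError("f_hi exceeds Nyquist")
            if self.envelope_cutoff >= rate / 2:
                raise ValueError("envelope cutoff at or above Nyquist")
        return self


@dataclass(frozen=True)
class BandEdges:
    edges: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.edges) - 1


def compute_band_edges(gmap: GreenwoodMap, spec: VocoderSpec) -> BandEdges:
    """Band boundaries equally spaced in basilar-membrane millimetres."""
    spec.validate()
    x_lo = float(gmap.position(spec.f_lo))
    x_hi = float(gmap.position(spec.f_hi))
    positions = np.linspace(x_lo, x_hi, spec.n_bands + 1)
    edges = gmap.frequency(positions)
    edges[0], edges[-1] = spec.f_lo, spec.f_hi  # endpoint-exact
    if np.any(np.diff(edges) <= 0):
        raise ValueError("band edges not strictly increasing")
    return BandEdges(tuple(float(e) for e in edges))


def _band_sos(lo: float, hi: float, order: int, rate: float) -> np.ndarray:
    nyq = rate / 2
    hi = min(hi, 0.999 * nyq)  # keep the design stable at the Nyquist edge
    return signal.butter(order // 2, [lo / nyq, hi / nyq], btype="bandpass", output="sos")


def extract_envelope(band_signal: AudioStimulus, spec: VocoderSpec) -> AudioStimulus:
    """Half-wave rectify, zero-phase low-pass, clip residual ringing at 0."""
    spec.validate(rate=band_signal.rate)
    rectified = np.maximum(band_signal.samples, 0.0)
    sos = signal.butter(
        spec.envelope_filter_order // 2,
        spec.envelope_cutoff / (band_signal.rate / 2),
        btype="lowpass",
        output="sos",
    )
    env = signal.sosfiltfilt(sos, rectified)
    return AudioStimulus(np.maximum(env, 0.0), band_signal.rate)


def rms_normalize(stim: AudioStimulus, target_rms: float) -> AudioStimulus:
    """Scale the waveform so its RMS equals ``target_rms``."""
    rms = stim.rms
    if rms == 0.0:
        raise ValueError("cannot RMS-normalize an all-zero signal")
    return AudioStimulus(stim.samples * (target_rms / rms), stim.rate)


def vocode(
    stim: AudioStimulus,
    spec: VocoderSpec | None = None,
    gmap: GreenwoodMap | None = None,
    seed: int = 0,
) -> AudioStimulus:
    """Noise-vocode ``stim``; output duration and RMS match the input.

    Per band: zero-phase Butterworth band-pass, envelope extraction,
    multiplication by a unit-RMS Gaussian noise carrier (one independent
    seeded stream per band), band-limiting of the modulated carrier by the
    same band filter, then summation across bands.
    """
    spec = (spec or VocoderSpec()).validate(rate=stim.rate)
    gmap = gmap or GreenwoodMap()
    edges = compute_band_edges(gmap, spec).edges
    rng = np.random.default_rng(seed)

    x = stim.samples
    out = np.zeros_like(x, dtype=float)
    for b in range(spec.n_bands):
        sos = _band_sos(edges[b], edges[b + 1], spec.band_filter_order, stim.rate)
        band = signal.sosfiltfilt(sos, x)
        env = extract_envelope(AudioStimulus(band, stim.rate), spec).samples
        carrier = rng.standard_normal(len(x))
        modulated = env * carrier
        if spec.refilter_carrier:
            modulated = signal.sosfiltfilt(sos, modulated)
        out += modulated

    in_rms = stim.rms
    if in_rms == 0.0:
        return AudioStimulus(out * 0.0, stim.rate)
    return rms_normalize(AudioStimulus(out, stim.rate), in_rms)
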