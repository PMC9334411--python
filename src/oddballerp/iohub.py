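"""File formats, run configuration and logging for the oddball-ERP pipeline.

The pipeline reads and writes the BrainVision triplet (``.vhdr`` header,
``.eeg`` binary data, ``.vmrk`` markers) that BrainAmp-family amplifiers
produce, mono WAV audio for the syllable stimuli, and a declarative YAML
run configuration with explicit seeds for every stochastic stage.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.io import wavfile

log = logging.getLogger("oddballerp")


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    """Route package logs to stderr and optionally to a file."""
    log.setLevel(getattr(logging, level.upper()))
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(fmt)
    log.addHandler(h)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        log.addHandler(fh)


# --------------------------------------------------------------------------
# Electrode montage
#
# Idealized 30-channel extended 10/20 montage on the unit sphere, exactly
# mirror-symmetric about the mid-sagittal (x = 0) plane.  x points right,
# y anterior, z superior; scale by HEAD_RADIUS_M for metric positions.
# --------------------------------------------------------------------------

HEAD_RADIUS_M = 0.09

MONTAGE_1020: dict[str, tuple[float, float, float]] = {
    "Fp1": (-0.330448, +0.940563, -0.078393),
    "Fp2": (+0.330448, +0.940563, -0.078393),
    "F7": (-0.846853, +0.513504, -0.138398),
    "F3": (-0.601006, +0.632422, +0.488706),
    "Fz": (+0.000000, +0.660790, +0.750571),
    "F4": (+0.601006, +0.632422, +0.488706),
    "F8": (+0.846853, +0.513504, -0.138398),
    "FC5": (-0.929323, +0.228725, +0.289903),
    "FC1": (-0.380681, +0.290015, +0.878051),
    "FCz": (+0.000000, +0.295144, +0.955453),
    "FC2": (+0.380681, +0.290015, +0.878051),
    "FC6": (+0.929323, +0.228725, +0.289903),
    "T7": (-0.977754, -0.179321, -0.108821),
    "C3": (-0.713996, -0.121439, +0.689538),
    "Cz": (+0.000000, -0.091067, +0.995845),
    "C4": (+0.713996, -0.121439, +0.689538),
    "T8": (+0.977754, -0.179321, -0.108821),
    "CP5": (-0.825068, -0.469230, +0.314780),
    "CP1": (-0.339087, -0.433008, +0.835179),
    "CP2": (+0.339087, -0.433008, +0.835179),
    "CP6": (+0.825068, -0.469230, +0.314780),
    "P7": (-0.704397, -0.709389, -0.024338),
    "P3": (-0.489816, -0.709200, +0.507065),
    "Pz": (+0.000000, -0.700599, +0.713555),
    "P4": (+0.489816, -0.709200, +0.507065),
    "P8": (+0.704397, -0.709389, -0.024338),
    "POz": (+0.000000, -0.896108, +0.443836),
    "O1": (-0.254363, -0.964140, +0.075717),
    "Oz": (+0.000000, -0.991961, +0.126546),
    "O2": (+0.254363, -0.964140, +0.075717),
}

SCALP_CHANNELS: tuple[str, ...] = tuple(MONTAGE_1020)
EOG_CHANNEL = "EOG"  # electrode under the left eye; not on the scalp sphere

#: left/right mirror pairs of the montage (midline channels map to themselves)
MIRROR_PAIRS: dict[str, str] = {}
for _c in SCALP_CHANNELS:
    if _c[-1].isdigit():
        n = int(_c[-1])
        _m = _c[:-1] + str(n + 1 if n % 2 else n - 1)
        MIRROR_PAIRS[_c] = _m if _m in MONTAGE_1020 else _c
    else:
        MIRROR_PAIRS[_c] = _c
for _l, _r in [("F7", "F8"), ("T7", "T8"), ("P7", "P8")]:
    MIRROR_PAIRS[_l], MIRROR_PAIRS[_r] = _r, _l


def montage_positions(labels: Sequence[str]) -> np.ndarray:
    """Unit-sphere positions (n x 3) for scalp labels."""
    try:
        return np.array([MONTAGE_1020[c] for c in labels], float)
    except KeyError as e:  # pragma: no cover - defensive
        raise KeyError(f"channel {e} not in the 10/20 montage") from None


# --------------------------------------------------------------------------
# Event vocabulary
# --------------------------------------------------------------------------

#: closed vocabulary of event codes <-> BrainVision marker descriptions
EVENT_TO_MARKER = {
    "standard": ("Stimulus", "S 1"),
    "deviant1": ("Stimulus", "S 2"),
    "deviant2": ("Stimulus", "S 3"),
    "response": ("Response", "R 1"),
}
MARKER_TO_EVENT = {v[1]: k for k, v in EVENT_TO_MARKER.items()}
STIMULUS_CODES = ("standard", "deviant1", "deviant2")


# --------------------------------------------------------------------------
# Recording container
# --------------------------------------------------------------------------


@dataclass
class Recording:
    """Continuous multi-channel EEG in microvolts with event markers.

    ``data`` is channels x samples; ``events`` is an ordered list of
    ``(sample_index, code)`` with codes from the closed event vocabulary.
    """

    channel_labels: list[str]
    sampling_rate: float
    data: np.ndarray
    events: list[tuple[int, str]] = field(default_factory=list)
    reference: str = "nose"

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def validate(self) -> "Recording":
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data rows do not match channel labels")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        samples = [s for s, _ in self.events]
        if samples != sorted(samples):
            raise ValueError("events not sorted by sample index")
        if samples and (samples[0] < 0 or samples[-1] >= self.n_samples):
            raise ValueError("event sample index outside recording")
        for _, code in self.events:
            if code not in EVENT_TO_MARKER:
                raise ValueError(f"unknown event code {code!r}")
        return self

    def copy(self) -> "Recording":
        return Recording(
            list(self.channel_labels),
            self.sampling_rate,
            self.data.copy(),
            list(self.events),
            self.reference,
        )

    def pick(self, labels: Sequence[str]) -> np.ndarray:
        """Data rows for the given labels (view-copied)."""
        idx = [self.channel_labels.index(c) for c in labels]
        return self.data[idx]


# --------------------------------------------------------------------------
# BrainVision triplet
# --------------------------------------------------------------------------

_VHDR_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0
; Written by oddballerp

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_channels}
SamplingInterval={sampling_interval_us}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
{channel_lines}
"""

_VMRK_TEMPLATE = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
{marker_lines}
"""


def write_brainvision(rec: Recording, out_prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write ``rec`` as a BrainVision triplet; returns (vhdr, eeg, vmrk).

    Data are stored as multiplexed little-endian IEEE float32 in microvolts
    (resolution 1); markers carry the closed stimulus/response vocabulary.
    """
    rec.validate()
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    stem = prefix.name
    vhdr, eeg, vmrk = (prefix.with_suffix(s) for s in (".vhdr", ".eeg", ".vmrk"))

    ch_lines = "\n".join(
        f"Ch{i + 1}={label},,1,µV" for i, label in enumerate(rec.channel_labels)
    )
    vhdr.write_text(
        _VHDR_TEMPLATE.format(
            stem=stem,
            n_channels=rec.n_channels,
            sampling_interval_us=f"{1e6 / rec.sampling_rate:.6f}".rstrip("0").rstrip("."),
            channel_lines=ch_lines,
        ),
        encoding="utf-8",
    )

    rec.data.T.astype("<f4").tofile(eeg)

    # BrainVision marker positions are 1-based
    lines = [f"Mk1=New Segment,,1,1,0,00000000000000000000"]
    for k, (sample, code) in enumerate(rec.events, start=2):
        mtype, desc = EVENT_TO_MARKER[code]
        lines.append(f"Mk{k}={mtype},{desc},{sample + 1},1,0")
    vmrk.write_text(_VMRK_TEMPLATE.format(stem=stem, marker_lines="\n".join(lines)), encoding="utf-8")
    return vhdr, eeg, vmrk


def _parse_ini(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = sections.setdefault(line[1:-1], {})
        elif "=" in line:
            k, v = line.split("=", 1)
            current[k.strip()] = v.strip()
    return sections


def read_brainvision(header_path: str | Path) -> Recording:
    """Read a BrainVision triplet into a :class:`Recording` (µV)."""
    vhdr = Path(header_path)
    if not vhdr.exists():
        raise FileNotFoundError(vhdr)
    sec = _parse_ini(vhdr.read_text(encoding="utf-8"))
    common = sec.get("Common Infos", {})
    binary = sec.get("Binary Infos", {})
    if common.get("DataFormat", "BINARY") != "BINARY" or common.get(
        "DataOrientation", "MULTIPLEXED"
    ) != "MULTIPLEXED":
        raise ValueError("unsupported BrainVision dialect (need binary multiplexed)")
    if binary.get("BinaryFormat") != "IEEE_FLOAT_32":
        raise ValueError(
            f"unsupported binary encoding {binary.get('BinaryFormat')!r}"
        )
    n_channels = int(common["NumberOfChannels"])
    sfreq = 1e6 / float(common["SamplingInterval"])

    labels = []
    resolutions = []
    for i in range(n_channels):
        entry = sec["Channel Infos"][f"Ch{i + 1}"]
        parts = entry.split(",")
        labels.append(parts[0])
        resolutions.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)

    eeg_path = vhdr.parent / common["DataFile"]
    vmrk_path = vhdr.parent / common["MarkerFile"]
    if not eeg_path.exists() or not vmrk_path.exists():
        raise FileNotFoundError("missing BrainVision companion file")

    raw = np.fromfile(eeg_path, dtype="<f4")
    if raw.size % n_channels:
        raise ValueError("data file size inconsistent with channel count")
    data = raw.reshape(-1, n_channels).T.astype(np.float64)
    data *= np.asarray(resolutions)[:, None]

    events: list[tuple[int, str]] = []
    msec = _parse_ini(vmrk_path.read_text(encoding="utf-8")).get("Marker Infos", {})
    for key in sorted(msec, key=lambda k: int(k[2:])):
        fields = msec[key].split(",")
        mtype, desc = fields[0], fields[1]
        if mtype in ("Stimulus", "Response") and desc in MARKER_TO_EVENT:
            events.append((int(fields[2]) - 1, MARKER_TO_EVENT[desc]))
    events.sort(key=lambda e: e[0])
    return Recording(labels, sfreq, data, events, reference="nose").validate()


# --------------------------------------------------------------------------
# WAV audio
# --------------------------------------------------------------------------


@dataclass
class AudioStimulus:
    """Mono waveform with samples in [-1, 1]."""

    samples: np.ndarray
    rate: int

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))


def read_wav(path: str | Path) -> AudioStimulus:
    """Read a mono PCM/float WAV, mapping samples to [-1, 1] floats."""
    rate, raw = wavfile.read(path)
    if raw.ndim != 1:
        raise ValueError("multi-channel WAV not supported")
    if np.issubdtype(raw.dtype, np.integer):
        info = np.iinfo(raw.dtype)
        scale = float(max(abs(info.min), info.max))
        offset = 0.0
        if info.min == 0:  # unsigned PCM (e.g. uint8) is offset binary
            offset = (info.max + 1) / 2.0
            scale = offset
        samples = (raw.astype(np.float64) - offset) / scale
    else:
        samples = raw.astype(np.float64)
    return AudioStimulus(samples, int(rate))


def write_wav(stim: AudioStimulus, path: str | Path) -> Path:
    """Write a mono float32 WAV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    wavfile.write(path, stim.rate, stim.samples.astype(np.float32))
    return path


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Declarative parameters for a full pipeline run.

    Defaults reproduce the study conditions: 800-trial 80/10/10 oddball with
    1400 ms onset-to-onset interval, 1000 Hz acquisition downsampled to
    500 Hz, 0.1-40 Hz Kaiser FIR band, -100..400 ms sensor epochs (the
    source stage uses an extended -200..500 ms window), 4-SD rejection and
    the two-stage ICA chain.
    """

    # paradigm
    n_trials: int = 800
    probabilities: tuple[float, float, float] = (0.8, 0.1, 0.1)
    isi_ms: float = 1400.0
    min_preceding_standards: int = 3
    stimulus_duration_ms: float = 300.0
    # acquisition / preprocessing
    acquisition_rate: float = 1000.0
    analysis_rate: float = 500.0
    highpass_hz: float = 0.1
    highpass_transition_hz: float = 0.2
    lowpass_hz: float = 40.0
    lowpass_transition_hz: float = 2.0
    kaiser_beta: float = 5.653
    reject_sd: float = 4.0
    ica_seed: int = 97
    ci_artifact_threshold: float = 0.5
    ocular_threshold: float = 0.7
    # sensor analysis
    epoch_window_ms: tuple[float, float] = (-100.0, 400.0)
    baseline_ms: tuple[float, float] = (-100.0, 0.0)
    source_epoch_window_ms: tuple[float, float] = (-200.0, 500.0)
    frontocentral_roi: tuple[str, ...] = ("FCz", "FC1", "FC2", "Fz", "Cz")
    parietal_roi: tuple[str, ...] = ("Pz", "P3", "P4", "CP1", "CP2")
    n1_window_ms: tuple[float, float] = (80.0, 160.0)
    p2_window_ms: tuple[float, float] = (180.0, 300.0)
    p3b_window_ms: tuple[float, float] = (300.0, 900.0)
    # behavior
    response_window_ms: tuple[float, float] = (200.0, 1200.0)
    proficiency_threshold: float | None = None  # None -> median split
    # source analysis
    snr: float = 3.0
    noise_cov_window_ms: tuple[float, float] = (-200.0, 0.0)
    cov_shrinkage: float = 0.1
    # seeds
    seed: int = 0

    def validate(self) -> "RunConfig":
        if abs(sum(self.probabilities) - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")
        for lo, hi in (
            self.epoch_window_ms,
            self.baseline_ms,
            self.source_epoch_window_ms,
            self.n1_window_ms,
            self.p2_window_ms,
            self.p3b_window_ms,
            self.response_window_ms,
            self.noise_cov_window_ms,
        ):
            if not lo < hi:
                raise ValueError(f"window ({lo}, {hi}) must have start < end")
        if self.n_trials <= 0 or self.isi_ms <= 0:
            raise ValueError("n_trials and isi_ms must be positive")
        return self

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        }
        return cls(**kwargs).validate()
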