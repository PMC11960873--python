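"""Audio ingest, standardization, segmentation and log-Mel extraction.

The frontend turns labeled mono recordings into fixed-shape log-Mel
spectrograms: clips are resampled to 22 050 Hz, zero-padded to a 2-second
window, cut into 1-second segments with 50 % overlap, and each segment is
mapped to a 128-band log-Mel matrix (STFT window 1024 samples, hop 512,
centered frames -> 44 frames per second).
"""

from __future__ import annotations

import json
import wave
from dataclasses import dataclass, replace
from fractions import Fraction
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from .classes import CLASSES

__all__ = [
    "FrontendConfig",
    "AudioClip",
    "LogMelSpectrogram",
    "load_clip",
    "standardize_duration",
    "segment",
    "extract_logmel",
    "logmel_batch",
    "mel_filterbank",
    "mel_center_frequencies",
    "read_manifest",
    "write_manifest",
    "save_spectrogram",
    "load_spectrogram",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class FrontendConfig:
    """Feature-extraction parameters.

    Defaults follow the standard bioacoustic log-Mel recipe: 22 050 Hz sample
    rate, 2-s clip standardization, 1-s analysis segments with 50 % overlap,
    128 Mel bands from an STFT with a 1024-sample window and 50 % window
    overlap (hop 512).
    """

    sample_rate: int = 22050
    clip_duration: float = 2.0
    segment_duration: float = 1.0
    segment_overlap: float = 0.5
    n_mels: int = 128
    win_length: int = 1024
    hop_length: int = 512
    log_floor: float = 1e-10
    mel_scale: str = "slaney"  # or "htk"
    center: bool = True
    log_mode: str = "natural"  # or "db"

    def __post_init__(self) -> None:
        if min(self.sample_rate, self.n_mels, self.win_length, self.hop_length) <= 0:
            raise ValueError("sample_rate, n_mels, win_length, hop_length must be positive")
        if self.clip_duration <= 0 or self.segment_duration <= 0:
            raise ValueError("durations must be positive")
        if not 0 < self.segment_overlap < 1:
            raise ValueError("segment_overlap must be in (0, 1)")
        if self.hop_length != self.win_length // 2:
            raise ValueError("hop_length must equal win_length / 2 (50% window overlap)")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")
        if self.mel_scale not in ("slaney", "htk"):
            raise ValueError("mel_scale must be 'slaney' or 'htk'")
        if self.log_mode not in ("natural", "db"):
            raise ValueError("log_mode must be 'natural' or 'db'")

    @property
    def clip_samples(self) -> int:
        return int(round(self.clip_duration * self.sample_rate))

    @property
    def segment_samples(self) -> int:
        return int(round(self.segment_duration * self.sample_rate))

    @property
    def segment_hop(self) -> int:
        return int(round(self.segment_samples * (1.0 - self.segment_overlap)))

    @property
    def n_frames(self) -> int:
        """Frames per 1-s segment: 1 + floor(n_samples / hop) for centered framing."""
        if self.center:
            return 1 + self.segment_samples // self.hop_length
        return 1 + (self.segment_samples - self.win_length) // self.hop_length

    @property
    def floor_value(self) -> float:
        """Value a silent cell takes after log compression."""
        power_floor = self.log_floor**2
        if self.log_mode == "db":
            return 10.0 * np.log10(power_floor)
        return float(np.log(power_floor))

    def to_dict(self) -> dict:
        return {
            "sample_rate": self.sample_rate,
            "clip_duration": self.clip_duration,
            "segment_duration": self.segment_duration,
            "segment_overlap": self.segment_overlap,
            "n_mels": self.n_mels,
            "win_length": self.win_length,
            "hop_length": self.hop_length,
            "log_floor": self.log_floor,
            "mel_scale": self.mel_scale,
            "center": self.center,
            "log_mode": self.log_mode,
        }


# ---------------------------------------------------------------------------
# domain types


@dataclass
class AudioClip:
    """A labeled mono waveform.

    ``augmentation`` is ``None`` for original audio, or a
    ``(stretch_rate, semitones)`` descriptor for augmented variants.
    """

    samples: np.ndarray
    rate: int
    label: str | None = None
    source_id: str = ""
    augmentation: tuple[float, int] | None = None
    segment_index: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip samples must be mono (1-D)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioClip samples must be finite")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(f"label {self.label!r} not in class dictionary {CLASSES}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class LogMelSpectrogram:
    """A 128 x T log-Mel matrix with its extraction config and provenance."""

    values: np.ndarray
    config: FrontendConfig
    source_id: str = ""
    segment_index: int | None = None
    augmentation: tuple[float, int] | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[0] != self.config.n_mels:
            raise ValueError(
                f"spectrogram shape {self.values.shape} inconsistent with "
                f"n_mels={self.config.n_mels}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrogram values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# WAV ingest

_PCM_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31, np.dtype(np.uint8): None}


def _read_wav(path: Path) -> tuple[int, np.ndarray]:
    """Read a RIFF/WAV file to float64 in [-1, 1]; channels along axis 1."""
    try:
        rate, data = wavfile.read(path)
    except ValueError:
        # scipy does not decode 24-bit PCM; fall back to the stdlib reader.
        return _read_wav_24bit(path)
    data = np.asarray(data)
    if data.ndim == 1:
        data = data[:, np.newaxis]
    if data.dtype == np.uint8:
        out = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.int16, np.int32):
        out = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    else:
        out = data.astype(np.float64)
    return rate, out


def _read_wav_24bit(path: Path) -> tuple[int, np.ndarray]:
    with wave.open(str(path), "rb") as wf:
        if wf.getsampwidth() != 3:
            raise ValueError(f"unsupported WAV encoding in {path}")
        n_ch, rate, n_frames = wf.getnchannels(), wf.getframerate(), wf.getnframes()
        raw = wf.readframes(n_frames)
    b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3)
    vals = (
        b[:, 0].astype(np.int32)
        | (b[:, 1].astype(np.int32) << 8)
        | (b[:, 2].astype(np.int32) << 16)
    )
    vals = np.where(vals >= 2**23, vals - 2**24, vals)
    out = (vals / 2**23).reshape(-1, n_ch)
    return rate, out


def load_clip(
    path: str | Path,
    label: str | None = None,
    source_id: str | None = None,
    config: FrontendConfig = FrontendConfig(),
) -> AudioClip:
    """Load a WAV file as a mono, rate-standardized :class:`AudioClip`.

    Multichannel audio is channel-averaged; the result is polyphase-resampled
    to ``config.sample_rate`` and peak-limited to [-1, 1].
    """
    path = Path(path)
    if not path.is_file() or path.stat().st_size == 0:
        raise ValueError(f"unreadable or empty audio file: {path}")
    try:
        rate, data = _read_wav(path)
    except ValueError:
        raise
    except Exception as exc:  # malformed RIFF etc.
        raise ValueError(f"cannot parse WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"audio file has no samples: {path}")
    mono = data.mean(axis=1) if data.ndim == 2 else data
    if rate != config.sample_rate:
        frac = Fraction(config.sample_rate, int(rate))
        mono = resample_poly(mono, frac.numerator, frac.denominator)
    peak = np.max(np.abs(mono)) if mono.size else 0.0
    if peak > 1.0:
        mono = mono / peak
    return AudioClip(
        samples=mono.astype(np.float32),
        rate=config.sample_rate,
        label=label,
        source_id=source_id if source_id is not None else path.stem,
    )


# ---------------------------------------------------------------------------
# standardization and segmentation


def standardize_duration(clip: AudioClip, config: FrontendConfig = FrontendConfig()) -> AudioClip:
    """Zero-pad (trailing) clips shorter than the 2-s window; pass longer clips through.

    Long clips are handled downstream by the 1-s sliding window, so no audio
    is discarded.
    """
    target = config.clip_samples
    if len(clip) >= target:
        return clip
    padded = np.zeros(target, dtype=np.float32)
    padded[: len(clip)] = clip.samples
    return replace(clip, samples=padded)


def segment(clip: AudioClip, config: FrontendConfig = FrontendConfig()) -> list[AudioClip]:
    """Cut a clip into 1-s windows with 50 % overlap (hop 11 025 samples).

    Window starts are multiples of the hop; a final window is added (and
    zero-padded) only when samples would otherwise remain uncovered.
    """
    win, hop = config.segment_samples, config.segment_hop
    n = len(clip)
    assert n >= win, "segment() requires a clip of at least one segment duration"
    n_windows = 1 + int(np.ceil((n - win) / hop))
    out: list[AudioClip] = []
    for k in range(n_windows):
        start = k * hop
        chunk = clip.samples[start : start + win]
        if len(chunk) < win:
            chunk = np.concatenate([chunk, np.zeros(win - len(chunk), dtype=np.float32)])
        out.append(replace(clip, samples=chunk, segment_index=k))
    return out


# ---------------------------------------------------------------------------
# mel filterbank


def _hz_to_mel(f: np.ndarray, scale: str) -> np.ndarray:
    f = np.asarray(f, dtype=np.float64)
    if scale == "htk":
        return 2595.0 * np.log10(1.0 + f / 700.0)
    # Slaney: linear below 1 kHz, logarithmic above
    f_sp = 200.0 / 3.0
    mel = f / f_sp
    min_log_hz = 1000.0
    min_log_mel = min_log_hz / f_sp
    logstep = np.log(6.4) / 27.0
    above = f >= min_log_hz
    mel = np.where(above, min_log_mel + np.log(np.maximum(f, min_log_hz) / min_log_hz) / logstep, mel)
    return mel


def _mel_to_hz(m: np.ndarray, scale: str) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    if scale == "htk":
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    f_sp = 200.0 / 3.0
    hz = m * f_sp
    min_log_hz = 1000.0
    min_log_mel = min_log_hz / f_sp
    logstep = np.log(6.4) / 27.0
    above = m >= min_log_mel
    hz = np.where(above, min_log_hz * np.exp(logstep * (np.maximum(m, min_log_mel) - min_log_mel)), hz)
    return hz


def mel_center_frequencies(config: FrontendConfig = FrontendConfig()) -> np.ndarray:
    """Center frequency (Hz) of each of the ``n_mels`` triangular filters."""
    fmax = config.sample_rate / 2.0
    mels = np.linspace(
        _hz_to_mel(np.array(0.0), config.mel_scale),
        _hz_to_mel(np.array(fmax), config.mel_scale),
        config.n_mels + 2,
    )
    return _mel_to_hz(mels, config.mel_scale)[1:-1]


@lru_cache(maxsize=8)
def _mel_filterbank_cached(config: FrontendConfig) -> np.ndarray:
    return _mel_filterbank_build(config)


def mel_filterbank(config: FrontendConfig = FrontendConfig()) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, 1 + win_length // 2).

    Slaney variant is area-normalized (each filter scaled by 2 / bandwidth).
    """
    return _mel_filterbank_cached(config)


def _mel_filterbank_build(config: FrontendConfig) -> np.ndarray:
    n_fft = config.win_length
    fmax = config.sample_rate / 2.0
    fft_freqs = np.linspace(0.0, fmax, 1 + n_fft // 2)
    mels = np.linspace(
        _hz_to_mel(np.array(0.0), config.mel_scale),
        _hz_to_mel(np.array(fmax), config.mel_scale),
        config.n_mels + 2,
    )
    f_pts = _mel_to_hz(mels, config.mel_scale)
    fb = np.zeros((config.n_mels, len(fft_freqs)))
    for i in range(config.n_mels):
        lo, ctr, hi = f_pts[i], f_pts[i + 1], f_pts[i + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    if config.mel_scale == "slaney":
        enorm = 2.0 / (f_pts[2 : config.n_mels + 2] - f_pts[:config.n_mels])
        fb *= enorm[:, np.newaxis]
    return fb


# ---------------------------------------------------------------------------
# STFT framing and log-Mel extraction


def stft_magnitude(
    samples: np.ndarray,
    win_length: int,
    hop_length: int,
    center: bool = True,
    window: np.ndarray | None = None,
) -> np.ndarray:
    """Magnitude STFT, shape (1 + win//2, n_frames)."""
    x = np.asarray(samples, dtype=np.float64)
    if window is None:
        window = np.hanning(win_length + 1)[:-1]  # periodic Hann
    if center:
        x = np.pad(x, win_length // 2)
        n_frames = 1 + len(samples) // hop_length
    else:
        n_frames = 1 + (len(x) - win_length) // hop_length
    idx = np.arange(win_length)[np.newaxis, :] + hop_length * np.arange(n_frames)[:, np.newaxis]
    frames = x[idx] * window
    return np.abs(np.fft.rfft(frames, axis=1)).T


def logmel_batch(waves: np.ndarray, config: FrontendConfig = FrontendConfig()) -> np.ndarray:
    """Log-Mel features of a (B, segment_samples) batch -> (B, n_mels, n_frames)."""
    waves = np.asarray(waves, dtype=np.float64)
    if waves.ndim != 2 or waves.shape[1] != config.segment_samples:
        raise ValueError(
            f"expected batch of {config.segment_samples}-sample segments, got {waves.shape}"
        )
    win, hop = config.win_length, config.hop_length
    window = np.hanning(win + 1)[:-1]
    if config.center:
        x = np.pad(waves, ((0, 0), (win // 2, win // 2)))
        n_frames = 1 + waves.shape[1] // hop
    else:
        x = waves
        n_frames = 1 + (waves.shape[1] - win) // hop
    idx = np.arange(win)[np.newaxis, :] + hop * np.arange(n_frames)[:, np.newaxis]
    frames = x[:, idx] * window  # (B, frames, win)
    power = np.abs(np.fft.rfft(frames, axis=2)) ** 2
    mel_power = power @ mel_filterbank(config).T  # (B, frames, mels)
    floor = config.log_floor**2
    if config.log_mode == "db":
        values = 10.0 * np.log10(mel_power + floor)
    else:
        values = np.log(mel_power + floor)
    return values.transpose(0, 2, 1)


def extract_logmel(seg: AudioClip, config: FrontendConfig = FrontendConfig()) -> LogMelSpectrogram:
    """Log-Mel spectrogram of one 1-s segment; shape (n_mels, 44) with defaults.

    Power STFT -> 128 triangular mel filters spanning 0 to Nyquist -> log
    compression with an additive power floor so digital silence maps to a
    uniform finite value.
    """
    if len(seg) != config.segment_samples:
        raise ValueError(
            f"segment length {len(seg)} != required {config.segment_samples} samples"
        )
    values = logmel_batch(seg.samples[np.newaxis, :], config)[0]
    return LogMelSpectrogram(
        values=values,
        config=config,
        source_id=seg.source_id,
        segment_index=seg.segment_index,
        augmentation=seg.augmentation,
        label=seg.label,
    )


# ---------------------------------------------------------------------------
# manifests and spectrogram persistence


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a corpus manifest CSV with columns path, label, source_id."""
    df = pd.read_csv(path, dtype=str)
    missing = {"path", "label", "source_id"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def save_spectrogram(spec: LogMelSpectrogram, path: str | Path) -> None:
    """Write the matrix as .npy with a JSON sidecar holding config + provenance."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), spec.values)
    sidecar = {
        "config": spec.config.to_dict(),
        "source_id": spec.source_id,
        "segment_index": spec.segment_index,
        "augmentation": list(spec.augmentation) if spec.augmentation else None,
        "label": spec.label,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_spectrogram(path: str | Path) -> LogMelSpectrogram:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    aug = meta.get("augmentation")
    return LogMelSpectrogram(
        values=values,
        config=FrontendConfig(**meta["config"]),
        source_id=meta.get("source_id", ""),
        segment_index=meta.get("segment_index"),
        augmentation=tuple(aug) if aug else None,
        label=meta.get("label"),
    )
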