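"""Time-stretch / pitch-shift augmentation for training segments.

The augmentation grid crosses three stretch rates {0.8, 1.0, 1.2} with five
semitone shifts {-2, -1, 0, 1, 2}, giving 15 variants per 1-second segment.
Both transforms run through a phase vocoder: time stretching resamples the
STFT frame sequence while accumulating per-bin phase advances; pitch
shifting composes a stretch at rate 2^(-s/12) with resampling back to the
original length, scaling all frequencies by 2^(s/12).

All kernels are batched over a leading segment axis so corpus-scale
augmentation amortizes the FFT work; the per-segment operations are the
batch size-1 case of the same code path.

Augmentation is applied to training folds only; evaluation always uses
original audio.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.fft import next_fast_len
from scipy.signal import resample

from .audio import AudioClip

__all__ = ["AugmentationGrid", "time_stretch", "pitch_shift", "augment_segment",
           "augment_batch"]

_N_FFT = 2048
_HOP = 512


@dataclass(frozen=True)
class AugmentationGrid:
    """The stretch-rate x semitone-shift grid; identity pair (1.0, 0) required."""

    stretch_rates: tuple[float, ...] = (0.8, 1.0, 1.2)
    semitone_shifts: tuple[int, ...] = (-2, -1, 0, 1, 2)

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.stretch_rates):
            raise ValueError("stretch rates must be positive")
        if any(abs(s) > 12 for s in self.semitone_shifts):
            raise ValueError("semitone shifts must lie in [-12, 12]")
        if 1.0 not in self.stretch_rates or 0 not in self.semitone_shifts:
            raise ValueError("grid must contain the identity pair (1.0, 0)")

    @property
    def cardinality(self) -> int:
        return len(self.stretch_rates) * len(self.semitone_shifts)

    def pairs(self) -> list[tuple[float, int]]:
        """Rate-major, shift-minor enumeration of the grid."""
        return [(r, s) for r in self.stretch_rates for s in self.semitone_shifts]


# ---------------------------------------------------------------------------
# batched phase vocoder (leading axis = segments)


def _stft(X: np.ndarray) -> np.ndarray:
    """(B, n) -> complex (B, bins, frames), centered, Hann window."""
    window = np.hanning(_N_FFT + 1)[:-1].astype(np.float32)
    n = X.shape[1]
    Xp = np.pad(np.asarray(X, dtype=np.float32), ((0, 0), (_N_FFT // 2, _N_FFT // 2)))
    n_frames = 1 + n // _HOP
    idx = np.arange(_N_FFT)[np.newaxis, :] + _HOP * np.arange(n_frames)[:, np.newaxis]
    frames = Xp[:, idx] * window  # (B, frames, n_fft)
    return np.fft.rfft(frames, axis=2).transpose(0, 2, 1)


def _istft(S: np.ndarray, length: int) -> np.ndarray:
    """Inverse of :func:`_stft` by windowed overlap-add."""
    window = np.hanning(_N_FFT + 1)[:-1].astype(np.float32)
    frames = np.fft.irfft(S.transpose(0, 2, 1), n=_N_FFT, axis=2).astype(np.float32) * window
    b, n_frames, _ = frames.shape
    out = np.zeros((b, _N_FFT + _HOP * (n_frames - 1)), dtype=np.float32)
    norm = np.zeros(out.shape[1], dtype=np.float32)
    wsq = window**2
    for i in range(n_frames):
        out[:, i * _HOP : i * _HOP + _N_FFT] += frames[:, i]
        norm[i * _HOP : i * _HOP + _N_FFT] += wsq
    out = out / np.maximum(norm, 1e-8)
    out = out[:, _N_FFT // 2 :]
    if out.shape[1] >= length:
        return out[:, :length]
    return np.pad(out, ((0, 0), (0, length - out.shape[1])))


def _phase_vocoder(S: np.ndarray, rate: float) -> np.ndarray:
    """Resample the frame axis of (B, bins, frames) STFTs by ``rate``.

    Magnitudes are linearly interpolated between frames; phases accumulate
    the wrapped instantaneous-frequency deviation so partials stay coherent.
    """
    b, n_bins, n_frames = S.shape
    time_steps = np.arange(0, n_frames, rate)
    omega = (2.0 * np.pi * _HOP * np.arange(n_bins) / _N_FFT).astype(np.float32)
    S_pad = np.concatenate([S, np.zeros((b, n_bins, 2), dtype=S.dtype)], axis=2)
    mag = np.abs(S_pad).astype(np.float32)
    phase = np.angle(S_pad).astype(np.float32)

    idx = time_steps.astype(int)
    frac = time_steps - idx
    frac = frac.astype(np.float32)
    m = (1.0 - frac) * mag[:, :, idx] + frac * mag[:, :, idx + 1]

    dphi = phase[:, :, idx + 1] - phase[:, :, idx] - omega[:, np.newaxis]
    dphi -= np.float32(2.0 * np.pi) * np.round(dphi / np.float32(2.0 * np.pi))
    advances = omega[:, np.newaxis] + dphi
    # accumulate in float64: tens of wrapped radians per frame would lose
    # precision in float32 over long stretches
    phi = (phase[:, :, 0:1] + np.concatenate(
        [np.zeros((b, n_bins, 1)), np.cumsum(advances[:, :, :-1], dtype=np.float64, axis=2)],
        axis=2,
    )).astype(np.float32)
    return m * (np.cos(phi) + 1j * np.sin(phi))


def _stretch_batch(X: np.ndarray, rate: float) -> np.ndarray:
    out_len = int(round(X.shape[1] / rate))
    return _istft(_phase_vocoder(_stft(X), rate), length=out_len)


def _shift_batch(X: np.ndarray, semitones: int) -> np.ndarray:
    if semitones == 0:
        return X.copy()
    n = X.shape[1]
    # snap the intermediate length to an FFT-fast size; this perturbs the
    # pitch ratio by < 0.1 % (~2 cents), far below the semitone grid spacing
    m = next_fast_len(int(round(n * 2.0 ** (semitones / 12.0))))
    stretched = _stretch_batch(X, rate=n / m)
    return resample(stretched, n, axis=1)


# ---------------------------------------------------------------------------
# public operations


def time_stretch(seg: AudioClip, rate: float) -> AudioClip:
    """Phase-vocoder time stretch: duration scales by 1/rate, pitch preserved."""
    if rate <= 0:
        raise ValueError("stretch rate must be positive")
    y = _stretch_batch(seg.samples[np.newaxis, :], rate)[0]
    return replace(seg, samples=y.astype(np.float32), augmentation=(rate, 0))


def pitch_shift(seg: AudioClip, semitones: int) -> AudioClip:
    """Shift spectral content by 2^(s/12) while preserving duration."""
    if abs(semitones) > 12:
        raise ValueError("semitone shift must lie in [-12, 12]")
    y = _shift_batch(seg.samples[np.newaxis, :], semitones)[0]
    return replace(seg, samples=y.astype(np.float32), augmentation=(1.0, semitones))


def _refit(Y: np.ndarray, n: int) -> np.ndarray:
    """Trim or zero-pad the tail so every row has exactly n samples."""
    if Y.shape[1] >= n:
        return Y[:, :n]
    return np.pad(Y, ((0, 0), (0, n - Y.shape[1])))


def augment_batch(X: np.ndarray, grid: AugmentationGrid = AugmentationGrid()) -> dict[tuple[float, int], np.ndarray]:
    """All grid variants of a (B, n) segment batch, keyed by (rate, shift).

    Stretch first, refit to exactly n samples, then pitch-shift; every
    output array has the input shape.
    """
    n = X.shape[1]
    X = np.asarray(X, dtype=np.float32)
    out: dict[tuple[float, int], np.ndarray] = {}
    for rate in grid.stretch_rates:
        base = X if rate == 1.0 else _refit(_stretch_batch(X, rate), n)
        for s in grid.semitone_shifts:
            out[(rate, s)] = _shift_batch(base, s)
    return out


def augment_segment(seg: AudioClip, grid: AugmentationGrid = AugmentationGrid()) -> list[AudioClip]:
    """All grid variants of one 1-s segment, each refit to exactly 1 s.

    Variants are emitted rate-major, shift-minor, each carrying its
    (rate, shift) descriptor and the parent's label and source_id.
    """
    batch = augment_batch(seg.samples[np.newaxis, :], grid)
    return [
        replace(seg, samples=batch[(rate, s)][0].astype(np.float32), augmentation=(rate, s))
        for rate, s in grid.pairs()
    ]
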