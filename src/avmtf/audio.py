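"""Audio front-end: waveform -> T x 25 modulation-subband envelope features.

Pipeline (all causal):

1. resample to 16 kHz mono;
2. 31-channel gammatone filterbank (80-8000 Hz, ERB spacing);
3. Hilbert envelope per gammatone subband;
4. polyphase decimation of the envelopes to an intermediate 100 Hz rate;
5. 25-channel modulation filterbank (0.5-12.5 Hz), averaging each
   modulation subband across the 31 gammatone channels;
6. polyphase resampling to the 25 Hz video frame rate;
7. per-video standardization of every column to zero mean, unit variance.

Filtering and channel-averaging are both linear, so the average across
gammatone channels is taken before modulation filtering; the result is
identical to filtering each channel and averaging afterwards.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .filterbanks import GammatoneBank, ModulationFilterbank

__all__ = [
    "AudioWaveform",
    "EnvelopeFeatures",
    "load_audio",
    "gammatone_envelopes",
    "modulation_decompose",
    "normalize_features",
    "extract_envelope_features",
]

log = logging.getLogger(__name__)

TARGET_RATE = 16000
FRAME_RATE = 25.0


@dataclass
class AudioWaveform:
    samples: np.ndarray
    rate: float

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class EnvelopeFeatures:
    """Per-video T x 25 modulation-subband envelope features at 25 Hz."""

    values: np.ndarray
    center_freqs: np.ndarray
    video_id: str = ""
    frame_rate: float = FRAME_RATE


def _resample(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    frac = Fraction(rate_out / rate_in).limit_denominator(10_000)
    return signal.resample_poly(x, frac.numerator, frac.denominator)


def load_audio(path, target_rate: int = TARGET_RATE) -> AudioWaveform:
    """Read a WAV file, convert to mono floats and resample to 16 kHz."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.size == 0:
        raise ValueError(f"empty audio file: {path}")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    if data.ndim == 2:  # average channels to mono
        data = data.mean(axis=1)
    if rate != target_rate:
        data = _resample(data, rate, target_rate)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite samples in {path}")
    return AudioWaveform(samples=data, rate=float(target_rate))


def gammatone_envelopes(w: AudioWaveform, bank: GammatoneBank | None = None) -> np.ndarray:
    """Hilbert envelope in each gammatone subband -> (31, n) at 16 kHz."""
    bank = bank or GammatoneBank()
    if w.rate != bank.rate:
        raise ValueError(f"waveform rate {w.rate} != filterbank rate {bank.rate}")
    subbands = bank.filter(w.samples)
    return np.abs(signal.hilbert(subbands, axis=-1))


def modulation_decompose(
    envelopes: np.ndarray,
    mfb: ModulationFilterbank | None = None,
    env_rate: float = float(TARGET_RATE),
    frame_rate: float = FRAME_RATE,
) -> np.ndarray:
    """Envelope subbands -> T x 25 modulation features at the video rate.

    ``envelopes`` is (n_channels, n) or (n,).  Each modulation filter is
    applied to the gammatone-channel average (see module docstring for why
    this equals per-channel filtering followed by averaging), then the 25
    series are resampled to ``frame_rate``.  Columns are ordered by
    ascending modulation center frequency.
    """
    mfb = mfb or ModulationFilterbank()
    envelopes = np.atleast_2d(np.asarray(envelopes, dtype=float))
    # warm-up: require at least ~2 periods of the slowest filter
    min_dur = 2.0 / mfb.center_freqs[0]
    dur = envelopes.shape[1] / env_rate
    if dur < min_dur:
        raise ValueError(
            f"envelope duration {dur:.2f} s shorter than the minimum "
            f"{min_dur:.1f} s required by the {mfb.center_freqs[0]} Hz filter"
        )
    mean_env = envelopes.mean(axis=0)
    if env_rate != mfb.rate:
        mean_env = _resample(mean_env, env_rate, mfb.rate)
    filtered = mfb.filter_all(mean_env)  # (n, 25)
    out = _resample(filtered, mfb.rate, frame_rate)
    return out


def normalize_features(
    X: np.ndarray,
    center_freqs: np.ndarray | None = None,
    video_id: str = "",
) -> EnvelopeFeatures:
    """Standardize each column per video (zero mean, unit variance).

    Zero-variance columns are set to exact zeros and flagged with a
    warning; this happens for silent or unmodulated synthetic input.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a T x J matrix with T >= 2")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    dead = sd == 0
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} zero-variance feature column(s) set to zero "
            f"(video {video_id or '<unnamed>'})",
            stacklevel=2,
        )
    sd_safe = np.where(dead, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, dead] = 0.0
    if center_freqs is None:
        center_freqs = ModulationFilterbank().center_freqs[: X.shape[1]]
    return EnvelopeFeatures(values=Z, center_freqs=np.asarray(center_freqs),
                            video_id=video_id)


def extract_envelope_features(
    w: AudioWaveform,
    bank: GammatoneBank | None = None,
    mfb: ModulationFilterbank | None = None,
    video_id: str = "",
) -> EnvelopeFeatures:
    """Full front-end: waveform -> standardized T x 25 features at 25 Hz."""
    mfb = mfb or ModulationFilterbank()
    env = gammatone_envelopes(w, bank)
    X = modulation_decompose(env, mfb, env_rate=w.rate)
    return normalize_features(X, center_freqs=mfb.center_freqs, video_id=video_id)
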