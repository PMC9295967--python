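"""Auditory filterbanks: gammatone bank for cochlear subbands and the
modulation filterbank applied to envelope signals.

The gammatone bank splits the 16 kHz waveform into 31 cochlea-like
frequency channels between 80 and 8000 Hz, spaced on the ERB-rate scale.
The modulation filterbank decomposes the (slow) amplitude envelope into
25 modulation-rate channels: first-order Butterworth bandpasses with a
0.75 Hz (-3 dB) bandwidth, spaced every 0.5 Hz from 0.5 to 12.5 Hz, the
Nyquist frequency of 25 fps video.  Because each canonical component
learned downstream is a linear combination of these bandpass outputs,
the bank's transfer-function matrix H is also the basis from which
effective modulation transfer functions are composed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = ["GammatoneBank", "ModulationFilterbank", "erb_space"]


def erb_space(f_low: float, f_high: float, n: int) -> np.ndarray:
    """Center frequencies equally spaced on the ERB-rate scale.

    Uses the Glasberg & Moore (1990) ERB-rate mapping
    ``E(f) = 21.4 * log10(1 + 0.00437 f)``.
    """
    if not (0 < f_low < f_high):
        raise ValueError("need 0 < f_low < f_high")
    e_lo = 21.4 * np.log10(1 + 0.00437 * f_low)
    e_hi = 21.4 * np.log10(1 + 0.00437 * f_high)
    erbs = np.linspace(e_lo, e_hi, n)
    return (10 ** (erbs / 21.4) - 1) / 0.00437


@dataclass
class GammatoneBank:
    """Bank of 4th-order gammatone IIR filters on an ERB-rate grid."""

    n_channels: int = 31
    f_low: float = 80.0
    f_high: float = 8000.0
    rate: float = 16000.0
    center_freqs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.f_high > self.rate / 2:
            raise ValueError("f_high must not exceed Nyquist")
        self.center_freqs = erb_space(self.f_low, self.f_high, self.n_channels)
        # a center at exactly Nyquist is nudged just below for the design;
        # the nominal grid (and the reported center_freqs) are unchanged
        design = np.minimum(self.center_freqs, self.rate / 2 * (1 - 1e-6))
        self._ba = [signal.gammatone(fc, "iir", fs=self.rate) for fc in design]

    def filter(self, x: np.ndarray) -> np.ndarray:
        """Filter a waveform through every channel -> (n_channels, n) array."""
        x = np.asarray(x, dtype=float)
        return np.stack([signal.lfilter(b, a, x) for b, a in self._ba])


@dataclass
class ModulationFilterbank:
    """25 first-order Butterworth bandpasses in the envelope domain.

    Parameters
    ----------
    n_channels:
        Number of modulation channels (default 25).
    spacing:
        Center-frequency spacing in Hz (default 0.5).
    bandwidth:
        -3 dB bandwidth in Hz (default 0.75); band edges sit at
        center +/- bandwidth/2, which for a Butterworth design are the
        half-power points by construction.
    f_min:
        Lowest center frequency (default 0.5 Hz; the grid then tops out
        at 12.5 Hz, the video-rate Nyquist).
    rate:
        Sample rate (Hz) the filters are designed at.  Envelopes are
        decimated to this rate before modulation filtering.
    """

    n_channels: int = 25
    spacing: float = 0.5
    bandwidth: float = 0.75
    f_min: float = 0.5
    rate: float = 100.0
    center_freqs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.center_freqs = self.f_min + self.spacing * np.arange(self.n_channels)
        top_edge = self.center_freqs[-1] + self.bandwidth / 2
        if top_edge >= self.rate / 2:
            raise ValueError("top band edge exceeds design-rate Nyquist")
        self._ba = []
        for fc in self.center_freqs:
            lo, hi = fc - self.bandwidth / 2, fc + self.bandwidth / 2
            b, a = signal.butter(1, [lo, hi], btype="bandpass", fs=self.rate)
            self._ba.append((b, a))

    def filter_channel(self, x: np.ndarray, j: int) -> np.ndarray:
        """Causal (forward-only) filtering of ``x`` with channel ``j``."""
        b, a = self._ba[j]
        return signal.lfilter(b, a, np.asarray(x, dtype=float))

    def filter_all(self, x: np.ndarray) -> np.ndarray:
        """Filter one series through every channel -> (n, n_channels)."""
        x = np.asarray(x, dtype=float)
        return np.stack([self.filter_channel(x, j) for j in range(self.n_channels)], axis=1)

    def transfer_matrix(self, freqs: np.ndarray) -> np.ndarray:
        """Complex frequency responses H on a grid -> (F, n_channels).

        This is the filter basis whose weighted column sums give the
        effective modulation transfer function of any learned component.
        """
        freqs = np.asarray(freqs, dtype=float)
        if np.any(freqs < 0) or np.any(freqs > self.rate / 2):
            raise ValueError("frequency grid outside [0, rate/2]")
        w = 2 * np.pi * freqs / self.rate
        cols = [signal.freqz(b, a, worN=w)[1] for b, a in self._ba]
        return np.stack(cols, axis=1)

    def impulse_responses(self, n_taps: int = 4096) -> np.ndarray:
        """Truncated impulse responses -> (n_taps, n_channels)."""
        imp = np.zeros(n_taps)
        imp[0] = 1.0
        return np.stack(
            [self.filter_channel(imp, j) for j in range(self.n_channels)], axis=1
        )

    def measured_bandwidths(self, resolution: float = 1e-3) -> np.ndarray:
        """Measured -3 dB bandwidth of each filter (Hz), from a fine grid."""
        out = np.empty(self.n_channels)
        for j, fc in enumerate(self.center_freqs):
            f = np.arange(max(resolution, fc - 2), fc + 2, resolution)
            mag = np.abs(self.transfer_matrix(f)[:, j])
            above = f[mag >= mag.max() / np.sqrt(2)]
            out[j] = above.max() - above.min()
        return out
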