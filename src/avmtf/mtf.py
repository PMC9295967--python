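"""Effective modulation transfer functions and facial loading maps.

Each canonical component's audio loading vector holds weights over the
25 modulation subbands.  By distributivity of convolution, summing the
subband filter outputs with those weights is the same as filtering the
envelope once with the weighted sum of the bank's impulse responses, so
the component's effective MTF is |H c| where H is the bank's transfer
matrix and c the loading column.  On the visual side, the loading column
reshapes to a 68 x 3 map of per-landmark, per-axis contributions — the
kinematic eigenregion coupled to that envelope filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .filterbanks import ModulationFilterbank
from .landmarks import N_LANDMARKS
from .rcca import RCCAModel, component_correlations, project

__all__ = [
    "EffectiveMTF",
    "FaceLoadingMap",
    "ComponentSpectrum",
    "effective_mtf",
    "composed_impulse_response",
    "component_spectra",
    "face_loading_map",
    "backproject_component",
    "speaker_identify",
]


@dataclass
class EffectiveMTF:
    freqs: np.ndarray  # (F,)
    magnitude: np.ndarray  # (F, J0)
    peak_freqs: np.ndarray  # (J0,)


@dataclass
class FaceLoadingMap:
    loadings: np.ndarray  # (68, 3, J0)
    magnitude: np.ndarray  # (68, J0), Euclidean norm over axes
    axis_fraction: np.ndarray  # (68, 3, J0), squared fractions summing to 1


@dataclass
class ComponentSpectrum:
    freqs: np.ndarray
    per_video: np.ndarray  # (n_videos, F, J0) power spectra
    average: np.ndarray  # (F, J0)
    peak_freqs: np.ndarray  # (n_videos, J0) per-video spectral peaks


def effective_mtf(model: RCCAModel, mfb: ModulationFilterbank | None = None,
                  freqs: np.ndarray | None = None) -> EffectiveMTF:
    """Compose per-component MTFs as |H loadings_A| on a frequency grid.

    H is the bank's matrix of real (magnitude) transfer functions;
    composing magnitudes keeps the peak of a symmetric loading profile
    at the profile's center, whereas complex composition lets the
    channels' phase rotation skew the peak upward by up to half a
    channel spacing.  Phase is retained internally and available via
    ``ModulationFilterbank.transfer_matrix``.  Peak frequencies take the
    global maximum; plateaus resolve to the lowest frequency.
    """
    mfb = mfb or ModulationFilterbank()
    if model.loadings_A.shape[0] != mfb.n_channels:
        raise ValueError("model audio dimension does not match filterbank channels")
    if freqs is None:
        freqs = np.linspace(0.0, mfb.center_freqs[-1], 1024)
    freqs = np.asarray(freqs, float)
    if freqs.max() > mfb.center_freqs[-1] + mfb.bandwidth:
        raise ValueError(
            f"frequency grid exceeds the modulation analysis band "
            f"(top {mfb.center_freqs[-1] + mfb.bandwidth} Hz)"
        )
    H = np.abs(mfb.transfer_matrix(freqs))  # (F, 25) magnitude responses
    mag = np.abs(H @ model.loadings_A)
    peaks = freqs[np.argmax(mag, axis=0)]
    return EffectiveMTF(freqs=freqs, magnitude=mag, peak_freqs=peaks)


def composed_impulse_response(mfb: ModulationFilterbank, weights: np.ndarray,
                              n_taps: int = 4096) -> np.ndarray:
    """Weighted sum of the bank's impulse responses (the composed filter)."""
    weights = np.asarray(weights, float)
    if weights.shape[0] != mfb.n_channels:
        raise ValueError("one weight per modulation channel required")
    return mfb.impulse_responses(n_taps) @ weights


def component_spectra(projections: dict, frame_rate: float = 25.0,
                      segment_s: float = 2.0, overlap: float = 0.5) -> ComponentSpectrum:
    """Average (Welch) power spectra of per-video component series.

    ``projections`` maps video id -> (T, J0) series, typically the audio
    loading projections X_A (Sigma_A W_A).  Videos shorter than one
    segment are skipped with a log entry.
    """
    import logging

    nperseg = int(round(segment_s * frame_rate))
    noverlap = int(round(nperseg * overlap))
    spectra, peaks = [], []
    for vid, series in projections.items():
        series = np.asarray(series, float)
        if len(series) < nperseg:
            logging.getLogger(__name__).info(
                "skipping %s: %d frames < one %d-frame segment", vid, len(series), nperseg
            )
            continue
        f, p = signal.welch(series, fs=frame_rate, nperseg=nperseg,
                            noverlap=noverlap, axis=0, window="hann")
        spectra.append(p)
        peaks.append(f[np.argmax(p, axis=0)])
    if not spectra:
        raise ValueError("no video long enough for one spectral segment")
    per_video = np.asarray(spectra)
    return ComponentSpectrum(freqs=f, per_video=per_video,
                             average=per_video.mean(axis=0),
                             peak_freqs=np.asarray(peaks))


def face_loading_map(model: RCCAModel) -> FaceLoadingMap:
    """Reshape visual loadings to per-landmark, per-axis contribution maps."""
    LV = model.loadings_V
    if LV.shape[0] % 3:
        raise ValueError("visual dimension must be divisible by 3 (x, y, z)")
    n_lm = LV.shape[0] // 3
    if n_lm != N_LANDMARKS:
        import warnings

        warnings.warn(f"expected {N_LANDMARKS} landmarks, got {n_lm}", stacklevel=2)
    maps = LV.reshape(n_lm, 3, -1)
    mag = np.linalg.norm(maps, axis=1)  # (68, J0)
    if np.any(mag.max(axis=0) == 0):
        import warnings

        warnings.warn("all-zero visual loading column; empty face map", stacklevel=2)
    denom = np.where(mag == 0, 1.0, mag**2)[:, None, :]
    frac = maps**2 / denom
    frac[np.broadcast_to((mag == 0)[:, None, :], frac.shape)] = 0.0
    return FaceLoadingMap(loadings=maps, magnitude=mag, axis_fraction=frac)


def backproject_component(model: RCCAModel, visual_variates: np.ndarray,
                          component: int) -> np.ndarray:
    """Rank-1 reconstruction of landmark motion for one component.

    Returns (T, 68, 3) in normalized coordinate units: the component's
    visual variate times its visual loading vector.
    """
    if not 0 <= component < model.n_components:
        raise IndexError(f"component {component} out of range 0..{model.n_components - 1}")
    v = np.asarray(visual_variates, float)[:, component]
    col = model.loadings_V[:, component]
    return np.outer(v, col).reshape(len(v), -1, 3)


def speaker_identify(model: RCCAModel, audio_candidates, video_features) -> int:
    """Pick which candidate audio stream matches a video segment.

    Projects every candidate and the video onto the first canonical
    component and returns the index with the highest CC1 correlation
    (ties break to the lowest index).  Streams are truncated to the
    shortest common length.
    """
    if len(audio_candidates) < 2:
        raise ValueError("need at least 2 candidate audio streams")
    XV = np.asarray(video_features, float)
    t = min([len(XV)] + [len(a) for a in audio_candidates])
    vv = project(model, XV[:t], "visual")[:, :1]
    scores = []
    for Xa in audio_candidates:
        av = project(model, np.asarray(Xa, float)[:t], "audio")[:, :1]
        scores.append(component_correlations(av, vv)[0])
    return int(np.argmax(scores))
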