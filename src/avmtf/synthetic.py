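"""Synthetic audiovisual corpora with planted latent-source structure.

The generator realizes the forward generative model that motivates the
analysis: a small set of latent narrowband modulation sources S (e.g.
bandlimited noise near 3-4 Hz for syllable-like oral rhythm, 1-2 Hz for
phrase-like head/face rhythm) drives both views linearly,

    X_A = S A_A' + eps_A      (25 envelope modulation subbands)
    X_V = S A_V' + eps_V      (204 landmark coordinates)

with view-specific Gaussian noise and per-speaker variation: each
speaker perturbs the mixing vectors multiplicatively and the source
center frequencies additively (speaking-rate jitter).  Corpora can be
produced at the feature level (directly as X_A / X_V pairs) or at the
waveform level, where the audio track is a noise carrier amplitude-
modulated by the source mixture so that the audio front-end recovers the
planted modulation spectrum, and the landmarks are a schematic static
face plus source-driven motion.

Latent sources are bandlimited Gaussian noise (hard FFT band masks):
the speech rhythms being emulated are quasi-regular, not strictly
periodic, so narrowband noise is the appropriate source model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from . import landmarks as lm
from .audio import FRAME_RATE, normalize_features
from .filterbanks import ModulationFilterbank

__all__ = [
    "SourceSpec",
    "SyntheticGroundTruth",
    "FeatureCorpus",
    "WaveformCorpus",
    "generate_sources",
    "generate_feature_views",
    "generate_feature_corpus",
    "generate_waveform_corpus",
    "flagship_ground_truth",
    "independent_ground_truth",
    "write_waveform_corpus",
    "MOUTH_LANDMARKS",
]

VIDEO_NYQUIST = 12.5
MOUTH_LANDMARKS = np.arange(48, 68)  # 68-point convention: outer+inner lips


@dataclass(frozen=True)
class SourceSpec:
    """One latent narrowband source in the modulation domain."""

    center_freq: float  # Hz
    bandwidth: float  # Hz
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.center_freq <= 0 or self.bandwidth <= 0:
            raise ValueError("center_freq and bandwidth must be positive")
        if self.center_freq + self.bandwidth / 2 >= VIDEO_NYQUIST:
            raise ValueError(
                f"source band [{self.center_freq - self.bandwidth / 2:.2f}, "
                f"{self.center_freq + self.bandwidth / 2:.2f}] Hz exceeds the "
                f"video-rate Nyquist limit of {VIDEO_NYQUIST} Hz"
            )


@dataclass
class SyntheticGroundTruth:
    """Planted sources and mixing patterns of a synthetic corpus."""

    sources: list  # list[SourceSpec]
    audio_mixing: np.ndarray  # (n_sources, 25)
    visual_mixing: np.ndarray  # (n_sources, 204)
    audio_noise_sd: float = 1.0
    visual_noise_sd: float = 1.0
    speaker_jitter: float = 0.1  # fractional multiplicative mixing jitter
    freq_jitter_sd: float = 0.2  # Hz, per-speaker center-frequency jitter
    seed: int = 0

    def __post_init__(self) -> None:
        self.audio_mixing = np.atleast_2d(np.asarray(self.audio_mixing, float))
        self.visual_mixing = np.atleast_2d(np.asarray(self.visual_mixing, float))
        k = len(self.sources)
        if self.audio_mixing.shape[0] != k or self.visual_mixing.shape[0] != k:
            raise ValueError("one mixing row per source required")
        if not (np.all(np.isfinite(self.audio_mixing)) and np.all(np.isfinite(self.visual_mixing))):
            raise ValueError("mixing vectors must be finite")
        if self.audio_noise_sd < 0 or self.visual_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class FeatureCorpus:
    """Corpus of standardized feature pairs with retained ground truth."""

    video_ids: list
    speaker_ids: list
    X_A: list  # list of (T, 25)
    X_V: list  # list of (T, 204)
    ground_truth: SyntheticGroundTruth

    def pairs(self):
        return list(zip(self.X_A, self.X_V, self.video_ids))

    def speakers(self):
        return sorted(set(self.speaker_ids))


@dataclass
class WaveformCorpus:
    video_ids: list
    speaker_ids: list
    waveforms: list  # list of 1-D arrays
    audio_rate: float
    landmark_series: list  # list[lm.LandmarkSeries]
    clip_fractions: list
    ground_truth: SyntheticGroundTruth


def generate_sources(specs, n_frames: int, frame_rate: float, seed) -> np.ndarray:
    """Realize latent sources as zero-mean unit-variance bandpass noise.

    Each column is Gaussian white noise FFT-masked to the spec band and
    re-standardized, so its power spectrum is concentrated within
    [center - bw/2, center + bw/2].
    """
    if n_frames < 2 * frame_rate:
        raise ValueError("need at least 2 s of frames")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_frames, d=1.0 / frame_rate)
    cols = []
    for spec in specs:
        if not isinstance(spec, SourceSpec):
            spec = SourceSpec(*spec)
        noise = rng.standard_normal(n_frames)
        spec_f = np.fft.rfft(noise)
        lo = spec.center_freq - spec.bandwidth / 2
        hi = spec.center_freq + spec.bandwidth / 2
        mask = (freqs >= lo) & (freqs <= hi)
        if not mask.any():
            raise ValueError(f"band [{lo}, {hi}] Hz contains no FFT bin at T={n_frames}")
        x = np.fft.irfft(spec_f * mask, n=n_frames)
        x = (x - x.mean()) / x.std()
        cols.append(spec.amplitude * x)
    return np.stack(cols, axis=1)


def _speaker_params(gt: SyntheticGroundTruth, speaker_index: int):
    """Per-speaker jittered mixing matrices and source specs."""
    rng = np.random.default_rng([gt.seed, 7919, speaker_index])
    A_A = gt.audio_mixing * (1 + gt.speaker_jitter * rng.standard_normal(gt.audio_mixing.shape))
    A_V = gt.visual_mixing * (1 + gt.speaker_jitter * rng.standard_normal(gt.visual_mixing.shape))
    specs = []
    for s in gt.sources:
        fc = s.center_freq + gt.freq_jitter_sd * rng.standard_normal()
        fc = float(np.clip(fc, s.bandwidth / 2 + 0.05, VIDEO_NYQUIST - s.bandwidth / 2 - 0.05))
        specs.append(SourceSpec(fc, s.bandwidth, s.amplitude))
    return A_A, A_V, specs


def generate_feature_views(S: np.ndarray, gt: SyntheticGroundTruth,
                           speaker_index: int = 0, seed=0,
                           jittered=None):
    """Mix sources into both feature views and standardize per video.

    Returns ``(X_A, X_V)`` with X_A column-standardized (as the audio
    front-end does) and X_V standardized pooled per spatial dimension
    (as the landmark pipeline does).
    """
    S = np.atleast_2d(np.asarray(S, float))
    if S.shape[1] != len(gt.sources):
        raise ValueError(
            f"S has {S.shape[1]} columns but ground truth has {len(gt.sources)} sources"
        )
    A_A, A_V, _ = jittered if jittered is not None else _speaker_params(gt, speaker_index)
    rng = np.random.default_rng(seed)
    T = S.shape[0]
    XA = S @ A_A + gt.audio_noise_sd * rng.standard_normal((T, A_A.shape[1]))
    XV = S @ A_V + gt.visual_noise_sd * rng.standard_normal((T, A_V.shape[1]))
    XA = normalize_features(XA).values
    XV = lm.standardize_per_dimension(XV.reshape(T, lm.N_LANDMARKS, 3)).reshape(T, -1)
    return XA, XV


def generate_feature_corpus(
    gt: SyntheticGroundTruth,
    n_speakers: int,
    videos_per_speaker: int,
    n_frames: int,
    seed: int | None = None,
    independent: bool = False,
) -> FeatureCorpus:
    """Feature-level corpus: many speakers, several videos each.

    With ``independent=True`` the visual view is driven by fresh,
    independent source realizations, producing audiovisually unrelated
    data for null-calibration studies.
    """
    seed = gt.seed if seed is None else seed
    video_ids, speaker_ids, XAs, XVs = [], [], [], []
    for sp in range(n_speakers):
        params = _speaker_params(gt, sp)
        _, _, specs = params
        for v in range(videos_per_speaker):
            sseed = [seed, 104729, sp, v]
            S = generate_sources(specs, n_frames, FRAME_RATE, sseed)
            XA, XV = generate_feature_views(S, gt, sp, seed=[seed, 15485863, sp, v],
                                            jittered=params)
            if independent:
                S2 = generate_sources(specs, n_frames, FRAME_RATE, [seed, 32452843, sp, v])
                _, XV = generate_feature_views(S2, gt, sp, seed=[seed, 49979687, sp, v],
                                               jittered=params)
            video_ids.append(f"spk{sp:03d}_vid{v:02d}")
            speaker_ids.append(f"spk{sp:03d}")
            XAs.append(XA)
            XVs.append(XV)
    return FeatureCorpus(video_ids, speaker_ids, XAs, XVs, gt)


def _mean_face() -> np.ndarray:
    """Schematic static 68-point face in pixel-like units."""
    pos = np.zeros((lm.N_LANDMARKS, 3))
    t = np.linspace(-np.pi / 2, np.pi / 2, 17)
    pos[0:17] = np.c_[80 * np.sin(t), 60 * np.cos(t) + 40, 10 * np.cos(t)]  # jaw line
    for i in range(10):  # brows
        side = -1 if i < 5 else 1
        pos[17 + i] = [side * (15 + 10 * (i % 5)), -40, 5]
    for i in range(9):  # nose
        pos[27 + i] = [0 if i < 4 else (i - 6) * 6, -20 + 5 * min(i, 4), 20]
    for i in range(12):  # eyes
        side = -1 if i < 6 else 1
        ang = 2 * np.pi * (i % 6) / 6
        pos[36 + i] = [side * 30 + 8 * np.cos(ang), -30 + 4 * np.sin(ang), 8]
    for i in range(20):  # mouth
        ang = 2 * np.pi * i / 20
        r = 18 if i < 12 else 10
        pos[48 + i] = [r * np.cos(ang), 30 + 0.6 * r * np.sin(ang), 12]
    return pos + np.array([160.0, 120.0, 0.0])


def generate_waveform_corpus(
    gt: SyntheticGroundTruth,
    n_speakers: int,
    videos_per_speaker: int,
    duration_s: float,
    audio_rate: float = 16000.0,
    seed: int | None = None,
    modulation_depth: float = 0.6,
) -> WaveformCorpus:
    """Waveform-level corpus for end-to-end front-end testing.

    The audio track is broadband Gaussian noise amplitude-modulated by
    ``max(0, 1 + depth * source_mix)``; the rectified (clipped) fraction
    per video is recorded.  Landmarks are the schematic mean face plus
    source-driven motion and estimation noise at 25 fps.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if audio_rate < 16000:
        raise ValueError("audio_rate must be >= 16000 Hz")
    seed = gt.seed if seed is None else seed
    n_frames = int(round(duration_s * FRAME_RATE))
    mean_face = _mean_face()
    video_ids, speaker_ids, waves, series, clipped = [], [], [], [], []
    for sp in range(n_speakers):
        params = _speaker_params(gt, sp)
        A_A, A_V, specs = params
        for v in range(videos_per_speaker):
            rng = np.random.default_rng([seed, 86028121, sp, v])
            S = generate_sources(specs, n_frames, FRAME_RATE, [seed, 104729, sp, v])
            # audio: modulate a noise carrier with the source mixture
            amps = np.array([s.amplitude for s in specs])
            mix = S @ amps / max(np.sqrt((amps**2).sum()), 1e-12)
            n_samp = int(round(duration_s * audio_rate))
            t_frame = np.arange(n_frames) / FRAME_RATE
            t_samp = np.arange(n_samp) / audio_rate
            mod = 1.0 + modulation_depth * np.interp(t_samp, t_frame, mix)
            frac = float((mod < 0).mean())
            mod = np.maximum(mod, 0.0)
            carrier = rng.standard_normal(n_samp)
            wave = carrier * mod
            peak = np.abs(wave).max()
            if peak > 0:
                wave = 0.9 * wave / peak
            # video: static face + planted motion + estimation jitter
            motion = (S @ A_V).reshape(n_frames, lm.N_LANDMARKS, 3)
            noise = gt.visual_noise_sd * rng.standard_normal(motion.shape)
            pos = mean_face[None] + 2.0 * motion + 2.0 * noise
            vid = f"spk{sp:03d}_vid{v:02d}"
            video_ids.append(vid)
            speaker_ids.append(f"spk{sp:03d}")
            waves.append(wave)
            series.append(lm.LandmarkSeries(pos, FRAME_RATE, vid))
            clipped.append(frac)
    return WaveformCorpus(video_ids, speaker_ids, waves, audio_rate, series, clipped, gt)


def write_waveform_corpus(corpus: WaveformCorpus, out_dir) -> Path:
    """Write WAVs, landmark tables, ground truth and a manifest to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for vid, spk, wave, ls, frac in zip(
        corpus.video_ids, corpus.speaker_ids, corpus.waveforms,
        corpus.landmark_series, corpus.clip_fractions,
    ):
        wav_path = out / f"{vid}.wav"
        lmk_path = out / f"{vid}_landmarks.csv"
        wavfile.write(wav_path, int(corpus.audio_rate), wave.astype(np.float32))
        lm.write_landmarks(lmk_path, ls)
        rows.append({"video_id": vid, "speaker_id": spk, "wav": wav_path.name,
                     "landmarks": lmk_path.name, "clip_fraction": frac})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    gt = corpus.ground_truth
    meta = {
        "sources": [asdict(s) for s in gt.sources],
        "audio_noise_sd": gt.audio_noise_sd,
        "visual_noise_sd": gt.visual_noise_sd,
        "speaker_jitter": gt.speaker_jitter,
        "freq_jitter_sd": gt.freq_jitter_sd,
        "seed": gt.seed,
    }
    (out / "ground_truth.json").write_text(json.dumps(meta, indent=2))
    np.savetxt(out / "audio_mixing.csv", gt.audio_mixing, delimiter=",")
    np.savetxt(out / "visual_mixing.csv", gt.visual_mixing, delimiter=",")
    return out


def _gaussian_bump(centers: np.ndarray, fc: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((centers - fc) / width) ** 2)


def oral_pattern(weight_y: float = 1.0, weight_xz: float = 0.25) -> np.ndarray:
    """Mouth-region mixing vector: vertical lip/jaw motion, length 204."""
    v = np.zeros((lm.N_LANDMARKS, 3))
    v[MOUTH_LANDMARKS, 0] = weight_xz
    v[MOUTH_LANDMARKS, 1] = weight_y
    v[MOUTH_LANDMARKS, 2] = weight_xz
    return v.reshape(-1)


def global_pattern(mouth_weight: float = 0.15) -> np.ndarray:
    """Global head/face mixing vector: broad motion over non-oral landmarks
    with a small oral involvement, length 204."""
    v = np.zeros((lm.N_LANDMARKS, 3))
    v[0:48, 0] = 0.6
    v[0:48, 1] = 0.6
    v[0:48, 2] = 0.4
    v[MOUTH_LANDMARKS] = mouth_weight
    return v.reshape(-1)


def flagship_ground_truth(
    audio_noise_sd: float = 1.0,
    visual_noise_sd: float = 1.0,
    speaker_jitter: float = 0.1,
    freq_jitter_sd: float = 0.2,
    seed: int = 0,
) -> SyntheticGroundTruth:
    """Two-timescale study conditions: a 4 Hz source driving an oral
    landmark pattern and a 1.5 Hz source driving a global head/face
    pattern — the desk-scale analog of syllable- and phrase-rate AV
    coupling."""
    mfb = ModulationFilterbank()
    # the oral/syllable-rate coupling is the strongest canonical component
    # in natural AV speech; the amplitude hierarchy reproduces that ordering
    # and keeps the two-source decomposition identifiable (equal strengths
    # would make the canonical pair degenerate under rotation)
    sources = [SourceSpec(4.0, 1.0, 1.3), SourceSpec(1.5, 1.0, 0.8)]
    audio_mixing = np.stack([
        _gaussian_bump(mfb.center_freqs, 4.0, 0.75),
        _gaussian_bump(mfb.center_freqs, 1.5, 0.75),
    ])
    visual_mixing = np.stack([oral_pattern(), global_pattern()])
    return SyntheticGroundTruth(
        sources=sources, audio_mixing=audio_mixing, visual_mixing=visual_mixing,
        audio_noise_sd=audio_noise_sd, visual_noise_sd=visual_noise_sd,
        speaker_jitter=speaker_jitter, freq_jitter_sd=freq_jitter_sd, seed=seed,
    )


def independent_ground_truth(seed: int = 0) -> SyntheticGroundTruth:
    """Same structure as the flagship conditions; used with
    ``generate_feature_corpus(..., independent=True)`` so the two views
    share no sources."""
    gt = flagship_ground_truth(seed=seed)
    return gt
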