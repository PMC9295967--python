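"""Reusable study routines over the synthetic corpora.

Each routine runs one self-contained numerical experiment at desk scale:
the flagship two-timescale recovery, the significance-level calibration
on audiovisually independent data, the no-spurious-component check at
large evaluation size, and the audio-video speaker-identification curve.
The analysis drivers and the verification suite both call these, so the
numbers they report are produced by one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import crossval as cv
from . import mtf as mtfmod
from . import synthetic as syn
from .pipeline import RunConfig, run_pipeline
from .rcca import accumulate_covariances, component_correlations, fit_rcca, project

__all__ = [
    "FlagshipOutcome",
    "flagship_replicate",
    "calibration_study",
    "floor_study",
    "speaker_id_study",
]


def _abs_cosine(a: np.ndarray, b: np.ndarray) -> float:
    return float(abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b)))


@dataclass
class FlagshipOutcome:
    n_reported: int
    peak_fast_hz: float  # MTF peak of the component matched to the 4 Hz source
    peak_slow_hz: float  # MTF peak of the component matched to the 1.5 Hz source
    cosine_oral: float
    cosine_global: float
    test_correlations: np.ndarray
    best_lambda: tuple

    @property
    def success(self) -> bool:
        """The two-timescale recovery criterion: at least two reported
        components whose MTF peaks land in the 3-4.5 Hz and 1-2 Hz bands
        and whose visual loadings match the planted patterns."""
        return (self.n_reported >= 2
                and 3.0 <= self.peak_fast_hz <= 4.5
                and 1.0 <= self.peak_slow_hz <= 2.0
                and self.cosine_oral > 0.9
                and self.cosine_global > 0.9)


def flagship_replicate(seed: int, out_dir=None, config: RunConfig | None = None) -> FlagshipOutcome:
    """One full pipeline run on the flagship two-source study conditions."""
    import tempfile

    config = config or RunConfig(seed=seed)
    if out_dir is None:
        with tempfile.TemporaryDirectory() as td:
            out = run_pipeline(config, td)
    else:
        out = run_pipeline(config, out_dir)
    res, em = out["result"], out["mtf"]
    gt = out["corpus"].ground_truth
    rep = np.flatnonzero(res.reported)
    order = rep[np.argsort(res.test_correlations[rep])[::-1]][:2]
    if len(order) < 2:
        return FlagshipOutcome(len(rep), np.nan, np.nan, 0.0, 0.0,
                               res.test_correlations, out["search"].best_lambda)
    peaks = em.peak_freqs[order]
    fast = order[int(np.argmax(peaks))]
    slow = order[int(np.argmin(peaks))]
    L = res.model.loadings_V
    return FlagshipOutcome(
        n_reported=int(len(rep)),
        peak_fast_hz=float(em.peak_freqs[fast]),
        peak_slow_hz=float(em.peak_freqs[slow]),
        cosine_oral=_abs_cosine(L[:, fast], gt.visual_mixing[0]),
        cosine_global=_abs_cosine(L[:, slow], gt.visual_mixing[1]),
        test_correlations=res.test_correlations,
        best_lambda=out["search"].best_lambda,
    )


def calibration_study(n_reps: int = 200, seed: int = 0, n_speakers: int = 8,
                      videos_per_speaker: int = 3, n_frames: int = 250,
                      n_train_speakers: int = 4, null_size: int = 200,
                      percentile: float = 95.0, lam: float = 1e-3) -> float:
    """False-positive rate of the 95th-percentile significance rule on
    audiovisually independent corpora.

    Matched correlations are computed per evaluation video and compared
    against a mismatch null built from single video pairs of the same
    length, so matched and null statistics are exchangeable under A/V
    independence and the nominal level is exact.  Returns the rate as a
    fraction (target 0.05).
    """
    hits = total = 0
    n_train = n_train_speakers * videos_per_speaker
    for rep in range(n_reps):
        rep_seed = (seed * 100003 + rep) % 2**31
        gt = syn.independent_ground_truth(seed=rep_seed)
        c = syn.generate_feature_corpus(gt, n_speakers, videos_per_speaker,
                                        n_frames, seed=rep_seed, independent=True)
        train = [(c.X_A[i], c.X_V[i], c.video_ids[i]) for i in range(n_train)]
        model = fit_rcca(accumulate_covariances(train), lam, lam)
        eval_ids = c.video_ids[n_train:]
        a = {c.video_ids[i]: project(model, c.X_A[i], "audio")
             for i in range(n_train, len(c.video_ids))}
        v = {c.video_ids[i]: project(model, c.X_V[i], "visual")
             for i in range(n_train, len(c.video_ids))}
        null = cv.mismatch_null(a, v, eval_ids, n=null_size, seed=rep_seed)
        thr = null.percentile(percentile)
        for vid in eval_ids:
            r = component_correlations(a[vid], v[vid])
            hits += int((r > thr).sum())
            total += r.size
    return hits / total


def floor_study(seed: int = 0, n_speakers: int = 12, videos_per_speaker: int = 2,
                n_frames: int = 1500, null_size: int = 1000) -> dict:
    """Run the full significance decision on an A/V-independent corpus
    with a large (>= 15,000-frame) test set: no component should survive
    the joint significance + 1% reporting rule."""
    gt = syn.independent_ground_truth(seed=seed)
    c = syn.generate_feature_corpus(gt, n_speakers, videos_per_speaker, n_frames,
                                    seed=seed, independent=True)
    # enlarge the test share so the evaluation set reaches 15k frames
    split = cv.make_split(c.video_ids, c.speaker_ids, test_frac=0.45, n_folds=5,
                          seed=seed + 1)
    res = cv.finalize_and_test(c, split, 1e-3, 1e-3, null_size=null_size,
                               seed=seed + 2)
    test_frames = sum(len(c.X_A[c.video_ids.index(v)]) for v in split.test_videos)
    return {
        "n_reported": int(res.reported.sum()),
        "n_test_frames": int(test_frames),
        "max_abs_matched": float(np.abs(res.test_correlations).max()),
    }


def speaker_id_study(seed: int = 0, noise_sd: float = 5.0,
                     durations_s=(0.5, 1.0, 2.0, 5.0, 15.0, 60.0),
                     n_trials: int = 200, n_speakers: int = 20,
                     videos_per_speaker: int = 3, n_frames: int = 1500,
                     n_candidates: int = 2, lam: float = 1e-2) -> dict:
    """Two-alternative AV speaker identification accuracy vs segment length.

    Fits a model on most speakers, then asks, for held-out videos, which
    of ``n_candidates`` audio streams matches a video segment (highest
    CC1 correlation).  Returns accuracies per duration.
    """
    gt = syn.flagship_ground_truth(audio_noise_sd=noise_sd, visual_noise_sd=noise_sd,
                                   seed=seed)
    c = syn.generate_feature_corpus(gt, n_speakers, videos_per_speaker, n_frames,
                                    seed=seed)
    split = cv.make_split(c.video_ids, c.speaker_ids, test_frac=0.2, n_folds=5,
                          seed=seed + 1)
    covs = cv.per_video_covariances(c)
    cov = covs[split.train_videos[0]]
    for vid in split.train_videos[1:]:
        cov = cov + covs[vid]
    model = fit_rcca(cov, lam, lam, 5)
    lookup = {vid: (XA, XV) for XA, XV, vid in c.pairs()}
    test = split.test_videos
    rng = np.random.default_rng(seed + 2)
    accuracies = {}
    for dur in durations_s:
        t = int(round(dur * 25))
        correct = 0
        for _ in range(n_trials):
            picks = rng.choice(len(test), n_candidates, replace=False)
            off = int(rng.integers(0, n_frames - t + 1))
            XV = lookup[test[picks[0]]][1][off:off + t]
            cands = [lookup[test[p]][0][off:off + t] for p in picks]
            correct += int(mtfmod.speaker_identify(model, cands, XV) == 0)
        accuracies[dur] = correct / n_trials
    return accuracies
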