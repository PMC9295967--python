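"""Speaker-disjoint evaluation: splits, match-mismatch null, regularization search.

The model is trained to find AV correlations that generalize *across
speakers*: 10% of videos (by speaker) are held out as a test set, the
remaining 90% are divided into five speaker-disjoint folds.  Model
quality on held-out data is measured with a match-mismatch objective —
the per-component correlation of correctly paired audio/video minus the
median correlation over mismatched pairings — and component significance
is judged against the 95th percentile of an empirical null built from
mismatched pairings (default 1000).  The two regularization weights are
searched over [1e-5, 1] with Gaussian-process Bayesian optimization
(Matern kernel, hedged LCB/EI/PI acquisition; 5 log-uniform random
evaluations followed by 5 GP-guided ones by default).  Components with a
test correlation below 1% are never reported, significant or not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .rcca import (CovarianceSet, RCCAModel, accumulate_covariances,
                   component_correlations, fit_rcca, project)

__all__ = [
    "SpeakerSplit",
    "NullDistribution",
    "SearchResult",
    "SignificanceResult",
    "make_split",
    "mismatch_null",
    "matched_correlation",
    "objective",
    "optimize_regularization",
    "cv_objective",
    "finalize_and_test",
    "per_video_covariances",
]

LAMBDA_BOUNDS = (1e-5, 1.0)
SIGNIFICANCE_PERCENTILE = 95.0
MIN_REPORTED_CORRELATION = 0.01


@dataclass
class SpeakerSplit:
    test_videos: list
    folds: list  # list of lists of video ids
    speaker_of: dict  # video id -> speaker id
    seed: int = 0

    @property
    def train_videos(self) -> list:
        return [v for fold in self.folds for v in fold]

    def validate(self) -> None:
        groups = [self.test_videos] + list(self.folds)
        speaker_sets = [set(self.speaker_of[v] for v in g) for g in groups]
        for i in range(len(speaker_sets)):
            for j in range(i + 1, len(speaker_sets)):
                shared = speaker_sets[i] & speaker_sets[j]
                if shared:
                    raise AssertionError(f"speaker(s) {sorted(shared)} appear in two splits")


@dataclass
class NullDistribution:
    samples: np.ndarray  # (n, J0) correlations from mismatched pairings

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    def percentile(self, p: float = SIGNIFICANCE_PERCENTILE) -> np.ndarray:
        return np.percentile(self.samples, p, axis=0)

    def median(self) -> np.ndarray:
        return np.median(self.samples, axis=0)


@dataclass
class SearchResult:
    lambdas: list  # [(lam_A, lam_V), ...]
    objectives: list
    acquisitions: list
    best_lambda: tuple
    best_objective: float


@dataclass
class SignificanceResult:
    model: RCCAModel
    test_correlations: np.ndarray
    null: NullDistribution
    significant: np.ndarray  # bool, exceeds 95th null percentile
    reported: np.ndarray  # bool, significant AND >= 1% correlation
    percentile: float = SIGNIFICANCE_PERCENTILE
    min_correlation: float = MIN_REPORTED_CORRELATION


def make_split(video_ids, speaker_ids, test_frac: float = 0.1, n_folds: int = 5,
               seed: int = 0) -> SpeakerSplit:
    """Speaker-level grouped split: test set plus n_folds CV folds.

    Fractions are honored as closely as speaker granularity permits;
    folds are balanced greedily by video count.  Deterministic in seed.
    """
    video_ids = list(video_ids)
    speaker_of = dict(zip(video_ids, speaker_ids))
    by_speaker: dict = {}
    for v, s in speaker_of.items():
        by_speaker.setdefault(s, []).append(v)
    speakers = sorted(by_speaker)
    if len(speakers) < n_folds + 1:
        raise ValueError(f"need at least {n_folds + 1} distinct speakers, got {len(speakers)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(speakers))
    n_total = len(video_ids)
    test, test_count = [], 0
    while order and (test_count < test_frac * n_total or not test):
        s = order.pop()
        if len(order) < n_folds:  # keep enough speakers for the folds
            order.append(s)
            break
        test.extend(by_speaker[s])
        test_count += len(by_speaker[s])
    folds: list = [[] for _ in range(n_folds)]
    for s in order:
        smallest = min(range(n_folds), key=lambda i: len(folds[i]))
        folds[smallest].extend(by_speaker[s])
    split = SpeakerSplit(test_videos=test, folds=folds, speaker_of=speaker_of, seed=seed)
    split.validate()
    return split


def per_video_covariances(corpus) -> dict:
    """Per-video covariance sets, so fold covariances are cheap sums."""
    out = {}
    for XA, XV, vid in corpus.pairs():
        out[vid] = accumulate_covariances([(XA, XV, vid)])
    return out


def _sum_covs(covs: dict, vids) -> CovarianceSet:
    vids = list(vids)
    total = covs[vids[0]]
    for v in vids[1:]:
        total = total + covs[v]
    return total


def matched_correlation(audio_vars: dict, visual_vars: dict, vids,
                        per_video: bool = False) -> np.ndarray:
    """Per-component correlation of correctly paired variates.

    Default: computed on variates concatenated across ``vids``.  With
    ``per_video=True``, the mean of per-video correlations instead.
    """
    vids = list(vids)
    if per_video:
        rs = [component_correlations(audio_vars[v], visual_vars[v]) for v in vids]
        return np.mean(rs, axis=0)
    A = np.concatenate([audio_vars[v] for v in vids])
    V = np.concatenate([visual_vars[v] for v in vids])
    return component_correlations(A, V)


def mismatch_null(audio_vars: dict, visual_vars: dict, vids=None, n: int = 1000,
                  seed: int = 0, speaker_of: dict | None = None) -> NullDistribution:
    """Empirical null from mismatched AV pairings.

    Each sample pairs the audio variates of one randomly chosen video
    with the visual variates of a different video (truncated to the
    shorter length) and records every component's correlation.  Matched
    pairings are excluded by construction.
    """
    vids = list(vids if vids is not None else audio_vars.keys())
    if len(vids) < 2:
        raise ValueError("need at least 2 videos for mismatched pairings")
    if speaker_of is not None:
        import warnings

        if len({speaker_of[v] for v in vids}) < 2:
            warnings.warn("all null videos share one speaker; null may be optimistic",
                          stacklevel=2)
    rng = np.random.default_rng(seed)
    m = len(vids)
    samples = []
    for _ in range(n):
        i = int(rng.integers(m))
        j = int(rng.integers(m - 1))
        if j >= i:
            j += 1
        A = audio_vars[vids[i]]
        V = visual_vars[vids[j]]
        t = min(len(A), len(V))
        samples.append(component_correlations(A[:t], V[:t]))
    return NullDistribution(np.asarray(samples))


def objective(matched: np.ndarray, null: NullDistribution,
              percentile: float = SIGNIFICANCE_PERCENTILE) -> float:
    """Match-mismatch objective: sum over fold-significant components of
    (matched correlation - median mismatched correlation).

    Components not exceeding the null's ``percentile`` contribute
    nothing; with no significant component the objective is 0.
    """
    thr = null.percentile(percentile)
    med = null.median()
    sig = matched > thr
    return float(np.sum((matched - med)[sig]))


def _variates(model: RCCAModel, corpus, vids) -> tuple[dict, dict]:
    lookup = {vid: (XA, XV) for XA, XV, vid in corpus.pairs()}
    a, v = {}, {}
    for vid in vids:
        XA, XV = lookup[vid]
        a[vid] = project(model, XA, "audio")
        v[vid] = project(model, XV, "visual")
    return a, v


def cv_objective(corpus, split: SpeakerSplit, lambda_A: float, lambda_V: float,
                 n_components: int | None = None, null_size: int = 1000,
                 percentile: float = SIGNIFICANCE_PERCENTILE, seed: int = 0,
                 covs: dict | None = None) -> float:
    """Summed match-mismatch objective over the five CV folds.

    Each fold's model is trained on the other folds and evaluated on the
    held-out fold (matched correlations on concatenated variates; null
    from mismatched pairings within the fold)."""
    covs = covs if covs is not None else per_video_covariances(corpus)
    total = 0.0
    for f, val_vids in enumerate(split.folds):
        train_vids = [v for g, fold in enumerate(split.folds) if g != f for v in fold]
        cov = _sum_covs(covs, train_vids)
        model = fit_rcca(cov, lambda_A, lambda_V, n_components)
        a, v = _variates(model, corpus, val_vids)
        matched = matched_correlation(a, v, val_vids)
        null = mismatch_null(a, v, val_vids, n=null_size, seed=[seed, f])
        total += objective(matched, null, percentile)
    return total


def _log_uniform(rng, bounds, size):
    lo, hi = np.log10(bounds[0]), np.log10(bounds[1])
    return 10 ** rng.uniform(lo, hi, size=size)


def optimize_regularization(
    eval_fn,
    bounds: tuple = LAMBDA_BOUNDS,
    n_initial: int = 5,
    n_calls: int = 10,
    seed: int = 0,
    use_gp: bool = True,
    n_candidates: int = 512,
) -> SearchResult:
    """Maximize ``eval_fn(lambda_A, lambda_V)`` over the log-lambda square.

    Starts with ``n_initial`` log-uniform random evaluations; remaining
    calls are proposed by a Gaussian-process surrogate (Matern 5/2) with
    a hedged acquisition that chooses probabilistically among lower
    confidence bound, expected improvement and probability of
    improvement.  ``use_gp=False`` degrades to pure random search with
    the same interface.
    """
    if n_calls < n_initial:
        raise ValueError("budget n_calls must be >= n_initial random points")
    rng = np.random.default_rng(seed)
    X, y, acqs = [], [], []
    for _ in range(n_initial):
        lam = _log_uniform(rng, bounds, 2)
        X.append(np.log10(lam))
        y.append(float(eval_fn(lam[0], lam[1])))
        acqs.append("random")
    gains = np.zeros(3)  # hedge gains for (LCB, EI, PI)
    names = ("lcb", "ei", "pi")
    for _ in range(n_calls - n_initial):
        if not use_gp:
            lam = _log_uniform(rng, bounds, 2)
            X.append(np.log10(lam))
            y.append(float(eval_fn(lam[0], lam[1])))
            acqs.append("random")
            continue
        kernel = (ConstantKernel(1.0, (1e-3, 1e3))
                  * Matern(length_scale=1.0, length_scale_bounds=(0.1, 10.0), nu=2.5)
                  + WhiteKernel(1e-6, (1e-10, 1e1)))
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                      random_state=int(rng.integers(2**31)))
        gp.fit(np.asarray(X), np.asarray(y))
        cand = np.log10(_log_uniform(rng, bounds, (n_candidates, 2)))
        mu, sd = gp.predict(cand, return_std=True)
        sd = np.maximum(sd, 1e-12)
        best = max(y)
        z = (mu - best) / sd
        acq_scores = [
            mu + 1.96 * sd,  # upper confidence bound (maximization LCB analog)
            sd * (z * stats.norm.cdf(z) + stats.norm.pdf(z)),  # EI
            stats.norm.cdf(z),  # PI
        ]
        probs = np.exp(gains - gains.max())
        probs /= probs.sum()
        pick = int(rng.choice(3, p=probs))
        x_next = cand[np.argmax(acq_scores[pick])]
        lam = 10 ** x_next
        val = float(eval_fn(lam[0], lam[1]))
        X.append(x_next)
        y.append(val)
        acqs.append(names[pick])
        gains[pick] += val - np.median(y)  # reward acquisitions that found good points
    lambdas = [tuple(10 ** np.asarray(x)) for x in X]
    best_i = int(np.argmax(y))
    return SearchResult(lambdas=lambdas, objectives=list(map(float, y)),
                        acquisitions=acqs, best_lambda=lambdas[best_i],
                        best_objective=float(y[best_i]))


def finalize_and_test(
    corpus,
    split: SpeakerSplit,
    lambda_A: float,
    lambda_V: float,
    n_components: int | None = None,
    null_size: int = 1000,
    percentile: float = SIGNIFICANCE_PERCENTILE,
    min_correlation: float = MIN_REPORTED_CORRELATION,
    seed: int = 0,
    covs: dict | None = None,
) -> SignificanceResult:
    """Fit the final model on all training folds; decide significance on
    the speaker-disjoint test set.

    A component is significant if its matched test correlation exceeds
    the 95th percentile of the test-set mismatch null; it is *reported*
    only if additionally its correlation reaches the 1% floor.
    """
    if not split.test_videos:
        raise ValueError("empty test set")
    covs = covs if covs is not None else per_video_covariances(corpus)
    cov = _sum_covs(covs, split.train_videos)
    model = fit_rcca(cov, lambda_A, lambda_V, n_components)
    a, v = _variates(model, corpus, split.test_videos)
    matched = matched_correlation(a, v, split.test_videos)
    null = mismatch_null(a, v, split.test_videos, n=null_size, seed=[seed, 1013])
    sig = matched > null.percentile(percentile)
    reported = sig & (matched >= min_correlation)
    return SignificanceResult(model=model, test_correlations=matched, null=null,
                              significant=sig, reported=reported,
                              percentile=percentile, min_correlation=min_correlation)
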