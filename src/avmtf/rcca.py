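"""L2-regularized canonical correlation analysis (rCCA).

Given two per-video-standardized feature streams X_A (T x 25 envelope
modulation subbands) and X_V (T x 204 landmark coordinates), rCCA finds
weight pairs (w_A, w_V) maximizing

    rho = w_A' S_AV w_V / sqrt((w_A' S_A w_A + lam_A s_A |w_A|^2)
                               (w_V' S_V w_V + lam_V s_V |w_V|^2))

where S_A = X_A' X_A etc. are unnormalized (Gram) covariances pooled
over videos.  The regularizers are scaled by the mean diagonal of each
view's covariance (s_A = tr(S_A)/J_A), so lambda values in [1e-5, 1] are
comparable across views of different dimension; the convention is
recorded on every fitted model.

The solution is computed on the symmetric whitened operator
``R_A^{-1/2} S_AV R_V^{-1} S_AV' R_A^{-1/2}`` (R = S + lam*s*I) via an
eigendecomposition — equivalent to the generalized eigenvalue problem of
the Lagrangian formulation, but numerically better behaved.

Backward weights W are not directly interpretable as the mixing patterns
of the forward generative model X = S A + eps; the forward patterns are
recovered as canonical loadings A_hat = Sigma W (covariance between
features and variates), which this module also computes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "CovarianceSet",
    "RCCAModel",
    "accumulate_covariances",
    "fit_rcca",
    "project",
    "component_correlations",
]


@dataclass
class CovarianceSet:
    """Pooled unnormalized covariances of the two views."""

    sigma_A: np.ndarray
    sigma_V: np.ndarray
    sigma_AV: np.ndarray
    n_frames: int
    video_ids: list = field(default_factory=list)

    def __add__(self, other: "CovarianceSet") -> "CovarianceSet":
        return CovarianceSet(
            self.sigma_A + other.sigma_A,
            self.sigma_V + other.sigma_V,
            self.sigma_AV + other.sigma_AV,
            self.n_frames + other.n_frames,
            self.video_ids + other.video_ids,
        )


@dataclass
class RCCAModel:
    W_A: np.ndarray  # (J_A, J_0)
    W_V: np.ndarray  # (J_V, J_0)
    lambda_A: float
    lambda_V: float
    rho: np.ndarray  # (J_0,) training canonical correlations, non-increasing
    loadings_A: np.ndarray  # Sigma_A W_A / n  (J_A, J_0)
    loadings_V: np.ndarray  # Sigma_V W_V / n  (J_V, J_0)
    n_frames: int
    conventions: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.W_A.shape[1]


def accumulate_covariances(video_pairs) -> CovarianceSet:
    """Pool covariances over an iterable of (X_A, X_V[, video_id]) tuples.

    Covariances are sums of per-video Gram matrices — equivalent to the
    covariance of the concatenated (per-video standardized) data.
    """
    sa = sv = sav = None
    n = 0
    ids = []
    for item in video_pairs:
        if len(item) == 3:
            XA, XV, vid = item
        else:
            XA, XV = item
            vid = f"video{len(ids)}"
        XA = np.asarray(XA, float)
        XV = np.asarray(XV, float)
        if XA.shape[0] != XV.shape[0]:
            raise ValueError(
                f"frame-count mismatch in {vid}: audio {XA.shape[0]} vs video {XV.shape[0]}"
            )
        if sa is None:
            sa = np.zeros((XA.shape[1], XA.shape[1]))
            sv = np.zeros((XV.shape[1], XV.shape[1]))
            sav = np.zeros((XA.shape[1], XV.shape[1]))
        sa += XA.T @ XA
        sv += XV.T @ XV
        sav += XA.T @ XV
        n += XA.shape[0]
        ids.append(vid)
    if sa is None:
        raise ValueError("no video pairs supplied")
    return CovarianceSet(sa, sv, sav, n, ids)


def _inv_sqrt(M: np.ndarray, rcond: float = 1e-12) -> np.ndarray:
    vals, vecs = linalg.eigh(M)
    if vals[-1] <= 0:
        raise np.linalg.LinAlgError("covariance is not positive semidefinite")
    if vals[0] < rcond * vals[-1]:
        raise np.linalg.LinAlgError(
            "regularized covariance is numerically singular; "
            "use a regularization weight lambda > 0"
        )
    return (vecs / np.sqrt(vals)) @ vecs.T


def fit_rcca(
    cov: CovarianceSet,
    lambda_A: float = 0.0,
    lambda_V: float = 0.0,
    n_components: int | None = None,
) -> RCCAModel:
    """Solve the regularized CCA problem on pooled covariances.

    Components are ordered by decreasing rho.  Sign convention: each
    component is flipped so the largest-magnitude entry of its audio
    loading column is positive (ties: first index wins).
    """
    if lambda_A < 0 or lambda_V < 0:
        raise ValueError("regularization weights must be >= 0")
    SA, SV, SAV = cov.sigma_A, cov.sigma_V, cov.sigma_AV
    JA, JV = SA.shape[0], SV.shape[0]
    J0 = min(JA, JV) if n_components is None else min(n_components, JA, JV)
    sA = np.trace(SA) / JA
    sV = np.trace(SV) / JV
    RA = SA + lambda_A * sA * np.eye(JA)
    RV = SV + lambda_V * sV * np.eye(JV)
    RA_isqrt = _inv_sqrt(RA)
    # guard RV conditioning with the same diagnostic as RA
    _inv_sqrt(RV)
    K = RA_isqrt @ SAV  # (JA, JV)
    M = K @ linalg.solve(RV, K.T, assume_a="pos")
    M = 0.5 * (M + M.T)
    vals, vecs = linalg.eigh(M)
    order = np.argsort(vals)[::-1][:J0]
    rho = np.sqrt(np.clip(vals[order], 0.0, 1.0))
    U = vecs[:, order]
    W_A = RA_isqrt @ U  # w_A' R_A w_A = 1 per column
    raw_V = linalg.solve(RV, SAV.T @ W_A, assume_a="pos")
    scale = np.where(rho > 1e-12, rho, 1.0)
    W_V = raw_V / scale  # w_V' R_V w_V = 1 where rho > 0
    loadings_A = SA @ W_A / cov.n_frames
    loadings_V = SV @ W_V / cov.n_frames
    # deterministic sign: largest |audio loading| entry positive
    peak = np.abs(loadings_A).argmax(axis=0)
    flip = np.sign(loadings_A[peak, np.arange(J0)])
    flip[flip == 0] = 1.0
    W_A, W_V = W_A * flip, W_V * flip
    loadings_A, loadings_V = loadings_A * flip, loadings_V * flip
    return RCCAModel(
        W_A=W_A, W_V=W_V, lambda_A=lambda_A, lambda_V=lambda_V, rho=rho,
        loadings_A=loadings_A, loadings_V=loadings_V, n_frames=cov.n_frames,
        conventions={
            "lambda_scaling": "lambda * mean-diagonal of each view's Gram matrix",
            "sign": "largest-|entry| audio loading positive",
            "loading_scale": "Gram / n_frames",
        },
    )


def project(
    model: RCCAModel,
    X: np.ndarray,
    view: str = "audio",
    use_loadings: bool = False,
) -> np.ndarray:
    """Project features to component space: X W (variates) or X Sigma W."""
    X = np.asarray(X, float)
    if view == "audio":
        W = model.loadings_A if use_loadings else model.W_A
    elif view == "visual":
        W = model.loadings_V if use_loadings else model.W_V
    else:
        raise ValueError("view must be 'audio' or 'visual'")
    if X.shape[1] != W.shape[0]:
        raise ValueError(f"feature dimension {X.shape[1]} != expected {W.shape[0]}")
    return X @ W


def component_correlations(audio_variates: np.ndarray, visual_variates: np.ndarray) -> np.ndarray:
    """Pearson correlation per component between paired variate columns.

    Zero-variance variates yield correlation 0 (with a warning from the
    degenerate standard deviation being replaced)."""
    A = np.asarray(audio_variates, float)
    V = np.asarray(visual_variates, float)
    if A.shape != V.shape:
        raise ValueError(f"variate shapes differ: {A.shape} vs {V.shape}")
    A = A - A.mean(axis=0)
    V = V - V.mean(axis=0)
    sa = np.sqrt((A * A).sum(axis=0))
    sv = np.sqrt((V * V).sum(axis=0))
    dead = (sa == 0) | (sv == 0)
    if np.any(dead):
        import warnings

        warnings.warn(f"{int(dead.sum())} zero-variance variate(s); correlation set to 0",
                      stacklevel=2)
    denom = np.where(dead, 1.0, sa * sv)
    r = (A * V).sum(axis=0) / denom
    r[dead] = 0.0
    return r
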