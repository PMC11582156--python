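"""Patch-based Marchenko-Pastur PCA denoising of MT-weighted image stacks.

Random-matrix theory predicts that the eigenvalue spectrum of a pure-noise
data matrix follows the Marchenko-Pastur (MP) law; principal components of a
patch whose eigenvalues are indistinguishable from that law carry no signal
and can be removed, with the noise variance estimated jointly from the
discarded tail.  The tensor variant (tMPPCA) exploits the multidimensional
redundancy of qMT data - each sliding spatial patch is a (voxels x powers x
offsets) tensor that is denoised by sequential mode unfoldings (spatial mode
first, then powers, then offsets), each thresholded by the MP criterion.

A Gaussian filter (kernel SD 1 voxel per measurement volume) is kept as the
conventional low-pass baseline for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage

__all__ = [
    "DenoiseConfig",
    "DenoiseResult",
    "mppca_matrix",
    "tmppca",
    "gaussian_baseline",
]


@dataclass(frozen=True)
class DenoiseConfig:
    """Denoising method selection and patch geometry.

    ``window`` is the spatial patch edge length (odd), applied per spatial
    dimension; ``aggregation`` combines the overlapping patch estimates by
    plain averaging or keeps only the center voxel of each patch.
    """

    method: str = "tmppca"  # tmppca | gaussian
    window: int = 3
    aggregation: str = "average_overlaps"  # average_overlaps | center_voxel
    gaussian_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in ("tmppca", "gaussian"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.window % 2 != 1 or self.window < 1:
            raise ValueError("window must be an odd positive integer")
        if self.aggregation not in ("average_overlaps", "center_voxel"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.gaussian_sd <= 0:
            raise ValueError("gaussian_sd must be > 0")


@dataclass
class DenoiseResult:
    """Denoised stack plus patch-wise noise and rank diagnostics.

    ``denoised + removed == input`` exactly; ``sigma_map`` and ``rank_map``
    are indexed by patch center (empty for the Gaussian baseline).
    """

    denoised: np.ndarray
    removed: np.ndarray
    sigma_map: np.ndarray
    rank_map: np.ndarray


def mppca_matrix(patch: np.ndarray) -> tuple:
    """MP-PCA denoise one data matrix (n_samples x n_measurements).

    Returns ``(denoised, sigma2, rank)``.  Eigenvalues of the sample
    covariance are scanned from the largest; ``p`` components are kept when
    the remaining eigenvalue tail is consistent with the MP law, i.e. its
    spread does not exceed the MP support width 4 * sigma^2 * sqrt(gamma)
    with sigma^2 estimated as the mean of the tail itself (the standard
    cumulative-tail estimator).
    """
    X = np.asarray(patch, dtype=float)
    if X.ndim != 2 or min(X.shape) < 2:
        raise ValueError("patch must be a 2-D matrix with both dimensions >= 2")
    transposed = X.shape[0] < X.shape[1]
    if transposed:
        X = X.T
    N, M = X.shape  # N >= M
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    lam = s**2 / N  # covariance eigenvalues, descending
    rank = M
    sigma2 = 0.0
    # relative slack keeps an exactly low-rank (zero-noise-tail) matrix from
    # being misclassified through eigenvalue roundoff
    slack = 1e-12 * (lam[0] if lam[0] > 0 else 1.0)
    for p in range(M - 1):
        tail = lam[p:]
        sig2 = float(np.mean(tail))
        gamma = (M - p) / N
        if lam[p] - lam[-1] < 4.0 * sig2 * np.sqrt(gamma) + slack:
            rank = p
            sigma2 = sig2
            break
    s_d = s.copy()
    s_d[rank:] = 0.0
    den = (U * s_d) @ Vt
    if transposed:
        den = den.T
    return den, sigma2, int(rank)


def _tensor_denoise(T: np.ndarray) -> tuple:
    """Sequential-unfolding MP-PCA of one patch tensor.

    Unfolds along each mode in order (mode 0 = patch voxels, then powers,
    then offsets), MP-thresholding each unfolding of the progressively
    denoised tensor.  Returns (denoised tensor, sigma2 from the first
    unfolding, retained rank of the first unfolding).
    """
    out = np.asarray(T, dtype=float)
    sigma2 = 0.0
    rank = 0
    for mode in range(out.ndim):
        mat = np.moveaxis(out, mode, 0).reshape(out.shape[mode], -1)
        if min(mat.shape) < 2:
            continue
        den, sig2, r = mppca_matrix(mat.T)  # samples = other modes
        den = den.T.reshape(np.moveaxis(out, mode, 0).shape)
        out = np.moveaxis(den, 0, mode)
        if mode == 0:
            sigma2, rank = sig2, r
    return out, sigma2, rank


def tmppca(stack: np.ndarray, cfg: DenoiseConfig | None = None) -> DenoiseResult:
    """Sliding-window tensor MP-PCA of a stack [spatial..., powers, offsets].

    Works on 2-D (y, x) or 3-D (z, y, x) spatial grids; the window is
    ``cfg.window`` per spatial dimension (3x3 or 3x3x3 by default).
    Overlapping patch estimates are combined per ``cfg.aggregation``.
    """
    cfg = cfg or DenoiseConfig()
    stack = np.asarray(stack, dtype=float)
    if stack.ndim not in (4, 5):
        raise ValueError("stack must be [y, x, powers, offsets] or [z, y, x, powers, offsets]")
    if stack.shape[-2] * stack.shape[-1] < 2:
        raise ValueError(
            "tMPPCA needs at least two measurement volumes; use the Gaussian baseline"
        )
    n_spatial = stack.ndim - 2
    spatial = stack.shape[:n_spatial]
    w = cfg.window
    if any(s < w for s in spatial):
        raise ValueError(f"spatial dims {spatial} smaller than window {w}")
    half = w // 2
    centers = [range(half, s - half) for s in spatial]
    acc = np.zeros_like(stack)
    weight = np.zeros(spatial)
    sigma_map = np.zeros(spatial)
    rank_map = np.zeros(spatial, dtype=int)
    for idx in product(*centers):
        sl = tuple(slice(i - half, i + half + 1) for i in idx)
        patch = stack[sl]  # (w.. , P, O)
        T = patch.reshape(w**n_spatial, *stack.shape[-2:])
        den, sig2, rank = _tensor_denoise(T)
        den = den.reshape(patch.shape)
        sigma_map[idx] = np.sqrt(max(sig2, 0.0))
        rank_map[idx] = rank
        if cfg.aggregation == "average_overlaps":
            acc[sl] += den
            weight[sl] += 1.0
        else:
            ci = (half,) * n_spatial
            acc[idx] = den[ci]
            weight[idx] = 1.0
    # voxels never covered by a full window (image border) pass through
    uncovered = weight == 0
    out = np.where(
        uncovered[(...,) + (None,) * 2],
        stack,
        acc / np.where(uncovered, 1.0, weight)[(...,) + (None,) * 2],
    )
    return DenoiseResult(
        denoised=out, removed=stack - out, sigma_map=sigma_map, rank_map=rank_map
    )


def gaussian_baseline(stack: np.ndarray, cfg: DenoiseConfig | None = None) -> DenoiseResult:
    """Gaussian filtering of each (power, offset) volume in the spatial
    dimensions only (kernel SD ``cfg.gaussian_sd`` voxels, no mixing across
    measurement volumes)."""
    cfg = cfg or DenoiseConfig(method="gaussian")
    stack = np.asarray(stack, dtype=float)
    n_spatial = stack.ndim - 2
    sd = [cfg.gaussian_sd] * n_spatial + [0.0, 0.0]
    out = ndimage.gaussian_filter(stack, sigma=sd, mode="nearest")
    empty = np.zeros(stack.shape[:n_spatial])
    return DenoiseResult(
        denoised=out,
        removed=stack - out,
        sigma_map=empty,
        rank_map=empty.astype(int),
    )
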