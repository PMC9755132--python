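"""Nonlocal-PCA patch denoiser.

Groups of matched patches are treated as a patch matrix (patches x voxels),
mean-centred and decomposed along principal axes; components whose variance
exceeds the assumed noise variance sigma^2 are retained, the rest discarded,
and the reconstructed patches are aggregated with 1 / (1 + k_retained)
weights.  This is a texture-adaptive nonlocal-PCA scheme in the spirit of
clustering-plus-PCA denoisers; it is a simplified stand-in, not a
reimplementation of any reference codebase.
"""

from __future__ import annotations

import numpy as np

from .blockmatch import gather_groups, match_all
from .spec import DenoiserSpec

__all__ = ["nlpca_filter_group", "nlpca_denoise_array"]

_CHUNK = 8192


def nlpca_filter_group(group: np.ndarray, sigma: float):
    """PCA-shrink one group; returns (filtered group, weight).

    Groups with fewer than 2 patches pass through unchanged.
    """
    group = np.asarray(group, dtype=float)
    n = group.shape[0]
    if n < 2:
        return group.copy(), 1.0
    flat = group.reshape(n, -1)
    mean = flat.mean(axis=0, keepdims=True)
    xc = flat - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # per-voxel component variance; pure-noise components fall well below
    # sigma^2 at this normalisation (random-matrix edge ~ sigma^2 (sqrt(n) +
    # sqrt(p))^2 / ((n-1) p) < sigma^2 for n << p)
    var = s**2 / ((n - 1) * flat.shape[1])
    keep = var > sigma**2
    s_kept = np.where(keep, s, 0.0)
    recon = (u * s_kept) @ vt + mean
    weight = 1.0 / (1.0 + int(keep.sum()))
    return recon.reshape(group.shape), weight


def nlpca_denoise_array(arr: np.ndarray, spec: DenoiserSpec) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if spec.sigma is None or spec.sigma <= 0:
        raise ValueError("denoiser sigma must be set and positive")
    if any(n < spec.patch_size for n in arr.shape):
        return arr.copy()
    ref_corners, offsets, selection = match_all(arr, spec)
    shape = arr.shape
    acc = np.zeros(shape)
    wacc = np.zeros(shape)
    n_ref = ref_corners.shape[0]
    sigma = spec.sigma
    for start in range(0, n_ref, _CHUNK):
        sl = slice(start, start + _CHUNK)
        groups, corners = gather_groups(
            arr, ref_corners[sl], offsets, selection[sl], spec.patch_size
        )
        groups = np.ascontiguousarray(groups, dtype=float)
        m, g = groups.shape[:2]
        if g < 2:
            est = groups
            weights = np.ones(m)
        else:
            flat = groups.reshape(m, g, -1)
            mean = flat.mean(axis=1, keepdims=True)
            xc = flat - mean
            u, s, vt = np.linalg.svd(xc, full_matrices=False)
            var = s**2 / ((g - 1) * flat.shape[2])
            keep = var > sigma**2
            s_kept = np.where(keep, s, 0.0)
            recon = np.einsum("mgk,mk,mkv->mgv", u, s_kept, vt) + mean
            weights = 1.0 / (1.0 + keep.sum(axis=1))
            est = recon.reshape(groups.shape)
        from .collaborative import _scatter_add

        _scatter_add(acc, wacc, est, weights, corners, shape)
    if np.any(wacc == 0):
        raise RuntimeError("aggregation left uncovered voxels (stride contract violated)")
    return acc / wacc
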