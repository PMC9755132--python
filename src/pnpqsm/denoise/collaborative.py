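"""Collaborative filtering and aggregation for block-matching denoisers.

A matched group of patches is pushed through a separable orthonormal cosine
transform applied across the patch dimensions *and* the grouping dimension,
its coefficients are hard-thresholded (the group DC is always kept), and the
filtered patches are averaged back into the volume with per-group weights
1 / (1 + N_retained).  The volumetric variant (3D patches) and the
slice-by-slice variant (2D patches per axial slice) share this machinery.
An optional second pass replaces hard thresholding by empirical Wiener
shrinkage driven by the first-pass estimate.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import dctn, idctn

from .blockmatch import gather_groups, match_all
from .spec import DenoiserSpec

__all__ = ["collaborative_filter", "aggregate", "bm_collaborative_denoise"]

_CHUNK = 16384  # reference patches per processing chunk (bounds memory)


def collaborative_filter(group: np.ndarray, spec: DenoiserSpec):
    """Filter one matched group; returns (filtered group, aggregation weight).

    ``group`` has shape (n_patches, *patch_shape).  The transform is the
    orthonormal DCT-II over every axis (grouping axis included); coefficients
    with magnitude below ``hard_threshold_factor * sigma`` are zeroed, except
    the group-wide DC which is always retained.  The weight follows the
    1 / (1 + N_retained) convention, N_retained counting surviving
    coefficients.
    """
    group = np.asarray(group, dtype=float)
    if group.size == 0:
        raise ValueError("empty group")
    if spec.sigma is None or spec.sigma <= 0:
        raise ValueError("collaborative_filter requires a positive sigma")
    coeffs = dctn(group, norm="ortho")
    thr = spec.hard_threshold_factor * spec.sigma
    keep = np.abs(coeffs) >= thr
    keep[(0,) * group.ndim] = True  # group DC survives
    coeffs = np.where(keep, coeffs, 0.0)
    n_retained = int(np.count_nonzero(coeffs))
    weight = 1.0 / (1.0 + n_retained)
    return idctn(coeffs, norm="ortho"), weight


def aggregate(groups, corners, weights, shape) -> np.ndarray:
    """Weighted per-voxel average of overlapping patch estimates.

    ``groups`` iterates over (group_size, *patch_shape) arrays, ``corners``
    over matching (group_size, ndim) integer corner arrays, ``weights`` over
    scalar per-group weights.  Every voxel must be covered by at least one
    patch (guaranteed upstream by stride <= patch_size); identity filtering
    reproduces the input exactly up to floating-point roundoff.
    """
    shape = tuple(shape)
    acc = np.zeros(shape)
    wacc = np.zeros(shape)
    for grp, crn, w in zip(groups, corners, weights):
        grp = np.asarray(grp, dtype=float)
        crn = np.asarray(crn, dtype=np.intp)
        p = grp.shape[1:]
        for patch, corner in zip(grp, crn):
            sl = tuple(slice(c, c + pl) for c, pl in zip(corner, p))
            acc[sl] += w * patch
            wacc[sl] += w
    if np.any(wacc == 0):
        raise RuntimeError("aggregation left uncovered voxels (stride contract violated)")
    return acc / wacc


def _batch_filter_hard(groups: np.ndarray, sigma: float, factor: float):
    """Vectorised `collaborative_filter` over a stack of equally sized groups."""
    axes = tuple(range(1, groups.ndim))
    coeffs = dctn(groups, axes=axes, norm="ortho")
    thr = factor * sigma
    keep = np.abs(coeffs) >= thr
    keep[(slice(None),) + (0,) * (groups.ndim - 1)] = True
    coeffs *= keep
    n_retained = keep.reshape(groups.shape[0], -1).sum(axis=1)
    weights = 1.0 / (1.0 + n_retained)
    return idctn(coeffs, axes=axes, norm="ortho"), weights


def _batch_filter_wiener(groups: np.ndarray, pilot: np.ndarray, sigma: float):
    """Empirical Wiener shrinkage with the first-pass estimate as pilot."""
    axes = tuple(range(1, groups.ndim))
    coeffs = dctn(groups, axes=axes, norm="ortho")
    pilot_c = dctn(pilot, axes=axes, norm="ortho")
    shrink = pilot_c**2 / (pilot_c**2 + sigma**2)
    coeffs *= shrink
    w_energy = shrink.reshape(groups.shape[0], -1).sum(axis=1)
    weights = 1.0 / (1.0 + w_energy)
    return idctn(coeffs, axes=axes, norm="ortho"), weights


def _scatter_add(acc, wacc, est, weights, corners, shape):
    """Accumulate weighted patch estimates via flat bincount."""
    ndim = len(shape)
    p = est.shape[2:]
    grid = np.indices(p).reshape(ndim, -1)  # (ndim, patch_voxels)
    lin = np.zeros(corners.shape[:2] + (grid.shape[1],), dtype=np.intp)
    stride_acc = 1
    strides = np.empty(ndim, dtype=np.intp)
    for ax in range(ndim - 1, -1, -1):
        strides[ax] = stride_acc
        stride_acc *= shape[ax]
    for ax in range(ndim):
        lin += (corners[..., ax, None] + grid[ax]) * strides[ax]
    vals = est.reshape(est.shape[0], est.shape[1], -1) * weights[:, None, None]
    wvals = np.broadcast_to(weights[:, None, None], vals.shape)
    size = int(np.prod(shape))
    acc += np.bincount(lin.ravel(), weights=vals.ravel(), minlength=size).reshape(shape)
    wacc += np.bincount(lin.ravel(), weights=wvals.ravel(), minlength=size).reshape(shape)


def bm_collaborative_denoise(arr: np.ndarray, spec: DenoiserSpec) -> np.ndarray:
    """Full block-matching collaborative-filtering pipeline on one array.

    Works for 2D (slice-wise variant) and 3D (volumetric variant) inputs.
    Inputs smaller than one patch in any dimension are returned unchanged.
    """
    arr = np.asarray(arr, dtype=float)
    if spec.sigma is None or spec.sigma <= 0:
        raise ValueError("denoiser sigma must be set and positive")
    if any(n < spec.patch_size for n in arr.shape):
        return arr.copy()

    ref_corners, offsets, selection = match_all(arr, spec)
    est = _run_stage(arr, arr, ref_corners, offsets, selection, spec, stage="hard")
    if spec.wiener_stage:
        # re-match on the cleaner first-pass estimate, Wiener-filter the data
        ref_corners, offsets, selection = match_all(est, spec)
        est = _run_stage(arr, est, ref_corners, offsets, selection, spec, stage="wiener")
    return est


def _run_stage(noisy, pilot, ref_corners, offsets, selection, spec, stage):
    shape = noisy.shape
    acc = np.zeros(shape)
    wacc = np.zeros(shape)
    n_ref = ref_corners.shape[0]
    for start in range(0, n_ref, _CHUNK):
        sl = slice(start, start + _CHUNK)
        groups, corners = gather_groups(
            noisy, ref_corners[sl], offsets, selection[sl], spec.patch_size
        )
        groups = np.ascontiguousarray(groups, dtype=float)
        if stage == "hard":
            est, weights = _batch_filter_hard(
                groups, spec.sigma, spec.hard_threshold_factor
            )
        else:
            pgroups, _ = gather_groups(
                pilot, ref_corners[sl], offsets, selection[sl], spec.patch_size
            )
            est, weights = _batch_filter_wiener(
                groups, np.ascontiguousarray(pgroups, dtype=float), spec.sigma
            )
        _scatter_add(acc, wacc, est, weights, corners, shape)
    if np.any(wacc == 0):
        raise RuntimeError("aggregation left uncovered voxels (stride contract violated)")
    return acc / wacc
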