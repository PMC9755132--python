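"""Block matching: find groups of mutually similar patches.

Two code paths implement the same contract.  `block_match` is the exact,
loop-free-but-per-reference definition used by tests and tiny inputs: it
scans every candidate corner within the search window, ranks by mean squared
distance and breaks ties by lexicographic corner order, with the reference
patch always first.  `match_all` is the vectorised production path: patch
distances for every (corner, offset) pair are obtained from cumulative-sum
window sums, one pass per offset, and the best ``max_group_size`` offsets are
selected per reference with a deterministic partial sort.
"""

from __future__ import annotations

import itertools

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .spec import DenoiserSpec

__all__ = ["block_match", "match_all"]


def block_match(volume: np.ndarray, reference_patch_corner, spec: DenoiserSpec):
    """Corners of the <= max_group_size patches most similar to the reference.

    Candidates are all patch corners within ``spec.search_radius`` (Chebyshev
    distance, per axis) of the reference corner that fit inside the volume.
    Similarity is mean squared distance over the patch; the reference is
    always first, remaining ties resolved by lexicographic corner order.
    """
    vol = np.asarray(volume, dtype=float)
    p = spec.patch_size
    if any(p > n for n in vol.shape):
        raise ValueError(f"patch size {p} exceeds volume shape {vol.shape}")
    ref = tuple(int(c) for c in reference_patch_corner)
    if any(c < 0 or c + p > n for c, n in zip(ref, vol.shape)):
        raise ValueError(f"reference patch corner {ref} not fully inside volume")

    ref_patch = vol[tuple(slice(c, c + p) for c in ref)]
    r = spec.search_radius
    candidates = []
    ranges = [
        range(max(0, c - r), min(n - p, c + r) + 1) for c, n in zip(ref, vol.shape)
    ]
    for corner in itertools.product(*ranges):
        if corner == ref:
            continue
        patch = vol[tuple(slice(c, c + p) for c in corner)]
        d = float(np.mean((patch - ref_patch) ** 2))
        candidates.append((d, corner))
    candidates.sort(key=lambda t: (t[0], t[1]))
    return [ref] + [c for _, c in candidates[: spec.max_group_size - 1]]


def _corner_window_sum(w: np.ndarray, p: int) -> np.ndarray:
    """Sum of w over every p-window; output shape (n_i - p + 1, ...)."""
    out = w
    for ax in range(w.ndim):
        c = np.cumsum(out, axis=ax, dtype=np.float64)
        pad_shape = list(c.shape)
        pad_shape[ax] = 1
        c = np.concatenate([np.zeros(pad_shape, dtype=c.dtype), c], axis=ax)
        hi = [slice(None)] * c.ndim
        lo = [slice(None)] * c.ndim
        hi[ax] = slice(p, c.shape[ax])
        lo[ax] = slice(0, c.shape[ax] - p)
        out = c[tuple(hi)] - c[tuple(lo)]
    return out


def _reference_corners(n: int, p: int, stride: int) -> np.ndarray:
    corners = list(range(0, n - p + 1, stride))
    if corners[-1] != n - p:
        corners.append(n - p)
    return np.asarray(corners, dtype=np.intp)


def match_all(volume: np.ndarray, spec: DenoiserSpec):
    """Vectorised matching over a stride grid of reference corners.

    Returns ``(ref_corners, offsets, selection)`` where ``ref_corners`` is
    (n_ref, ndim), ``offsets`` is (n_off, ndim) in lexicographic order, and
    ``selection`` is (n_ref, group_size) indices into ``offsets`` (the zero
    offset always first).  Group size is ``spec.max_group_size`` capped by
    the number of valid candidates of the worst-placed reference.
    """
    vol = np.ascontiguousarray(volume, dtype=np.float32)
    p = spec.patch_size
    ndim = vol.ndim
    if any(p > n for n in vol.shape):
        raise ValueError(f"patch size {p} exceeds volume shape {vol.shape}")
    r = spec.search_radius
    stride = spec.effective_stride

    axes_corners = [_reference_corners(n, p, stride) for n in vol.shape]
    mesh = np.meshgrid(*axes_corners, indexing="ij")
    ref_corners = np.stack([m.ravel() for m in mesh], axis=1)  # (n_ref, ndim)
    n_ref = ref_corners.shape[0]

    offsets = np.array(
        list(itertools.product(*[range(-r, r + 1)] * ndim)), dtype=np.intp
    )  # lexicographic by construction
    n_off = offsets.shape[0]
    zero_idx = int(np.flatnonzero((offsets == 0).all(axis=1))[0])

    dist = np.full((n_ref, n_off), np.inf, dtype=np.float32)
    nmax = np.array(vol.shape) - p  # max valid corner per axis
    for oi, off in enumerate(offsets):
        if oi == zero_idx:
            dist[:, oi] = -1.0  # reference always sorts first
            continue
        lo = np.maximum(0, -off)
        hi = np.minimum(nmax, nmax - off)
        if np.any(hi < lo):
            continue
        sl_a = tuple(slice(l, h + p) for l, h in zip(lo, hi))
        sl_b = tuple(slice(l + o, h + o + p) for l, h, o in zip(lo, hi, off))
        d2 = vol[sl_a] - vol[sl_b]
        np.square(d2, out=d2)
        ws = _corner_window_sum(d2, p)
        valid = np.all((ref_corners >= lo) & (ref_corners <= hi), axis=1)
        idx = tuple((ref_corners[valid] - lo).T)
        dist[valid, oi] = ws[idx]

    n_valid_min = int(np.min(np.sum(np.isfinite(dist), axis=1)))
    group_size = min(spec.max_group_size, n_valid_min)

    if group_size < n_off:
        part = np.argpartition(dist, group_size - 1, axis=1)[:, :group_size]
    else:
        part = np.broadcast_to(np.arange(n_off), (n_ref, n_off)).copy()
    part_d = np.take_along_axis(dist, part, axis=1)
    order = np.argsort(part_d, axis=1, kind="stable")
    selection = np.take_along_axis(part, order, axis=1)
    return ref_corners, offsets, selection


def gather_groups(volume: np.ndarray, ref_corners, offsets, selection, patch_size: int):
    """Stack the matched patches: output (n_ref, group_size, *patch_shape)."""
    vol = np.asarray(volume)
    ndim = vol.ndim
    windows = sliding_window_view(vol, (patch_size,) * ndim)
    corners = ref_corners[:, None, :] + offsets[selection]  # (n_ref, g, ndim)
    return windows[tuple(corners[..., ax] for ax in range(ndim))], corners
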