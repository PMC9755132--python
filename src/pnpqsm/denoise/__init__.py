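"""Pluggable denoiser family for the plug-and-play v-subproblem.

Registered denoisers (all deterministic, constant volumes are fixed points):

==============  ==============================================================
``identity``    pass-through (useful for solver limit tests)
``gaussian``    isotropic Gaussian smoothing, width = sigma voxels
``nlm``         non-local means (scikit-image)
``bm3d_slices`` block-matching collaborative filtering, 2D patches per axial
                slice
``bm4d``        volumetric block-matching collaborative filtering (3D
                patches grouped along a 4th dimension)
``nlpca``       nonlocal-PCA patch shrinkage
==============  ==============================================================

All share the ``denoise(volume, spec)`` entry point; when the volume carries
a mask, denoising runs on the bounding box of the mask (padded by one patch)
and is the identity outside it.
"""

from __future__ import annotations

import numpy as np

from ..volume import VolumeGrid
from .blockmatch import block_match, match_all
from .collaborative import aggregate, bm_collaborative_denoise, collaborative_filter
from .nlpca import nlpca_denoise_array, nlpca_filter_group
from .spec import DenoiserSpec

__all__ = [
    "DenoiserSpec",
    "denoise",
    "nlpca_denoise",
    "block_match",
    "collaborative_filter",
    "aggregate",
    "registered_denoisers",
]


def _identity(arr: np.ndarray, spec: DenoiserSpec) -> np.ndarray:
    return arr.copy()


def _gaussian(arr: np.ndarray, spec: DenoiserSpec) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(arr, sigma=spec.sigma)


def _nlm(arr: np.ndarray, spec: DenoiserSpec) -> np.ndarray:
    from skimage.restoration import denoise_nl_means

    return denoise_nl_means(
        arr,
        patch_size=spec.patch_size,
        patch_distance=spec.search_radius,
        h=0.8 * spec.sigma,
        sigma=spec.sigma,
        fast_mode=True,
    )


def _bm3d_slices(arr: np.ndarray, spec: DenoiserSpec) -> np.ndarray:
    out = np.empty_like(arr, dtype=float)
    for k in range(arr.shape[2]):  # axial = third axis
        out[:, :, k] = bm_collaborative_denoise(arr[:, :, k], spec)
    return out


_REGISTRY = {
    "identity": _identity,
    "gaussian": _gaussian,
    "nlm": _nlm,
    "bm3d_slices": _bm3d_slices,
    "bm4d": bm_collaborative_denoise,
    "nlpca": nlpca_denoise_array,
}


def registered_denoisers() -> list[str]:
    return sorted(_REGISTRY)


def denoise(volume: VolumeGrid, spec: DenoiserSpec) -> VolumeGrid:
    """Apply the denoiser named by ``spec`` to a volume.

    Requires a positive ``spec.sigma`` (except for the identity).  With a
    mask, the denoiser sees only the padded bounding box of the mask; voxels
    outside the box are returned untouched.
    """
    if spec.name not in _REGISTRY:
        raise KeyError(
            f"unknown denoiser {spec.name!r}; registered: {registered_denoisers()}"
        )
    if spec.name != "identity" and (spec.sigma is None or spec.sigma <= 0):
        raise ValueError("denoiser sigma must be set and positive")
    if not np.all(np.isfinite(volume.data)):
        raise ValueError("denoiser input contains non-finite values")
    fn = _REGISTRY[spec.name]
    data = np.asarray(volume.data, dtype=float)
    if volume.mask is not None and not volume.mask.all():
        if not volume.mask.any():
            return volume.with_data(data.copy())
        idx = np.nonzero(volume.mask)
        pad = spec.patch_size
        box = tuple(
            slice(max(0, int(i.min()) - pad), min(n, int(i.max()) + 1 + pad))
            for i, n in zip(idx, data.shape)
        )
        out = data.copy()
        out[box] = fn(data[box], spec)
        return volume.with_data(out)
    return volume.with_data(fn(data, spec))


def nlpca_denoise(volume: VolumeGrid, spec: DenoiserSpec) -> VolumeGrid:
    """Nonlocal-PCA denoiser entry point (same contract as `denoise`)."""
    from dataclasses import replace

    return denoise(volume, replace(spec, name="nlpca"))
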