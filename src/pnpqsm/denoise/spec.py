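"""Denoiser specification shared by the whole pluggable family."""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class DenoiserSpec:
    """Parameters of a registered denoiser D_sigma.

    ``sigma`` is the assumed noise standard deviation in image units; inside
    the plug-and-play loop it defaults to sqrt(alpha/beta) (the
    proximal-operator correspondence) when left ``None``.  ``patch_size`` is
    the patch edge length in voxels (cubes for volumetric denoisers, squares
    for the slice-wise one), ``search_radius`` the Chebyshev radius of the
    block-matching window, ``max_group_size`` the number of patches stacked
    per group.  ``hard_threshold_factor`` scales sigma into the
    hard-threshold level of the collaborative filter;  ``wiener_stage``
    enables the optional second (empirical Wiener) pass.
    """

    name: str = "bm4d"
    sigma: float | None = None
    patch_size: int = 4
    search_radius: int = 3
    max_group_size: int = 8
    hard_threshold_factor: float = 2.7
    wiener_stage: bool = False
    stride: int | None = None  # reference-patch stride; default patch_size // 2

    def __post_init__(self) -> None:
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError(f"denoiser sigma must be > 0, got {self.sigma}")
        if self.patch_size < 2:
            raise ValueError(f"patch_size must be >= 2, got {self.patch_size}")
        if self.max_group_size < 1:
            raise ValueError(f"max_group_size must be >= 1, got {self.max_group_size}")
        if self.search_radius < 1:
            raise ValueError(f"search_radius must be >= 1, got {self.search_radius}")

    @property
    def effective_stride(self) -> int:
        if self.stride is not None:
            return max(1, int(self.stride))
        return max(1, self.patch_size // 2)

    def with_sigma(self, sigma: float) -> "DenoiserSpec":
        return replace(self, sigma=float(sigma))
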