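"""3D scalar volumes with voxel geometry.

``VolumeGrid`` is the carrier for every field in the pipeline: the
susceptibility map chi (ppm), the local tissue field phi (ppm, i.e. field
offset normalised by B0), magnitude images, masks and ROI label maps.  It
bundles the array with the voxel size in mm, the main-field direction and an
optional binary mask.  Arrays use a fixed (x, y, z) axis order with 0-based
indices; NIfTI affine handling lives at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["VolumeGrid", "InvalidGeometryError"]


class InvalidGeometryError(ValueError):
    """Raised for non-positive voxel sizes, shape mismatches or a zero B0."""


def _as_unit_b0(b0_dir) -> np.ndarray:
    b0 = np.asarray(b0_dir, dtype=float)
    if b0.shape != (3,):
        raise InvalidGeometryError(f"b0_dir must be a 3-vector, got shape {b0.shape}")
    norm = float(np.linalg.norm(b0))
    if norm == 0.0:
        raise InvalidGeometryError("b0_dir must be a nonzero vector")
    if abs(norm - 1.0) > 1e-9:
        logger.warning("b0_dir has norm %.6g; normalizing to a unit vector", norm)
        b0 = b0 / norm
    return b0


@dataclass
class VolumeGrid:
    """A 3D real scalar field on a regular grid.

    Parameters
    ----------
    data
        3D real array, axis order (x, y, z).
    voxel_size
        Voxel edge lengths ``(dx, dy, dz)`` in mm, strictly positive.
    b0_dir
        Unit vector of the main magnetic field; non-unit inputs are
        normalised with a warning.
    mask
        Optional binary array of the same shape (values in {0, 1}).
    units_label
        Free-text unit tag, e.g. ``"ppm"`` or ``"normalized field"``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    b0_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    mask: np.ndarray | None = None
    units_label: str = "ppm"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvalidGeometryError(f"data must be 3D, got ndim={self.data.ndim}")
        if np.iscomplexobj(self.data):
            raise InvalidGeometryError("data must be real-valued")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise InvalidGeometryError(f"voxel sizes must be positive, got {vs}")
        self.voxel_size = vs
        self.b0_dir = _as_unit_b0(self.b0_dir)
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.data.shape:
                raise InvalidGeometryError(
                    f"mask shape {self.mask.shape} != data shape {self.data.shape}"
                )
            vals = np.unique(self.mask)
            if not np.all(np.isin(vals, (0, 1))):
                raise InvalidGeometryError("mask values must be in {0, 1}")
            self.mask = self.mask.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, units_label: str | None = None) -> "VolumeGrid":
        """Return a copy carrying the same grid metadata but new voxel data."""
        return replace(
            self,
            data=np.asarray(data),
            units_label=self.units_label if units_label is None else units_label,
        )

    def masked(self) -> np.ndarray:
        """Data with mask-external voxels zeroed (identity if no mask)."""
        if self.mask is None:
            return self.data
        return self.data * self.mask
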