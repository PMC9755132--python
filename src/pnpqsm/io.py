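"""NIfTI I/O and unit conversion.

Volumes are stored internally in a fixed (x, y, z) axis order with voxel
sizes taken from the NIfTI header; the affine is preserved on write.  World
coordinates only exist at this boundary.  Susceptibility and field maps are
kept in ppm internally; conversion from radians uses the proton
gyromagnetic ratio and explicit TE/B0.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .volume import VolumeGrid

__all__ = [
    "read_volume",
    "write_volume",
    "radians_to_ppm",
    "ppm_to_radians",
    "GYROMAGNETIC_RATIO_MHZ_PER_T",
]

GYROMAGNETIC_RATIO_MHZ_PER_T = 42.577478518  # proton, MHz/T


def read_volume(path, b0_dir=(0.0, 0.0, 1.0), units_label: str = "ppm") -> VolumeGrid:
    """Load a 3D NIfTI volume (4D accepted only with a singleton last dim)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if data.shape[3] != 1:
            raise ValueError(f"expected 3D volume, got 4D with {data.shape[3]} frames")
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    vol = VolumeGrid(
        data.astype(np.float64),
        voxel_size=tuple(float(z) for z in zooms),
        b0_dir=b0_dir,
        units_label=units_label,
    )
    vol.affine = img.affine  # kept for round-trip writes
    return vol


def write_volume(volume: VolumeGrid, path) -> None:
    """Write a volume as NIfTI-1; voxel sizes go into the header zooms."""
    affine = getattr(volume, "affine", None)
    if affine is None:
        affine = np.diag(list(volume.voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), affine)
    img.header.set_zooms(volume.voxel_size)
    img.header["descrip"] = volume.units_label.encode()[:79]
    nib.save(img, str(path))


def _rad_ppm_factor(te_ms: float, b0_t: float) -> float:
    if te_ms <= 0 or b0_t <= 0:
        raise ValueError("TE and B0 must be positive")
    gamma_hz = GYROMAGNETIC_RATIO_MHZ_PER_T * 1e6
    return 2.0 * np.pi * gamma_hz * b0_t * (te_ms * 1e-3) * 1e-6  # rad per ppm


def radians_to_ppm(field: VolumeGrid, te_ms: float, b0_t: float) -> VolumeGrid:
    """Convert a phase-offset field from radians at TE to ppm of B0."""
    return field.with_data(field.data / _rad_ppm_factor(te_ms, b0_t), units_label="ppm")


def ppm_to_radians(field: VolumeGrid, te_ms: float, b0_t: float) -> VolumeGrid:
    """Inverse of `radians_to_ppm`."""
    return field.with_data(field.data * _rad_ppm_factor(te_ms, b0_t), units_label="rad")
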