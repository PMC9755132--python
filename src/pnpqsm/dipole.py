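"""Fourier-domain dipole kernel and the forward/adjoint QSM operators.

The local field perturbation phi produced by an isotropic susceptibility
distribution chi is a convolution with the unit dipole response.  In the
Fourier domain the convolution is a pointwise multiplication by

    D(k) = 1/3 - (k . b0)^2 / |k|^2

where k is the physical spatial-frequency vector (cycles/mm) and b0 the unit
main-field direction.  D vanishes on the magic-angle cone (angle ~54.7 deg to
b0), which is what makes single-orientation dipole inversion ill-posed.  The
value at k = 0 is undefined by the formula; by convention we set it to 0,
which enforces a zero-mean field response.

All operators use plain (circular) FFTs; `forward_field` offers an optional
pad-by-2 mode for sources close to the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import InvalidGeometryError, VolumeGrid, _as_unit_b0

__all__ = [
    "DipoleKernel",
    "build_dipole_kernel",
    "forward_field",
    "adjoint_field",
    "tkd_invert",
]


@dataclass(frozen=True)
class DipoleKernel:
    """Dipole kernel sampled on the unshifted FFT frequency grid.

    ``values`` lie in [-2/3, 1/3]; ``values[0, 0, 0]`` equals ``dc_value``.
    The kernel is real and even (D(-k) = D(k)), hence the induced linear
    operator is self-adjoint.
    """

    values: np.ndarray
    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    b0_dir: np.ndarray
    dc_value: float = 0.0


def build_dipole_kernel(
    shape,
    voxel_size=(1.0, 1.0, 1.0),
    b0_dir=(0.0, 0.0, 1.0),
    dc_value: float = 0.0,
) -> DipoleKernel:
    """Sample D(k) = 1/3 - (k.b0)^2/|k|^2 on the FFT grid of ``shape``.

    Frequencies are physical (cycles/mm): component i is
    ``fftfreq(shape[i]) / voxel_size[i]``, so anisotropic voxels tilt the
    magic-angle cone correctly.  The singular value at k = 0 is replaced by
    ``dc_value`` (default 0, the zero-mean-field convention).
    """
    shape = tuple(int(n) for n in shape)
    if len(shape) != 3 or any(n < 4 for n in shape):
        raise InvalidGeometryError(f"shape must be 3 ints >= 4, got {shape}")
    vs = tuple(float(v) for v in voxel_size)
    if any(v <= 0 for v in vs):
        raise InvalidGeometryError(f"voxel sizes must be positive, got {vs}")
    b0 = _as_unit_b0(b0_dir)

    freqs = [np.fft.fftfreq(n, d=d) for n, d in zip(shape, vs)]
    kx, ky, kz = np.meshgrid(*freqs, indexing="ij", sparse=True)
    k_par = kx * b0[0] + ky * b0[1] + kz * b0[2]
    k2 = kx**2 + ky**2 + kz**2
    with np.errstate(divide="ignore", invalid="ignore"):
        values = 1.0 / 3.0 - np.where(k2 > 0, k_par**2 / np.where(k2 > 0, k2, 1.0), 0.0)
    values[0, 0, 0] = float(dc_value)
    return DipoleKernel(values=values, shape=shape, voxel_size=vs, b0_dir=b0, dc_value=float(dc_value))


def _check_shapes(vol: VolumeGrid, kernel: DipoleKernel) -> None:
    if vol.shape != tuple(kernel.shape):
        raise InvalidGeometryError(
            f"volume shape {vol.shape} does not match kernel shape {kernel.shape}"
        )


def _apply_kernel(data: np.ndarray, values: np.ndarray) -> np.ndarray:
    return np.fft.ifftn(values * np.fft.fftn(data)).real


def forward_field(chi: VolumeGrid, kernel: DipoleKernel, pad: bool = False) -> VolumeGrid:
    """Field perturbation induced by ``chi``: F^H { D F chi }, real part.

    With ``pad=True`` the volume is zero-padded by a factor of two per axis
    before the circular convolution and trimmed afterwards, suppressing
    wrap-around from sources near the boundary.
    """
    _check_shapes(chi, kernel)
    if pad:
        big_shape = tuple(2 * n for n in kernel.shape)
        big_kernel = build_dipole_kernel(
            big_shape, kernel.voxel_size, kernel.b0_dir, kernel.dc_value
        )
        big = np.zeros(big_shape)
        sl = tuple(slice(0, n) for n in chi.shape)
        big[sl] = chi.data
        out = _apply_kernel(big, big_kernel.values)[sl]
    else:
        out = _apply_kernel(chi.data, kernel.values)
    return chi.with_data(out)


def adjoint_field(phi: VolumeGrid, kernel: DipoleKernel) -> VolumeGrid:
    """Adjoint of `forward_field`; equal to it since D is real and even."""
    _check_shapes(phi, kernel)
    return phi.with_data(_apply_kernel(phi.data, kernel.values))


def tkd_invert(phi: VolumeGrid, kernel: DipoleKernel, threshold: float = 0.19) -> VolumeGrid:
    """Truncated k-space division: direct inversion with a clipped kernel.

    Kernel magnitudes below ``threshold`` are clipped to
    ``sign(D) * threshold`` (sign(0) treated as +1) before dividing, which
    bounds noise amplification near the magic-angle cone at the price of
    underestimated susceptibility.
    """
    if not (0.0 < threshold < 2.0 / 3.0):
        raise ValueError(f"TKD threshold must lie in (0, 2/3), got {threshold}")
    _check_shapes(phi, kernel)
    d = kernel.values
    sign = np.where(d >= 0, 1.0, -1.0)
    d_trunc = np.where(np.abs(d) >= threshold, d, sign * threshold)
    chi = np.fft.ifftn(np.fft.fftn(phi.data) / d_trunc).real
    return phi.with_data(chi, units_label="ppm")
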