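"""Synthetic susceptibility phantoms, analytic oracles and noisy observations.

Everything a solver or metric needs is generated here, so the whole pipeline
is testable without scanner data: piecewise-constant susceptibility maps
with labelled inclusions, the closed-form field of a uniformly magnetised
sphere (an analytic oracle for the dipole convolution), Gaussian field noise
with a fixed seed, and a brain-like phantom whose ROI susceptibilities span
the physiologic range with thin vessel structures to probe sharpness.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dipole import DipoleKernel, forward_field
from .volume import InvalidGeometryError, VolumeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "Inclusion",
    "PhantomSpec",
    "NoiseSpec",
    "make_phantom",
    "analytic_sphere_field",
    "simulate_observation",
    "make_brainlike_phantom",
]


@dataclass(frozen=True)
class Inclusion:
    """One geometric inclusion: kind in {sphere, ellipsoid, cuboid}.

    ``center`` and ``size`` are in mm; for a sphere ``size`` is the radius,
    for an ellipsoid the three semi-axes, for a cuboid the three full edge
    lengths.  ``susceptibility`` is in ppm, ``label`` a unique positive id.
    """

    kind: str
    center: tuple[float, float, float]
    size: tuple[float, float, float] | float
    susceptibility: float
    label: int


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    inclusions: list[Inclusion] = field(default_factory=list)
    background_susceptibility: float = 0.0
    texture_amplitude: float = 0.0
    texture_seed: int = 0

    def __post_init__(self) -> None:
        labels = [inc.label for inc in self.inclusions]
        if any(l <= 0 for l in labels):
            raise ValueError("inclusion labels must be positive")
        if len(set(labels)) != len(labels):
            raise ValueError("inclusion labels must be unique")


@dataclass(frozen=True)
class NoiseSpec:
    """I.i.d. Gaussian field noise: standard deviation in field units (ppm)."""

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"noise sigma must be >= 0, got {self.sigma}")


def _voxel_centers(shape, voxel_size):
    axes = [(np.arange(n) + 0.5) * d for n, d in zip(shape, voxel_size)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _inclusion_membership(inc: Inclusion, shape, voxel_size) -> np.ndarray:
    x, y, z = _voxel_centers(shape, voxel_size)
    cx, cy, cz = inc.center
    if inc.kind == "sphere":
        r = float(inc.size) if np.isscalar(inc.size) else float(inc.size[0])
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r**2
    if inc.kind == "ellipsoid":
        a, b, c = inc.size
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0
    if inc.kind == "cuboid":
        lx, ly, lz = inc.size
        return (
            (np.abs(x - cx) <= lx / 2)
            & (np.abs(y - cy) <= ly / 2)
            & (np.abs(z - cz) <= lz / 2)
        )
    raise ValueError(f"unknown inclusion kind {inc.kind!r}")


def make_phantom(spec: PhantomSpec) -> tuple[VolumeGrid, VolumeGrid, VolumeGrid]:
    """Voxelise a `PhantomSpec` into (chi, labels, mask).

    Membership is by voxel centre (no antialiasing), so per-label means are
    exact.  Overlapping inclusions: the later one wins, with a logged
    warning.  The mask is the union of all inclusions plus any nonzero
    background support (the full grid when a background susceptibility or
    texture is requested).
    """
    shape = tuple(int(n) for n in spec.shape)
    chi = np.full(shape, float(spec.background_susceptibility))
    labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    for inc in spec.inclusions:
        member = _inclusion_membership(inc, shape, spec.voxel_size)
        if not member.any():
            raise InvalidGeometryError(
                f"inclusion label={inc.label} does not intersect the grid"
            )
        if (member & occupied).any():
            logger.warning(
                "inclusion label=%d overlaps an earlier inclusion; later wins", inc.label
            )
        chi[member] = inc.susceptibility
        labels[member] = inc.label
        occupied |= member

    if spec.background_susceptibility != 0.0 or spec.texture_amplitude > 0.0:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = occupied.copy()

    if spec.texture_amplitude > 0.0:
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(spec.texture_seed)
        tex = gaussian_filter(rng.standard_normal(shape), sigma=3.0)
        tex *= spec.texture_amplitude / max(tex.std(), 1e-30)
        chi = chi + np.where(occupied, 0.0, tex)  # keep per-label means exact

    meta = dict(voxel_size=spec.voxel_size)
    return (
        VolumeGrid(chi, mask=mask.astype(np.uint8), units_label="ppm", **meta),
        VolumeGrid(labels.astype(float), units_label="label", **meta),
        VolumeGrid(mask.astype(float), units_label="mask", **meta),
    )


def analytic_sphere_field(
    shape,
    voxel_size,
    center,
    radius: float,
    delta_chi: float,
    b0_dir=(0.0, 0.0, 1.0),
) -> VolumeGrid:
    """Closed-form field of a uniformly magnetised sphere.

    Outside the sphere the field offset (in the same ppm units as chi) is

        (delta_chi / 3) * (a / r)^3 * (3 cos^2 theta - 1)

    with a the radius and theta the angle from ``b0_dir``; inside it is 0
    (Lorentz-corrected convention).  Exact point-wise evaluation at voxel
    centres; serves as the independent oracle for the Fourier-domain dipole
    convolution.
    """
    shape = tuple(int(n) for n in shape)
    vs = tuple(float(v) for v in voxel_size)
    if radius < 2 * min(vs):
        raise InvalidGeometryError("sphere radius must span at least 2 voxels")
    extent = [n * d for n, d in zip(shape, vs)]
    if any(c < 0 or c > e for c, e in zip(center, extent)):
        raise InvalidGeometryError(f"center {center} outside grid extent {extent}")
    b0 = np.asarray(b0_dir, dtype=float)
    b0 = b0 / np.linalg.norm(b0)
    x, y, z = _voxel_centers(shape, vs)
    dx, dy, dz = x - center[0], y - center[1], z - center[2]
    r2 = dx**2 + dy**2 + dz**2
    r = np.sqrt(r2)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_t = np.where(r > 0, (dx * b0[0] + dy * b0[1] + dz * b0[2]) / np.where(r > 0, r, 1.0), 0.0)
        fld = (delta_chi / 3.0) * (radius / np.where(r > 0, r, 1.0)) ** 3 * (3 * cos_t**2 - 1.0)
    fld = np.where(r < radius, 0.0, fld)
    fld[r == 0] = 0.0
    return VolumeGrid(fld, voxel_size=vs, b0_dir=b0, units_label="ppm")


def simulate_observation(
    chi: VolumeGrid, kernel: DipoleKernel, noise: NoiseSpec, pad: bool = False
) -> VolumeGrid:
    """Observed local field: phi = forward_field(chi) + n, n ~ N(0, sigma^2).

    Deterministic under a fixed seed.  If ``chi`` carries a mask the field is
    restricted to its support, mimicking a local-field map after brain
    masking.
    """
    phi = forward_field(chi, kernel, pad=pad)
    data = phi.data
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        data = data + rng.normal(0.0, noise.sigma, size=data.shape)
    if chi.mask is not None:
        data = data * chi.mask
    return phi.with_data(data, units_label=chi.units_label)


def make_brainlike_phantom(
    seed: int, shape=(96, 96, 96), voxel_size=(1.0, 1.0, 1.0)
) -> tuple[VolumeGrid, VolumeGrid, VolumeGrid]:
    """Brain-like phantom: >= 6 labelled ROIs plus thin vessel structures.

    An ellipsoidal "brain" support holds eight ellipsoidal ROIs whose
    susceptibilities span roughly -0.05 to 0.15 ppm (the physiologic range of
    deep grey-matter structures), a weak smooth background texture, and a few
    random 2-3 voxel wide cylindrical "vessels" at venous susceptibility to
    probe reconstruction sharpness.  Vessels are deliberately left out of the
    label map: they are sharpness probes, not ROIs.  Reproducible under
    ``seed``; different seeds give different geometries.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(n) for n in shape)
    vs = tuple(float(v) for v in voxel_size)
    extent = np.array([n * d for n, d in zip(shape, vs)])
    center = extent / 2.0

    roi_chis = np.array([-0.05, -0.02, 0.01, 0.04, 0.06, 0.09, 0.12, 0.15])
    n_roi = len(roi_chis)
    inclusions = []
    # ROI centres on a jittered ring inside the brain ellipsoid so they never
    # overlap each other or the support boundary.
    brain_semi = 0.40 * extent
    ring_r = 0.55
    for i, chi_val in enumerate(roi_chis):
        ang = 2 * np.pi * (i + rng.uniform(-0.1, 0.1)) / n_roi
        zoff = rng.uniform(-0.35, 0.35)
        c = center + brain_semi * np.array(
            [ring_r * np.cos(ang), ring_r * np.sin(ang), zoff * 0.8]
        )
        semi = rng.uniform(0.040, 0.060, size=3) * extent
        inclusions.append(
            Inclusion("ellipsoid", tuple(c), tuple(semi), float(chi_val), i + 1)
        )

    spec = PhantomSpec(
        shape=shape,
        voxel_size=vs,
        inclusions=inclusions,
        texture_amplitude=0.0,
    )
    chi, labels, _ = make_phantom(spec)

    x, y, z = _voxel_centers(shape, vs)
    brain = (
        ((x - center[0]) / brain_semi[0]) ** 2
        + ((y - center[1]) / brain_semi[1]) ** 2
        + ((z - center[2]) / (1.05 * brain_semi[2])) ** 2
    ) <= 1.0

    data = chi.data.copy()
    roi_occ = labels.data > 0

    # smooth background texture inside the brain, outside ROIs
    from scipy.ndimage import gaussian_filter

    # isotropic component plus an oriented lamellar component: folded
    # grey/white structures are locally anisotropic and self-similar along
    # the lamination direction, which is what patch-grouping denoisers
    # exploit in real brain maps
    iso = gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    lam_axis = int(rng.integers(3))
    lam_sigma = [0.8, 0.8, 0.8]
    lam_sigma[lam_axis] = 6.0
    lam = gaussian_filter(rng.standard_normal(shape), sigma=lam_sigma)
    tex = 0.6 * iso / max(iso.std(), 1e-30) + 0.8 * lam / max(lam.std(), 1e-30)
    tex *= 0.015 / max(tex.std(), 1e-30)
    data = np.where(brain & ~roi_occ, tex, data)

    # thin cylindrical vessels (2-3 voxels wide) at venous susceptibility
    vessel = np.zeros(shape, dtype=bool)
    xx = np.broadcast_to(x, shape)
    yy = np.broadcast_to(y, shape)
    zz = np.broadcast_to(z, shape)
    pts = np.stack([xx, yy, zz], axis=-1)
    for _ in range(5):
        p0 = center + (rng.uniform(-0.5, 0.5, 3)) * brain_semi
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        radius_mm = rng.uniform(0.8, 1.1) * min(vs)
        rel = pts - p0
        along = rel @ direction
        perp2 = np.einsum("...i,...i->...", rel, rel) - along**2
        vessel |= (perp2 <= radius_mm**2) & (np.abs(along) < 0.9 * brain_semi.min())
    vessel &= brain & ~roi_occ
    data[vessel] = 0.20

    data = np.where(brain, data, 0.0)
    mask = brain.astype(np.uint8)
    chi_out = VolumeGrid(data, voxel_size=vs, mask=mask, units_label="ppm")
    labels_out = VolumeGrid(labels.data * brain, voxel_size=vs, units_label="label")
    mask_out = VolumeGrid(mask.astype(float), voxel_size=vs, units_label="mask")
    return chi_out, labels_out, mask_out
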