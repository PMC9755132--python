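"""Image-quality metrics and ROI statistics for comparing reconstructions.

Global metrics follow the QSM-challenge conventions: RMSE and HFEN are
normalised errors scaled by 100 (so 0 is perfect and 100 means an error as
large as the reference), HFEN after a Laplacian-of-Gaussian filter (15-voxel
kernel, sigma 1.5) that isolates fine structure, SSIM is the mean local
structural similarity, CC the Pearson correlation, MI the Shannon mutual
information of the 64-bin joint histogram in nats, and the no-reference blur
metric compares neighbouring-voxel variation before and after a fixed
low-pass, slice-wise, in [0, 1] with higher = blurrier.

Every metric is invariant to voxels outside the mask: inputs are zeroed
there before any filtering, and statistics are taken over mask voxels only.

ROI statistics mirror standard agreement analyses: per-label means, ordinary
least-squares regression of test on reference means (slope beta, R^2, p),
and Bland-Altman bias +/- 2 sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_laplace, uniform_filter1d

from .volume import VolumeGrid

__all__ = [
    "MetricsReport",
    "ROITable",
    "rmse",
    "hfen",
    "ssim_metric",
    "cross_correlation",
    "mutual_information",
    "blur_metric",
    "roi_analysis",
    "evaluate",
]


@dataclass
class MetricsReport:
    rmse: float
    hfen: float
    ssim: float
    cc: float
    mi: float
    blur: float
    mask_voxels: int
    reference_id: str = "reference"
    test_id: str = "test"

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "hfen": self.hfen,
            "ssim": self.ssim,
            "cc": self.cc,
            "mi": self.mi,
            "blur": self.blur,
            "mask_voxels": self.mask_voxels,
            "reference_id": self.reference_id,
            "test_id": self.test_id,
        }


@dataclass
class ROITable:
    table: pd.DataFrame  # label, name, mean_chi_test, mean_chi_reference, n_voxels
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    bias: float
    two_sigma: float


def _unpack(x) -> np.ndarray:
    return x.data if isinstance(x, VolumeGrid) else np.asarray(x, dtype=float)


def _prep(test, reference, mask):
    t = _unpack(test)
    r = _unpack(reference)
    if t.shape != r.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {r.shape}")
    if mask is None:
        m = np.ones(t.shape, dtype=bool)
    else:
        m = _unpack(mask).astype(bool)
        if m.shape != t.shape:
            raise ValueError("mask shape mismatch")
    if not m.any():
        raise ValueError("mask is empty")
    return t * m, r * m, m


def rmse(test, reference, mask=None) -> float:
    """Normalised root-mean-square error: 100 * ||t - r|| / ||r|| over mask."""
    t, r, m = _prep(test, reference, mask)
    denom = np.linalg.norm(r[m])
    if denom == 0:
        raise ZeroDivisionError("reference is identically zero inside the mask")
    return 100.0 * float(np.linalg.norm((t - r)[m]) / denom)


def hfen(test, reference, mask=None) -> float:
    """High-frequency error norm: normalised error after LoG filtering.

    Laplacian-of-Gaussian with sigma = 1.5 voxels on a 15-voxel support;
    insensitive to DC offsets by construction.
    """
    t, r, m = _prep(test, reference, mask)
    # remove the in-mask mean before zero-filling so a pure DC offset does
    # not create a step at the mask boundary (LoG is DC-blind by design)
    t = (t - t[m].mean()) * m
    r = (r - r[m].mean()) * m
    sigma = 1.5
    truncate = 7.0 / sigma  # radius 7 -> 15-voxel kernel
    lt = gaussian_laplace(t, sigma=sigma, truncate=truncate)
    lr = gaussian_laplace(r, sigma=sigma, truncate=truncate)
    denom = np.linalg.norm(lr[m])
    if denom == 0:
        raise ZeroDivisionError("LoG of reference vanishes inside the mask")
    return 100.0 * float(np.linalg.norm((lt - lr)[m]) / denom)


def ssim_metric(test, reference, mask=None) -> float:
    """Mean local SSIM over the mask, Gaussian-weighted 11-voxel window.

    The dynamic range is the reference max - min over the mask.
    """
    from skimage.metrics import structural_similarity

    t, r, m = _prep(test, reference, mask)
    data_range = float(r[m].max() - r[m].min())
    if data_range == 0:
        raise ValueError("constant reference: SSIM undefined")
    min_dim = min(t.shape)
    kw = dict(gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
              data_range=data_range, full=True)
    if min_dim >= 11:
        _, smap = structural_similarity(r, t, **kw)
    else:
        # thin volumes: per-axial-slice SSIM, averaged
        smap = np.empty_like(t)
        for k in range(t.shape[2]):
            _, smap[:, :, k] = structural_similarity(r[:, :, k], t[:, :, k], **kw)
    return float(smap[m].mean())


def cross_correlation(test, reference, mask=None) -> float:
    """Pearson correlation of test and reference over mask voxels."""
    t, r, m = _prep(test, reference, mask)
    rv = r[m]
    tv = t[m]
    if rv.std() == 0:
        raise ValueError("constant reference: correlation undefined")
    return float(np.corrcoef(tv, rv)[0, 1])


def mutual_information(test, reference, mask=None, bins: int = 64) -> float:
    """Shannon mutual information of the joint histogram, in nats."""
    t, r, m = _prep(test, reference, mask)
    tv, rv = t[m], r[m]
    joint, _, _ = np.histogram2d(tv, rv, bins=bins)
    total = joint.sum()
    if total == 0:
        return 0.0
    p = joint / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    denom = (px @ py)[nz]
    if not nz.any() or np.all(denom == 0):
        return 0.0
    return float(np.sum(p[nz] * np.log(p[nz] / denom)))


def _slice_blur(img: np.ndarray) -> float:
    """No-reference blur score of one 2D slice (variation-loss construction).

    Low-pass the slice with a 9-tap moving average along each axis, compare
    the loss of neighbouring-pixel variation, and keep the worse (blurrier)
    of the two directions.
    """
    scores = []
    for ax in range(2):
        blurred = uniform_filter1d(img, size=9, axis=ax, mode="nearest")
        d_f = np.abs(np.diff(img, axis=ax))
        d_b = np.abs(np.diff(blurred, axis=ax))
        v = np.maximum(0.0, d_f - d_b)
        s_f = d_f.sum()
        if s_f == 0:
            scores.append(0.0)
        else:
            scores.append(float((s_f - v.sum()) / s_f))
    return max(scores)


def blur_metric(volume, mask=None) -> float:
    """Per-image blur in [0, 1] (higher = blurrier), axial-slice averaged."""
    v = _unpack(volume)
    if mask is None and isinstance(volume, VolumeGrid) and volume.mask is not None:
        mask = volume.mask
    if mask is None:
        m = np.ones(v.shape, dtype=bool)
    else:
        m = _unpack(mask).astype(bool)
    if not m.any():
        raise ValueError("mask is empty")
    v = v * m
    scores = [
        _slice_blur(v[:, :, k]) for k in range(v.shape[2]) if m[:, :, k].any()
    ]
    return float(np.mean(scores))


def roi_analysis(test, reference, labels, names: dict[int, str] | None = None) -> ROITable:
    """Per-ROI mean susceptibilities with regression and Bland-Altman summary.

    Ordinary least squares (with intercept) of test means on reference
    means; bias is the mean of per-ROI differences, limits of agreement
    +/- 2 sigma of those differences.
    """
    t = _unpack(test)
    r = _unpack(reference)
    lab = _unpack(labels).astype(int)
    ids = sorted(int(i) for i in np.unique(lab) if i > 0)
    if len(ids) < 2:
        raise ValueError("ROI analysis needs at least 2 labelled regions")
    rows = []
    for i in ids:
        sel = lab == i
        rows.append(
            {
                "label": i,
                "name": (names or {}).get(i, f"roi_{i}"),
                "mean_chi_test": float(t[sel].mean()),
                "mean_chi_reference": float(r[sel].mean()),
                "n_voxels": int(sel.sum()),
            }
        )
    df = pd.DataFrame(rows)
    fit = stats.linregress(df["mean_chi_reference"], df["mean_chi_test"])
    diffs = df["mean_chi_test"] - df["mean_chi_reference"]
    return ROITable(
        table=df,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        bias=float(diffs.mean()),
        two_sigma=float(2.0 * diffs.std(ddof=1)) if len(diffs) > 1 else 0.0,
    )


def evaluate(test, reference, mask=None, reference_id="reference", test_id="test") -> MetricsReport:
    """Full global metric panel for one reconstruction against a reference."""
    _, _, m = _prep(test, reference, mask)
    return MetricsReport(
        rmse=rmse(test, reference, mask),
        hfen=hfen(test, reference, mask),
        ssim=ssim_metric(test, reference, mask),
        cc=cross_correlation(test, reference, mask),
        mi=mutual_information(test, reference, mask),
        blur=blur_metric(test, mask),
        mask_voxels=int(m.sum()),
        reference_id=reference_id,
        test_id=test_id,
    )
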