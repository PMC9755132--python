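"""End-to-end reconstruction runs: config in, artifact bundle out.

`run_pipeline` ties the modules together the way the CLI does: load (or
receive) the field, mask and optional truth/labels, run the selected solver,
and write the susceptibility map, per-iteration residual log, metric panel,
ROI table and a reproducibility manifest into the output directory.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .denoise import DenoiserSpec, denoise, registered_denoisers
from .dipole import build_dipole_kernel, tkd_invert
from .io import radians_to_ppm, read_volume, write_volume
from .metrics import evaluate, roi_analysis
from .solvers import ADMMParams, l2_closed_form, pnp_admm, tv_admm
from .volume import VolumeGrid

logger = logging.getLogger(__name__)

SOLVERS = ("l2", "tv", "pnp", "tkd")


@dataclass
class RunConfig:
    field_path: str
    mask_path: str | None = None
    labels_path: str | None = None
    truth_path: str | None = None
    solver: str = "pnp"
    denoiser: str = "bm4d"
    mu: float = 1.0
    alpha: float = 1e-3
    beta: float = 1.0
    max_iters: int = 50
    rel_tol: float = 1e-3
    sigma: float | None = None
    noise_back_lambda: float = 0.0
    tkd_threshold: float = 0.19
    input_units: str = "ppm"  # "ppm" | "radians"
    te_ms: float | None = None
    b0_t: float | None = None
    b0_dir: tuple[float, float, float] = (0.0, 0.0, 1.0)
    out_dir: str = "qsm_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.solver not in SOLVERS:
            raise ValueError(f"unknown solver {self.solver!r}; choose from {SOLVERS}")
        if self.denoiser not in registered_denoisers():
            raise ValueError(
                f"unknown denoiser {self.denoiser!r}; registered: {registered_denoisers()}"
            )
        if self.input_units not in ("ppm", "radians"):
            raise ValueError("input_units must be 'ppm' or 'radians'")
        if self.input_units == "radians" and (self.te_ms is None or self.b0_t is None):
            raise ValueError("radian inputs need explicit te_ms and b0_t")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _admm_params(cfg: RunConfig) -> ADMMParams:
    return ADMMParams(
        mu=cfg.mu,
        alpha=cfg.alpha,
        beta=cfg.beta,
        max_iters=cfg.max_iters,
        rel_tol=cfg.rel_tol,
        denoiser=DenoiserSpec(name=cfg.denoiser, sigma=cfg.sigma),
        noise_back_lambda=cfg.noise_back_lambda,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run one reconstruction and write the artifact bundle.

    Returns a dict of output paths and summary numbers.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    phi = read_volume(config.field_path, b0_dir=config.b0_dir, units_label=config.input_units)
    if config.input_units == "radians":
        phi = radians_to_ppm(phi, config.te_ms, config.b0_t)
    mask = None
    if config.mask_path:
        mask = read_volume(config.mask_path).data > 0.5
        phi.mask = mask
        phi.__post_init__()

    kernel = build_dipole_kernel(phi.shape, phi.voxel_size, config.b0_dir)
    params = _admm_params(config)
    if mask is not None:
        params.fidelity_weight_M = mask.astype(float)

    state = None
    if config.solver == "l2":
        chi = l2_closed_form(phi, kernel, alpha=config.alpha)
        if mask is not None:
            chi = chi.with_data(chi.data * mask)
    elif config.solver == "tkd":
        chi = tkd_invert(phi, kernel, threshold=config.tkd_threshold)
        if mask is not None:
            chi = chi.with_data(chi.data * mask)
    elif config.solver == "tv":
        chi, state = tv_admm(phi, kernel, params)
    else:
        chi, state = pnp_admm(phi, kernel, params)

    results: dict = {}
    chi_path = out / "chi.nii.gz"
    write_volume(chi, chi_path)
    results["chi"] = str(chi_path)

    if state is not None:
        import pandas as pd

        hist = pd.DataFrame(
            state.residual_history, columns=["primal_residual", "data_residual"]
        )
        hist.index.name = "iteration"
        hist_path = out / "residuals.csv"
        hist.to_csv(hist_path)
        results["residuals"] = str(hist_path)
        results["iterations"] = state.iteration

    if config.truth_path:
        truth = read_volume(config.truth_path)
        report = evaluate(chi, truth, mask, test_id=config.solver)
        metrics_path = out / "metrics.json"
        metrics_path.write_text(json.dumps(report.to_dict(), indent=2))
        results["metrics"] = str(metrics_path)
        results["metrics_values"] = report.to_dict()
        if config.labels_path:
            labels = read_volume(config.labels_path)
            roi = roi_analysis(chi, truth, labels)
            roi_path = out / "roi_table.csv"
            roi.table.to_csv(roi_path, index=False)
            summary = {
                "slope": roi.slope,
                "intercept": roi.intercept,
                "r_squared": roi.r_squared,
                "p_value": roi.p_value,
                "bias": roi.bias,
                "two_sigma": roi.two_sigma,
            }
            (out / "roi_summary.json").write_text(json.dumps(summary, indent=2))
            results["roi_table"] = str(roi_path)
            results["roi_summary"] = summary

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": {
            "pnpqsm": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = str(out / "manifest.json")
    return results


def run_denoise(input_path, output_path, spec: DenoiserSpec, mask_path=None) -> None:
    vol = read_volume(input_path)
    if mask_path:
        vol.mask = read_volume(mask_path).data > 0.5
        vol.__post_init__()
    write_volume(denoise(vol, spec), output_path)


def phantom_spec_from_yaml(path):
    """Deserialize a `PhantomSpec` from YAML."""
    from .phantom import Inclusion, PhantomSpec

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    incs = [
        Inclusion(
            kind=i["kind"],
            center=tuple(i["center"]),
            size=tuple(i["size"]) if isinstance(i["size"], (list, tuple)) else float(i["size"]),
            susceptibility=float(i["susceptibility"]),
            label=int(i["label"]),
        )
        for i in raw.get("inclusions", [])
    ]
    return PhantomSpec(
        shape=tuple(raw["shape"]),
        voxel_size=tuple(raw.get("voxel_size", (1.0, 1.0, 1.0))),
        inclusions=incs,
        background_susceptibility=float(raw.get("background_susceptibility", 0.0)),
        texture_amplitude=float(raw.get("texture_amplitude", 0.0)),
        texture_seed=int(raw.get("texture_seed", 0)),
    )
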