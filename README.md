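# pnpqsm — plug-and-play ADMM dipole inversion for QSM

Quantitative susceptibility mapping (QSM) recovers the tissue magnetic
susceptibility distribution χ (in ppm) from the local magnetic field map φ
measured with gradient-echo MRI. In the Fourier domain the two are related
through the dipole kernel

    D(k) = 1/3 − (k·b₀)² / |k|²,        F φ = D · F χ,

which vanishes on the magic-angle cone (≈54.7° to B₀), making the inversion
ill-posed: naive division amplifies noise into streaking artifacts.

`pnpqsm` is a toolbox for this inversion aimed at people developing or
evaluating QSM reconstruction methods. It provides:

- **Solvers** — truncated k-space division (TKD) and closed-form Tikhonov
  (L2) baselines, total-variation-regularised ADMM (QSM-TV), and the central
  **plug-and-play ADMM** solver, which alternates

      χ ← argmin  β/2‖χ − v + u‖² + μ/2‖M(F^H D F χ − φ)‖²
      v ← D_σ(χ + u)
      u ← u + (χ − v)

  where the regulariser's proximal step is an arbitrary registered denoiser
  D_σ. An optional "adding-noise-back" step remixes a fraction of the data
  residual into φ to counter over-smoothing.
- **Denoisers** — a pluggable family sharing one interface: volumetric
  block-matching collaborative filtering (BM4D-style: 3D patches grouped
  along a 4th dimension, orthonormal DCT, hard thresholding at 2.7σ,
  weighted aggregation, optional Wiener second pass), a 2D slice-wise
  variant (BM3D-style), nonlocal-PCA patch shrinkage, non-local means, and
  Gaussian/identity baselines. Any of them plugs into the solver unchanged.
- **Phantoms** — labelled geometric phantoms, a brain-like phantom with
  physiologic ROI susceptibilities (−0.05 … 0.15 ppm) and thin vessels, the
  analytic field of a magnetised sphere as a forward-model oracle, and
  seeded Gaussian field noise.
- **Metrics** — the standard QSM comparison panel: normalised RMSE and
  high-frequency error norm (HFEN, ×100 challenge convention), SSIM,
  Pearson cross-correlation, mutual information (nats), a no-reference blur
  score, and ROI statistics (means, regression slope β and R², Bland–Altman
  bias ± 2σ).
- **I/O + CLI** — NIfTI volumes via nibabel, radians↔ppm conversion with
  explicit TE/B₀, and a `pnpqsm` command with `simulate`, `reconstruct`,
  `eval`, `denoise` and `benchmark` subcommands.

## Worked example

Simulate a 64³ brain-like phantom, reconstruct with PnP-BM4D, and evaluate:

```python
import numpy as np
from pnpqsm import (ADMMParams, DenoiserSpec, build_dipole_kernel,
                    make_brainlike_phantom, simulate_observation, NoiseSpec,
                    pnp_admm, evaluate, roi_analysis)

chi, labels, mask = make_brainlike_phantom(seed=7, shape=(64, 64, 64))
kernel = build_dipole_kernel(chi.shape, chi.voxel_size, chi.b0_dir)
phi = simulate_observation(chi, kernel, NoiseSpec(sigma=0.001, seed=7), pad=True)
phi.mask = chi.mask; phi.__post_init__()

params = ADMMParams(mu=100.0, beta=1.0, max_iters=15, rel_tol=5e-4,
                    denoiser=DenoiserSpec(name="bm4d", sigma=0.008),
                    fidelity_weight_M=chi.mask.astype(float))
rec, state = pnp_admm(phi, kernel, params)

rep = evaluate(rec, chi, chi.mask)
roi = roi_analysis(rec, chi, labels)
print(f"RMSE {rep.rmse:.1f}  HFEN {rep.hfen:.1f}  SSIM {rep.ssim:.3f}")
print(f"ROI slope {roi.slope:.3f}  R^2 {roi.r_squared:.3f}  bias {roi.bias:.4f} ppm")
```

prints (64³ phantom, seed 7):

```
RMSE 23.5  HFEN 18.8  SSIM 0.744
ROI slope 0.920  R^2 0.998  bias -0.0054 ppm
```

RMSE/HFEN are percentages of the reference norm (0 = perfect); the ROI
regression says the mean susceptibility of each labelled region is recovered
at 92% of its true value with essentially no scatter and a bias well under
0.01 ppm.

The same pipeline from the shell:

```sh
pnpqsm simulate --seed 7 --shape 64 --noise-sigma 0.001 --out-dir sim/
pnpqsm reconstruct --field sim/field.nii.gz --mask sim/mask.nii.gz \
       --solver pnp --denoiser bm4d --mu 100 --sigma 0.008 --out-dir rec/
pnpqsm eval --test rec/chi.nii.gz --reference sim/chi_true.nii.gz \
       --mask sim/mask.nii.gz --labels sim/labels.nii.gz
```

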