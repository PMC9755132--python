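# Methods

## Forward model

A susceptibility distribution χ (ppm) induces a local field offset
φ = d * χ + n, where d is the unit dipole response and n i.i.d. Gaussian
field noise. In the Fourier domain the convolution is a pointwise product
with D(k) = 1/3 − (k·b₀)²/|k|². The kernel is sampled on the physical
frequency grid (cycles/mm, `fftfreq(n)/voxel_size` per axis) so anisotropic
voxels tilt the magic-angle cone correctly. D(0) is undefined by the
formula; the package sets it to a configurable `dc_value`, default 0, the
zero-mean-field convention. The convolution is circular (plain FFT); an
optional pad-by-2 mode computes the aperiodic convolution for sources near
the boundary. Because D is real and even, the forward operator is
self-adjoint; the adjoint is exposed separately for clarity and for the
conjugate-gradient sub-solver.

Units: χ and φ are both kept in ppm (field normalised by B₀). Conversion
from radians at echo time TE uses φ_ppm = φ_rad / (2π·γ̄·B₀·TE) · 10⁶ with
γ̄ = 42.577478518 MHz/T, at the I/O boundary only.

## Solvers

**TKD** divides Fφ by the kernel with magnitudes clipped at a threshold
(default 0.19), sign(0) treated as +1.

**L2 (Tikhonov)** has the closed form χ = F^H[D·Fφ / (D² + αP)], with P = 1
or, by default, P = Σ|Eᵢ|² for the FFT-diagonal forward-difference gradient
operators — penalising gradient energy rather than intensity, which
preserves more low-frequency contrast.

**QSM-TV** minimises μ/2‖M(Aχ−φ)‖² + α‖W∇χ‖₁ by ADMM, splitting on the
gradient g = ∇χ: the g-update is isotropic soft-thresholding of the
(optionally W-weighted) gradient at α/β, the χ-update is FFT-diagonal when
the fidelity weight M is the identity and warm-started conjugate gradients
otherwise. Gradients are forward differences with periodic boundary,
voxel-size-scaled.

**PnP-ADMM** replaces the regulariser's proximal step with a denoiser:
χ-update (data consistency) → v = D_σ(χ + u) → u += χ − v. The χ-update is
the exact Fourier solution for identity M, else warm-started CG on
(βI + μA^H M²A)χ = β(v−u) + μA^H M²φ. The denoiser strength defaults to the
proximal correspondence σ = sqrt(α/β); a fixed user σ and a geometric decay
schedule are also supported. The "adding-noise-back" step, disabled by
default (λ = 0), replaces φ with φ + λ(φ − Aχ) before each χ-update.
Stopping: `max_iters` or relative χ-change below `rel_tol`. One printed
inconsistency in the source formulation weights the proximal term α/2 in
one place and β/2 in another; the package treats this as a typo and uses β
throughout, reserving α for regulariser/denoiser strength.

Initialisation is χ = v = 0, u = 0 (or a supplied initial χ). All iterates
are checked for NaN/Inf and abort with diagnostics.

## Denoisers

All denoisers are deterministic and share `denoise(volume, spec)`. With a
mask, they operate on the padded bounding box of the mask and are the
identity outside.

*Block-matching collaborative filtering.* Reference patches on a stride
grid (stride = patch/2, min 1, guaranteeing coverage) are each matched to
the `max_group_size` most similar patches within a Chebyshev search window
(mean squared distance; reference first; ties lexicographic). The group is
transformed by an orthonormal separable DCT-II across the patch axes and
the grouping axis, hard-thresholded at 2.7σ (the group DC always survives),
inverse-transformed, and aggregated into the volume with per-group weights
1/(1 + N_retained). The volumetric variant uses 4³ patches; the slice-wise
variant runs the 2D pipeline per axial slice. An optional second pass
re-matches on the first-pass estimate and applies empirical Wiener
shrinkage instead of hard thresholding. Similarity is computed on the raw
volume (no coarse prefilter) — a deliberate simplification. Defaults
(patch 4, group 8, search radius 3) favour tractability; deeper groups are
configurable.

*Nonlocal PCA.* Matched groups are mean-centred and decomposed by SVD;
components whose per-voxel variance s²/((N−1)·p³) exceeds σ² are retained.
At this normalisation the largest pure-noise component falls at
σ²(√N+√p³)²/((N−1)p³) < σ², so noise-only groups collapse toward their mean
while a genuine rank-1 population survives. This is a simplified
texture-adaptive nonlocal-PCA scheme, not a port of any reference code.

*Baselines.* Non-local means delegates to scikit-image; `gaussian` smooths
with width σ voxels; `identity` passes through (useful in solver limit
tests).

The production block matcher vectorises patch distances with
cumulative-sum window sums (one pass per offset) and selects groups with a
deterministic partial sort; it is cross-checked against the brute-force
reference implementation in the tests.

## Phantoms

`make_phantom` voxelises spheres/ellipsoids/cuboids by voxel-centre
membership (no antialiasing), so per-label means are exact; overlaps go to
the later inclusion with a logged warning. `analytic_sphere_field`
evaluates the closed-form sphere field ((Δχ/3)(a/r)³(3cos²θ−1) outside,
0 inside) as an independent oracle for the FFT forward model; on a 128³
grid the two agree to better than 1% in the 1.5a–3a shell.

`make_brainlike_phantom` builds an ellipsoidal support containing eight
constant ellipsoidal ROIs spanning −0.05…0.15 ppm (the deep grey-matter
range), a weak textured background (amplitude 0.015 ppm: an isotropic
smooth component plus an oriented lamellar component, mimicking the locally
anisotropic, self-similar structure of folded cortex), and five 2–3-voxel
cylindrical "vessels" at 0.20 ppm occupying < 2% of the mask. Vessels probe
reconstruction sharpness and are intentionally absent from the label map so
ROI regression is not dominated by partial-volume effects.

The canonical study (`pnpqsm.experiments.run_study`) simulates the
observation with the padded (aperiodic) convolution while the solvers
assume the circular operator — avoiding the inverse crime of inverting the
exact operator that generated the data — and adds field noise
σ = 0.001 ppm (≈1/9 of the in-mask field std, typical of a 3 T single-echo
local-field map). The panel runs at 96³; the same conditions at smaller
grids are used in unit tests for speed.

What passing tests on this phantom do **not** show: performance under
residual background fields, phase-unwrapping errors, flow or motion
artifacts, spatially varying noise, microstructure anisotropy, or textures
with the full richness of in-vivo susceptibility contrast. In particular,
the synthetic truth is piecewise-constant-plus-smooth-texture — inside the
model class of the TV prior — so TV attains a higher SSIM here than the
patch-based prior, whereas the patch-based reconstruction recovers thin
vessels and region edges with visibly lower error and wins on RMSE and CC.
On real brain data the balance reported in the literature favours the patch
prior across the board; the phantom reproduces the fine-structure advantage
and the RMSE ordering but not the SSIM ordering.

## Metrics

RMSE and HFEN use the ×100 normalised convention (100·‖t−r‖/‖r‖ over the
mask), HFEN after a Laplacian-of-Gaussian filter (σ = 1.5 voxels, 15-voxel
support). Before filtering, volumes are zeroed outside the mask (HFEN
additionally removes the in-mask mean first so a pure DC offset does not
manufacture a boundary step). SSIM is the mean local structural similarity
(Gaussian 11-voxel window, dynamic range = reference range over the mask;
per-slice fallback for thin volumes). MI is Shannon mutual information of
the 64-bin joint histogram in nats. The blur score compares
neighbouring-voxel variation before and after a fixed 9-tap low-pass,
per axial slice, averaged over mask-intersecting slices; range [0, 1],
higher = blurrier. Every metric is invariant to voxels outside the mask.
ROI analysis reports per-label means, OLS regression (with intercept) of
test on reference means, and Bland–Altman bias ± 2σ.

## Tuned defaults (canonical phantom study)

| solver | parameters |
|---|---|
| L2 | α = 1e-3 (gradient mode) |
| QSM-TV | μ = 1, α = 1e-4, β = 0.1, 40 iterations, CG 12/1e-4 |
| PnP-BM4D | μ = 100, β = 1, σ = 0.008, 15 iterations, CG 15/1e-5 |

These were chosen on the 64³ phantom by sweeping each solver to its best
metric panel and are exposed through `ADMMParams`/the CLI; nothing is
hard-wired. The fidelity weight M defaults to the binary brain mask.

## Numerical choices and degenerate inputs

FFT normalisation follows numpy's default pair. Division by zero on the
cone is excluded analytically (denominators β + μD² > 0; TV/L2 denominators
vanish only at k = 0, where the quotient is defined as 0). CG that reaches
its iteration cap returns the best iterate with a logged warning. Constant
references raise for CC/SSIM; zero references raise for RMSE/HFEN;
degenerate joint histograms give MI = 0. Empty masks are rejected
everywhere. `soft_shrink` defines 0/0 as 0 at exactly-zero gradient
magnitude.

## Known limitations

- Phase preprocessing (unwrapping, background-field removal, brain
  extraction) is out of scope; inputs must already be local-field maps.
- Single-orientation only; no susceptibility tensors or multi-orientation
  reconstruction.
- The BM4D-style denoiser is a from-scratch implementation with classic
  defaults, not bit-compatible with any reference binary.
- Runtime: the PnP solver costs one block-matching denoise per iteration
  (~10 s at 96³ per call on one CPU); the defaults keep a full study at 96³
  under ~4 minutes.
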