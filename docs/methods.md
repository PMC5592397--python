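# Methods

`dcecs` quantifies how the choice of *temporal* sparsity regularizer affects
compressed-sensing (CS) reconstructions of dynamic contrast-enhanced (DCE)
breast MRI — both the image error itself and, more importantly for oncology,
the accuracy of the Tofts–Kety pharmacokinetic parameters derived from the
reconstructed voxel time courses. Because no public single-slice breast
DCE-MRI raw dataset with hundreds of retrospective sampling patterns exists,
the package ships a synthetic acquisition with known parameter maps and runs
the full evaluation on it; user-supplied complex k-space can be substituted
at every stage.

## Measurement model and reconstruction

A single-slice dynamic acquisition is the complex array
`X ∈ C^{m×n×d}` (rows × columns × dynamics). Measurements follow

    B = A X + ε,   A = M F,

with `F` the centered orthonormal 2-D spatial Fourier transform applied per
dynamic, `M` a binary Cartesian sampling mask that keeps or drops whole
phase-encode lines per dynamic, and `ε` additive complex white Gaussian
noise. Reconstruction solves

    X̂ = argmin_X  ½‖A X − B‖_F² + α S(X)

by FISTA (accelerated proximal gradient; the Lipschitz constant of the
fidelity gradient is exactly 1 because `F` is unitary and `M` a selection),
with `S` one of:

| label | S(X) | prox |
|-------|------|------|
| FT | ‖F_t X‖₁, temporal DFT | soft threshold in coefficient space (exact) |
| WT | ‖W_t X‖₁, temporal Haar | soft threshold in coefficient space (exact) |
| TV | ‖∇_t X‖₁ | inner Chambolle–Pock denoiser (inexact) |
| TGV | temporal second-order total generalized variation | inner Chambolle–Pock on (z, v) (inexact) |
| NN | ‖X‖_* of the mn×d Casorati matrix | singular-value soft threshold (exact) |
| ZF | — | zero-filled baseline: A^H B |

Data are rescaled so the zero-filled image has unit maximum magnitude before
iterating (weights are calibrated on that scale) and the output is scaled
back. Iterations stop when the relative image change drops below `tol`
(default 1e-3) or at the per-model iteration cap. For TV/TGV the objective
carries a fidelity weight `lam` (written `1/(2 lam)·fidelity + S_α`,
equivalently `½·fidelity + lam·α·‖∇_t X‖₁`); both parameters are accepted and
the effective ℓ1 weight is `lam·α`.

### Numerical choices

* **Temporal Haar for arbitrary length.** The per-level pairing
  (averages/details scaled by 1/√2, an odd leftover passed through) yields an
  exactly orthonormal matrix for every `d`, coinciding with the standard
  orthonormal Haar at powers of two. Exact unitarity matters: the
  soft-threshold solution of the ℓ1 prox is only exact for unitary
  transforms. (Symmetric-extension padding to a power of two was rejected
  for precisely that reason — the padded composite is not an isometry.)
* **Finite differences.** `∇_t` is the forward difference with replicate
  (Neumann) boundary, last difference structurally zero; its adjoint is the
  exact negative divergence.
* **Inexact prox + warm start.** The TV/TGV prox has no closed form; it is
  approximated by a fixed number of Chambolle–Pock iterations
  (`inner_iter`, defaults 20 / 40) whose dual variables are warm-started
  across outer FISTA iterations. Cold-started inner solves leave a few
  percent prox error that the accelerated outer loop amplifies; with warm
  starts the prox error contracts as the outer iterates settle, and the
  whole procedure stays deterministic. A standalone primal-dual mode
  (`method="pd"`) solves the TV/TGV problems without FISTA and converges to
  the same objective value (verified in the tests).
* **TGV boundary convention.** The temporal TGV² value is
  `min_v α1‖∇_t z − v‖₁ + α0‖D₂ v‖₁` with `v` on the d−1 inter-frame
  differences. Two idealized properties of TGV² — (i) affine time courses
  are exact fixed points of the prox, and (ii) `α0 → ∞` forces `v → 0` and
  reduces the functional to `α1·TV` — pull the discrete design in opposite
  directions: (i) requires constants in the kernel of `D₂`, (ii) requires
  that kernel to be trivial. No single discretization satisfies both, so
  `D₂`'s boundary is selectable: `"neumann"` (default; interior second
  differences, exact ramp preservation, the continuum behaviour where the
  kernel of the symmetrized derivative is the rigid motions) or
  `"dirichlet"` (zero-extended, exact TV reduction for every input). The
  reconstruction uses the default. `α0 = 2 α1` by default (`tgv_ratio`),
  a conventional split when no ratio is prescribed.
* **Step sizes.** The primal-dual steps validate against
  `σ·τ·‖K‖² ≤ 1` with the conservative bounds `‖∇_t‖² ≤ 4` and `‖K_TGV‖² ≤ 12`.
* **Divergence guard.** FISTA aborts with a diagnostic if the tracked
  objective grows past 10× its initial value (e.g. a wrong Lipschitz
  constant).

## Sampling patterns

Masks are `(phase-encode × readout × dynamic)` with whole lines sampled: a
fully sampled central window (default 20 of 128 lines at full scale, 6 of 48
at the desk scale — the same ≈15% center fraction) plus `p` random
peripheral lines per dynamic, `p = round(n_pe/R_target) − center_width`. The
peripheral budget `p·d` is divided as evenly as possible across peripheral
lines (quotas differing by at most 1) and each line's quota is assigned to
random dynamics — every peripheral line is sampled roughly equally often but
at random times. A `fixed_p` mode samples exactly `p` lines per dynamic with
greedy count balancing instead. Masks are bit-exact functions of their seed.
At 128 phase encodes and target 4.5 the achieved acceleration is
128/28 ≈ 4.57.

## Pharmacokinetic analysis

Tissue contrast concentration follows the standard Tofts–Kety model,

    C_T(t) = K^trans ∫₀ᵗ C_P(s) · exp(K^trans (s − t)/v_e) ds,

with `K^trans` (1/min) the plasma→EES volume transfer constant and `v_e` the
EES volume fraction. The forward model integrates a *piecewise-linear* C_P
against the exponential kernel in closed form per segment (recursive O(d)
update, `expm1`-stable), which is exact for the interpolated input and free
of quadrature bias at coarse DCE frame spacing. Only voxels whose mean
signal over the last three dynamics is ≥ 2× the mean over the first three
(pre-contrast) dynamics are analyzed; the quotient direction is configurable
since enhancement must exceed baseline for the filter to make sense.
Voxelwise fits use bounded trust-region nonlinear least squares
(`K^trans ∈ [0, 5]`, `v_e ∈ (0, 1]`) from the fixed start (0.1, 0.3), with
three deterministic restarts only when a solve fails or leaves a large
relative residual; failures are logged and dropped from the maps.

Signals are converted to concentration linearly,
`C_T = (S/S₀ − 1)/gain`, mirroring the synthetic forward model
`S = background·(1 + gain·C_T)`; an SPGRE signal equation, T1 mapping, coil
sensitivities, and motion are all out of scope.

## Synthetic acquisition

The phantom emulates the study conditions the evaluation needs, not breast
anatomy per se: a smooth elliptical tissue background (magnitude ≈0.8 with
10% smooth texture on 0.05 "air"), a circular tumor whose voxels follow
Tofts–Kety with log-normal parameter heterogeneity, and complex white
Gaussian k-space noise (σ = 0.01 per component against a ≈0.8 background,
SNR ≈ 80 — a well-tuned clinical protocol).

* Tumor means default to `K^trans = 0.425 /min`, `v_e = 0.635` —
  representative of an enhancing malignant breast lesion.
* Heterogeneity: coefficients of variation 0.4 for `K^trans` and 0.12 for
  `v_e` (multiplicative log-normal, renormalized so the tumor mean is exact,
  `v_e` clipped inside (0, 1]). Malignant lesions vary strongly in perfusion
  and less in interstitial volume; the agreement analysis (CCC) is only
  meaningful when the true maps have spread to agree about.
* AIF: the classic biexponential population input
  `C_P(t) = D(a₁e^{−m₁(t−t₀)} + a₂e^{−m₂(t−t₀)})` for `t ≥ t₀`, with the
  classic parameters a = (3.99, 4.78) mM, m = (0.144, 0.011) min⁻¹, D = 1 —
  chosen because its convolution with the Tofts kernel has a closed form,
  giving an independent oracle for the numerical forward model.
* Timing: `d = 30` dynamics at 0.1 min spacing, contrast arrival at frame 5
  (≥3 pre-contrast frames for the baseline, ≥3 late frames for the
  enhancement filter).

What the phantom does **not** emulate: anatomy-specific aliasing structure,
patient motion, B₁/T₁ effects, multi-coil acquisition, and the nonlinear
signal-to-concentration mapping of a real SPGRE protocol. Passing results
therefore demonstrate correctness and the *relative* behaviour of the
regularizers under controlled conditions, not absolute in-vivo performance.

## Evaluation

* **SER** (dB): `−20 log₁₀(‖X̂ − X_FS‖_F / ‖X_FS‖_F)` against the fully
  sampled reconstruction, on magnitude images (a complex option exists).
* **CCC**: Lin's concordance `2 cov(a,b)/(var a + var b + (ā − b̄)²)` with
  population moments, between undersampled and fully sampled parameter
  maps over their common enhancing support (and separately restricted to
  the tumor ROI). A literal textual variant that mixes standard deviations
  and variances is available behind `form="as_printed"` but is not an
  agreement measure (it returns 1 for perfectly anticorrelated
  equal-variance inputs), so Lin's form is the default.
* **Tumor means**, ROI **curve differences** vs. the fully sampled data, and
  **Bland–Altman** tables (differences plotted against the fully sampled
  values by default; the conventional pairwise-mean abscissa is available).
* **Paired comparisons** across mask seeds use the two-sided Wilcoxon
  signed-rank test with Holm adjustment — no normality assumption across
  masks is needed, and the test is exact under ties handling for the small
  ensembles used here.

## Ensemble experiment

One fully sampled noisy k-space is simulated once; every mask seed then
retrospectively undersamples that same data, isolating sampling-pattern
variance. The fully sampled reference image and reference parameter maps
are computed once and reused. Per-seed mask seeds derive from
`SeedSequence((global_seed, index))`, so the experiment is a deterministic
function of its configuration; re-runs produce bit-identical CSVs.

**Weight calibration.** The stock per-model weights (`α`, iteration caps,
and for TV/TGV the steps σ = τ = 0.2 and λ = 0.5) were hand-optimized for
the full-size in-vivo acquisition; an ℓ1 weight only means something
relative to the scale and temporal sampling of the data it was tuned on.
The pipeline therefore optimizes every model individually before comparing
them, automatically: each
regularizer's `α` is selected from a fixed log-spaced multiplier grid
(1/64 … 2 × stock) by maximizing SER against the fully sampled reference on
one dedicated calibration mask seed, disjoint from the evaluation seeds.
The grid and the calibration seed are part of the configuration, so the
step is deterministic and reproducible. `calibrate=False` skips it.

**Default problem sizes.** The default experiment is desk-scale: 48×32
in-plane, 30 dynamics, 10 mask seeds at target R = 4.5 (a full-size
acquisition would be 192×128×105 with hundreds of seeds), chosen so the
complete ensemble — calibration, six reconstructions per seed, voxelwise
fitting, and statistics — runs in minutes on one CPU while preserving the
center fraction, the enhancement curve shape, and enough tumor voxels
(~110) for stable CCCs. The full-scale geometry runs through the same code
path when time allows.

## Known limitations

* TGV trails TV slightly in image error here; its joint (z, v) subproblem
  converges more slowly, and at a fixed inner budget some of the gap is
  solver-induced rather than model-induced.
* The calibration proxy (SER vs. the fully sampled reference) stands in for
  a visual artifact assessment; other proxies (fit residuals,
  no-reference sharpness) could shift the chosen weights.
* The CCC between parameter maps depends on the population of voxels
  entering it; both the all-enhancing and tumor-restricted populations are
  reported because the choice is not standardized.
* Single-coil, single-slice, Cartesian only; 3-D, non-Cartesian, and
  parallel-imaging models are out of scope.
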