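# Methods

This note documents the models, conventions, numerical choices and known
limitations of `smval`.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Conventions

All FODs live on the unit sphere under the normalized measure
dn̂ = dΩ/4π, so the uniform density is P ≡ 1 and ⟨1⟩ = 1.  Spherical
harmonics are the real, dΩ-orthonormal basis with Condon–Shortley phase;
only even degrees appear (antipodal symmetry), ordered l ascending, m from
−l to +l.  FOD coefficients are p_lm = ∫dΩ Y_lm P (so p₀₀ = √4π), and the
per-degree invariants are p_l = ‖p_lm‖ / N_l with N_l = √(4π(2l+1)),
giving p_l = |⟨P_l(cos θ)⟩| ∈ [0, 1] for axially symmetric FODs, p_l = 1
for a delta bundle and 0 for the uniform sphere.  Dispersion angles use
θ = arccos √⟨cos²θ_i⟩ with length-weighted tangent averages; the
invariant-based angle is θ_p2 = arccos √((2p₂+1)/3).

Internally b-values are ms/μm², diffusivities μm²/ms, lengths μm.  bval
files in s/mm² are detected by magnitude and converted on read.

Two water diffusivities appear and are deliberately distinct:

* **D₀ = 2.0 μm²/ms** — the idealized free axoplasm diffusivity used in the
  morphometric prediction D̃a (the value a perfect cylinder would show at
  room temperature).
* **D_w = 2.1 μm²/ms** — the self-diffusion coefficient of bulk water near
  21 °C, used for the free-water compartment.  At the lowest shell
  (b = 2 ms/μm²) the surviving free-water signal is
  100·e^(−2·2.1) ≈ 1.5 % of S₀, which is why the free-water fraction can be
  pinned to zero for unconstrained fitting on this protocol.

## Synthetic axon populations

Each axon is a centerline through a rectangular block: a straight line
along its sampled direction plus one transverse sinusoid (amplitude u,
wavelength ℓ, random phase and azimuth), with cross-sectional area
A(z) = Ā(1 + a sin(2πz/ℓ_b + φ)) and a myelin annulus of outer radius
r/g (g-ratio g, default 0.7).  These choices are deliberately minimal —
one knob per morphological feature — because each admits a closed-form
oracle:

* sinusoidal beading ⇒ exact axial tortuosity Λ∥ = ⟨Ā/A⟩ = 1/√(1−a²);
* sinusoidal undulation ⇒ ⟨cos²θ_u⟩ ≈ 1/√(1+(uk)²), k = 2π/ℓ (exact for
  the unweighted slope average; the length-weighted value used by the
  pipeline differs by ≲10⁻³ at the default amplitudes);
* straight cylinders ⇒ D̃a = D₀ exactly and f from cylinder geometry.

Orientations come from a delta, Watson(κ), or exponential-decay-family
distribution.  Watson sampling is exact rejection from a truncated
exponential envelope e^{κt} on t ∈ [0, 1] (acceptance ≳ 0.5 for all κ);
κ ≥ 10⁶ is treated as the delta limit.  Axons are clipped to the box
(longest in-box run of centerline points) and generated ≥ 12 μm long so the
10 μm morphometry filter keeps >90 % of the intra-axonal volume.  One
master seed drives everything; per-axon streams are spawned from a
`SeedSequence`, so populations are bit-identical across runs.

The ground-truth record (θ, f, Λ∥, ⟨cos²θ_u⟩, D̃a) is computed from the
generator's own tangents and areas, never through the morphometry pipeline
under test.

**What the generator does not emulate:** segmentation errors, axon
branching and caliber trends, non-circular cross-sections, spatial
clustering, membranes/mitochondria, and the voxel-level partial-volume
mixing of crossing tracts.  Passing tests therefore demonstrate the
correctness of the measurement and estimation chain on ideal segmented
geometry, not robustness to segmentation artifacts.

## Morphometry

Per axon: align the length-weighted mean tangent (equivalently the
end-to-end direction) to +z, trim 1 μm of arc length per end (oblique
end-slices), resample at uniform arc length, and smooth with a Gaussian of
σ = √(2Dt)/2 ≈ 3.39 μm (D = 2 μm²/ms, t = Δ = 11.5 ms) — the coarse-graining
scale of diffusing water.  The smoother acts on the *deviation from the
secant line* with a reflecting boundary, so a straight axon is exactly
invariant and end tangents are not bent; areas are interpolated, not
smoothed.  Axons shorter than 2 μm after trimming are rejected and logged.

Population quantities: the main axis is the principal eigenvector of the
length-weighted tangent outer-product sum; θ is the Eq.-style
arccos-root-mean-cos² over all segments; the tangent FOD is a histogram on
a level-4 subdivided icosahedron (5120 face bins, antipodally symmetrized,
length-weighted by default with a flag to count segments equally); f uses
all axons, f = V_intra/(V_box − V_myelin); shape metrics (diameter, Λ∥,
θ_u) use only axons ≥ 10 μm; D̃a aggregates per-axon contributions with
volume weights.

## FOD families

The exponential-decay family is the axially symmetric FOD whose invariants
are exactly p_l = Cλ^l for even l ≥ 2.  Resumming the even-degree
generating function Σ(2l+1)λ^l P_l(t) gives the closed form

    P(t) = (1−C) + (C/2)(1−λ²)[(1−2λt+λ²)^(−3/2) + (1+2λt+λ²)^(−3/2)],

the potential of two symmetric point sources at ±λn̂₀ inside the unit
sphere plus an isotropic floor.  Its correctness gate is convention-free:
Gauss–Legendre quadrature of P·P_l must return Cλ^l (the suite checks
l = 2…16 to 10⁻⁶).  Non-negativity: the minimum of P sits at the equator,
giving the analytic bound C ≤ 1/(1 − (1−λ²)(1+λ²)^(−3/2)); the numeric
grid-plus-Brent minimization is kept as a cross-check.  The Poisson-kernel
FOD is the one-parameter C = 1 member (p_l = λ^l); the Watson density
e^{κt²}/M(½,3/2,κ) gets its invariants by quadrature.  Neither follows
Cλ^l for generic parameters — the property that discriminates the family
from both references.

FOD lobe segmentation (for crossing-fiber voxels) runs steepest-ascent on
the mesh neighbor graph, merges peaks within 30° axially (which also
fuses antipodes), assigns sub-floor peaks to the nearest significant one,
renormalizes each lobe to unit mass and computes per-lobe p_l (rotation
invariance makes an explicit rotation to the lobe frame unnecessary).

## Forward model and protocol

K_l projections use 64-point Gauss–Legendre on x ∈ [0, 1]; with the
orthonormal-in-dΩ basis the factorization s_lm = p_lm K_l holds with no
extra constant (verified by the delta-FOD case, where s_l/K_l ≡ 1).  Two
simulation routes are provided and cross-checked to 10⁻⁵: the SH product
route, and direct spherical quadrature of the convolution on a
Gauss–Legendre × trapezoid product grid.  Signal invariants come from
per-shell least-squares SH fits (43 directions support lmax = 6 exactly:
28 coefficients); with fewer directions the degree is reduced with a
warning.  The spherical mean is taken from the l = 0 invariant of that
fit — unlike the raw directional average it carries no quadrature bias
from the finite direction design.

The default protocol reproduces the study design: shells b = 2, 3, 4
ms/μm², 43 directions each generated by seeded electrostatic repulsion on
the half-sphere, one b0 before each shell (132 volumes), δ = 6 ms,
Δ = 11.5 ms (timing is metadata only — Gaussian compartments have no
explicit time dependence).  Noise is Rician (magnitude of complex Gaussian
at σ = S₀/SNR) or Gaussian, always seeded.

## Estimators

* **DKI**: two-pass weighted linear least squares of the log-signal
  cumulant expansion to b²; weights are squared predicted signals.  Oracle:
  analytic cumulants of Gaussian mixtures are recovered to 10⁻⁸ when the
  signal is generated from the truncated expansion itself.
* **WMTI** (aligned-fiber closed form, from the published tensor-based
  description): f = K_max/(K_max+3) over a dense direction grid, then
  per-direction intra/extra apparent diffusivities taking the branch with
  the smaller intra value (hence Da ≤ De∥); tensors are refit from the
  directional values; p2 = √(3/2 Σ(λ_ai − Da/3)²)/Da from the intra-tensor
  eigenvalues.  Negative directional kurtosis flags the sample invalid.
* **NODDI**: Gaussian-likelihood fit of (f, f_w, κ) with fixed
  Da = De∥ = 0.6 μm²/ms (the ex vivo setting), the tortuosity constraint
  De⊥ = De∥(1−f), a Watson FOD expanded to lmax = 8 via quadrature
  invariants (the published κ→p2 closed forms are replaced by quadrature),
  an isotropic compartment at 2.0 μm²/ms, multi-start over
  κ ∈ {0.5, 2, 8, 32} and the fascicle axis refined within the fit.
* **SMT**: fit of (f, D∥) to per-shell spherical means under
  D∥ = Da = De∥ and the tortuosity constraint, diffusivities bounded by
  2 μm²/ms; p2 is read off afterwards from s₂ = p₂K₂ with K_l²-weighting.
* **SMI**: cubic polynomial regression (scikit-learn
  `PolynomialFeatures` + `LinearRegression`) from the 12 per-shell
  invariants {s₀, s₂, s₄, s₆}×{b} to (f, Da, De∥, De⊥, p₂, p₄, p₆), f_w
  fixed to 0.  The training prior is a stand-in (the published prior is
  not reproduced here): uniform f ∈ [0.05, 0.95], Da, De∥ ∈ [0.5, 2],
  De⊥ ∈ [0.05, 1.5] μm²/ms, FOD from the exponential-decay family with
  λ ∈ [0, 0.95] (C = 1 by default; a "rich" prior additionally samples C
  over the non-negativity domain so p₂, p₄, p₆ vary independently).
  Training at a finite SNR (default 50, as Gaussian noise of
  σ = 1/(SNR√n_dir) per invariant) regularizes the polynomial transverse
  to the noiseless manifold; this matters when test FODs (e.g. Watson
  histograms) are not exactly exponential-decay.  Strictly noiseless
  training (`snr=None`) is used for the self-consistency gates.  Test
  features outside the training hull are flagged as extrapolation.

All estimators are scikit-learn-style: settings in the constructor,
`fit(X)` over signal rows, results in `results_`/`params_`.

## Statistics

Pearson ρ with a two-sided t-test on N−2 degrees of freedom and a Fisher-z
95 % CI with variance 1/(N−3) (the MATLAB `corrcoef` convention);
Benjamini–Hochberg q-values via statsmodels, property-tested against the
brute-force step-up definition; Lin's ρ_c with population (1/N) moments
(Pearson keeps sample moments — both conventions documented because they
differ at small N); permutation and bootstrap variants behind flags.
Constant columns (e.g. NODDI's fixed Da) yield undefined correlations and
are excluded from the FDR family rather than erroring the whole matrix.
The sensitivity/specificity report treats rows as exchangeable paired
samples; when ROIs overlap (a combined region alongside its parts) this
overstates the effective N — a caveat inherited by any pooled design.

## Problem sizes

Defaults were chosen so the full chain runs comfortably on one CPU:
populations of 10²–10³ axons per sample for the synthetic studies
(dispersion-angle agreement uses 600 axons per angle; Monte-Carlo
convergence tests use 10⁵–2·10⁵ direction draws), SMI training at
5·10⁴ samples for the acceptance gates and 10⁴–2·10⁴ inside the demo
pipeline, and an 8-sample demo study with 80–150 axons per sample.

## Known limitations

* The estimators operate on single-fascicle synthetic voxels; the
  crossing-fiber partial-volume effects discussed for real cingulum ROIs
  are only representable through the FOD lobe tools, not the demo pipeline.
* Rician likelihoods are not implemented (fits assume denoised/Gaussian
  data); the Rician simulator exists for forward studies only.
* The WMTI closed form is exact only for two aligned Gaussian
  compartments; under dispersion its p2 saturates — visible in the demo
  pipeline and consistent with its aligned-fiber validity domain.
* SMI's accuracy depends on its stand-in prior; off-prior FOD shapes are
  handled through the rich prior + training noise, not by re-deriving the
  published training configuration.
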