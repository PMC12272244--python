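# smval — Standard Model validation against 3d axon morphometry

`smval` is a Python toolkit for validating the **Standard Model (SM) of
diffusion in white matter** against ground-truth axon morphometry of the
kind obtained from volume electron microscopy.  It is aimed at diffusion-MRI
microstructure researchers who want to test, on controlled synthetic tissue,
whether SM parameter estimators are *sensitive* (each estimate correlates
with its true tissue counterpart) and *specific* (it does not correlate with
the wrong ones).

## The model

A white-matter voxel's diffusion signal is modeled as a spherical
convolution of a fiber orientation distribution (FOD) P(n̂) with an axially
symmetric fascicle kernel,

    S(b, û)/S₀ = ∫ dn̂ P(n̂) K(b, ξ, û·n̂),
    K(b, ξ, x) = f e^(−b Da x²) + (1−f−f_w) e^(−b De⊥ − b(De∥−De⊥)x²) + f_w e^(−b Dw),

with kernel parameters ξ = {f, Da, De∥, De⊥} (+ free-water fraction f_w).
In the spherical-harmonic basis the convolution factorizes, s_lm = p_lm K_l,
and the rotational invariants obey **s_l = p_l K_l** per even degree l —
the identity on which the whole toolkit is built and tested.  The l = 2 FOD
invariant maps to a dispersion angle θ_p2 = arccos √((2p₂+1)/3).

The package spans the whole validation chain:

| module | what it does |
|---|---|
| `smval.synthetic` | 3d axon populations (Watson / exponential-decay-family orientations, sinusoidal undulation and beading, myelin via g-ratio) with analytic ground truth |
| `smval.morphometry` | EM-style metrics: dispersion angle θ, tangent FOD, intra-axonal fraction f, diameter 2r, axial tortuosity Λ∥ = ⟨Ā/A(z)⟩, undulation angle θ_u, and the predicted intra-axonal diffusivity D̃a = Σ w_k (D₀/Λ_k)⟨cos²θ_u⟩_k |
| `smval.fod` | SH decomposition, invariants p_l, θ_p2, the exponential-decay FOD family (p_l = Cλ^l exactly), Watson and Poisson-kernel references, FOD lobe segmentation |
| `smval.forward` | multi-shell PGSE simulation (b = 2, 3, 4 ms/μm², 3×43 directions + 3 b0 = 132 volumes), kernel projections K_l, signal invariants, Rician noise |
| `smval.estimators` | the four SM estimators — WMTI, NODDI, SMT, SMI — as scikit-learn-style estimators, plus DKI and FOD recovery from a fitted kernel |
| `smval.validation` | Pearson ρ with t-test p and Fisher CI, Benjamini–Hochberg FDR, Lin's concordance ρ_c, sensitivity/specificity reports |

## Worked example

Generate a dispersed population, measure it, simulate its signal, and fit it:

```python
import numpy as np
from smval import (PopulationSpec, generate_population, population_metrics,
                   sh_fit, rot_invariants, theta_from_p2,
                   KernelParams, make_protocol, simulate_signal)
from smval.estimators import SMTEstimator
from smval.fod import watson_kappa_for_theta

spec = PopulationSpec(n_axons=300, box=(50, 50, 40), fod_model="watson",
                      fod_params={"kappa": watson_kappa_for_theta(20.0)},
                      undulation_amplitude=0.3, beading_amplitude=0.3, seed=7)
pop = generate_population(spec)
metrics, fod_hist, _ = population_metrics(pop.axons, pop.box)
p2 = rot_invariants(sh_fit(fod_hist, lmax=8)).pl[2]
print(f"f = {metrics.f:.3f}  theta = {metrics.theta_deg:.1f} deg  "
      f"theta_p2 = {theta_from_p2(p2):.1f} deg  Da_pred = {metrics.Da_pred:.2f}")

protocol = make_protocol()                      # 132 volumes
xi = KernelParams(f=0.5, Da=1.6, De_par=1.6, De_perp=0.8)
signal = simulate_signal(protocol, sh_fit(fod_hist, lmax=8), xi)
fit = SMTEstimator(protocol).fit(signal.values[None, :]).results_[0]
print(f"SMT: f = {fit.xi.f:.3f}  D_par = {fit.xi.Da:.2f}")
```

prints

```
f = 0.097  theta = 20.2 deg  theta_p2 = 20.2 deg  Da_pred = 1.91
SMT: f = 0.506  D_par = 1.62
```

The morphometry arm recovers the generative 20° dispersion both directly
(θ, the length-weighted tangent average) and through the FOD invariant
(θ_p2) — the agreement of these two routes is one of the package's core
validation properties.  The SMT fit recovers the kernel it was handed to
within ~2% (the residual bias comes from the FOD's high-degree content
aliasing into the spherical mean at finite angular sampling).

A complete synthetic study — several "ROI" populations spanning a
sham-to-injured range, all four estimators, and the correlation matrices —
runs via `smval.pipeline.run_pipeline` or the CLI:

```bash
smval gen-axons --config spec.json --out pop.csv
smval morpho pop.csv --box 50 50 40 --out metrics.json
smval simulate --fod fod.csv --kernel '{"f":0.5,"Da":1.6,"De_par":1.6,"De_perp":0.8}' --out sig.csv
smval fit --method smi --signals sig.csv --out fit.json
smval validate --dmri dmri.csv --em em.csv --out report/
```

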