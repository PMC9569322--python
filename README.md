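# memquench

Tryptophan-fluorescence analysis of protein–membrane interactions: binding
isotherms, boundary-lipid counting by contact quenching, fluorophore depth
in the bilayer by distribution analysis of depth-dependent quenching, TCSPC
lifetime fits, binding kinetics, and spectral shape metrics — with a
synthetic-data generator so every stage is testable end to end.

The package is aimed at membrane biophysicists working with intrinsic Trp
(or other single-band) fluorescence of membrane-binding proteins — e.g.
pore-forming toxins such as the sticholysins binding
sphingomyelin-containing vesicles — who titrate protein with vesicles,
quench with spin-labeled lipids, and need the standard model fits with
uncertainties and goodness-of-fit in a scriptable, reproducible form.

## Models

**Binding isotherm.** A monomer occupies `n` lipids with association
constant `K_a`; mass action gives the bound fraction

θ(L_T, P_T) = 1 − ½[1 − L_T/(n·P_T) − 1/(K_a·P_T) + √((L_T/(n·P_T) + 1/(K_a·P_T) − 1)² + 4/(K_a·P_T))]

and the measured emission is F = F_sol·(1 + (F_b/F_sol − 1)·θ). Fitting a
vesicle titration yields (n, K_a, F_b/F_sol).

**Boundary-lipid contact quenching.** With a mole fraction [Q] of
quencher-labeled PC in the membrane, an accessible fluorophore touching
`L_n` lipids emits

F([Q]) = (F₀ − F_min)·(1 − [Q])^{L_n} + F_min,

so a quenching series yields the number of PC contacts `L_n` and the
non-quenchable fraction `F_min`. Stern–Volmer ratios F₀/F vs τ₀/τ separate
static from dynamic quenching.

**Depth distribution analysis.** Quenchers at calibrated depths `h` from
the bilayer center (TEMPO-PC 18.2 Å … 14-SLPC 2.9 Å) give a profile
QP(h) = F₀/F − 1 modelled as mirrored Gaussians

QP(h) = S/(σ√2π)·[exp(−(h−h_m)²/2σ²) + exp(−(h+h_m)²/2σ²)],

yielding mean depth `h_m`, spread σ and accessibility-related area `S`
(∫QP dh = 2S; the mirror term captures trans-leaflet quenching).

**Photophysics.** Multi-exponential TCSPC decays by iterative
reconvolution with the IRF under Poisson maximum likelihood;
intensity-weighted average lifetimes τ̄ = Σα_iτ_i²/Σα_iτ_i;
rise-to-plateau bi-exponential binding kinetics; λ_max/FWHM band metrics
with scattering-blank subtraction.

Each fitter is a scikit-learn-style estimator (`BindingIsotherm`,
`ExposureCurve`, `DepthQuenchingProfile`, `MultiExponentialDecay`,
`BindingKinetics`) with `fit`/`predict`/`get_params` and
trailing-underscore fitted attributes; module-level functions
(`fit_binding`, `fit_exposure`, `fit_depth`, …) wrap them and return typed
result records with standard errors, residuals, RMSD and χ²_red.

## Worked example

```python
import numpy as np
from memquench import (get_scenario, make_titration, make_quenching_series,
                       fit_binding, fit_exposure, make_depth_profile,
                       fit_depth, saturation_lp_ratio)

cfg = get_scenario("StnI_chol")              # StnI on DOPC:PSM:Chol 70:15:15
curve = make_titration(cfg, seed=7)          # CV 2% measurement noise
fit = fit_binding(curve)
print(f"n        = {fit.n:6.1f} lipids/monomer")
print(f"K_a      = {fit.K_a:8.2e} M^-1")
print(f"F_b/F_sol= {fit.F_b_ratio:6.2f}")
lp = saturation_lp_ratio(fit, threshold=0.95, protein_total=1e-7)
print(f"L/P at 95% binding = {lp:.0f}")

efit = fit_exposure(make_quenching_series(cfg, seed=7))
print(f"L_n   = {efit.L_n:.2f} PC contacts   F_min = {efit.F_min:.2f}")

dfit = fit_depth(make_depth_profile(cfg, seed=7, n_replicates=3))
print(f"h_m = {dfit.h_m:.1f} A   sigma = {dfit.sigma:.1f} A   S = {dfit.S:.1f} A")
```

prints

```
n        =   59.7 lipids/monomer
K_a      = 9.60e+08 M^-1
F_b/F_sol=   1.71
L/P at 95% binding = 69
L_n   = 3.00 PC contacts   F_min = 0.73
h_m = 15.2 A   sigma = 6.5 A   S = 4.9 A
```

The scenario's generating parameters are n = 55.3, K_a = 4.1×10⁸ M⁻¹,
F_b/F_sol = 1.75, L_n = 2.49, F_min = 0.72, (h_m, σ, S) = (15.0, 7.1, 5.2) Å;
the printed values are single noisy-realization estimates, so they scatter
around those targets — the stoichiometry within ~8%, the mean Trp depth
within ~0.2 Å here. Saturation (θ = 0.95) is reached below L/P = 80, which
is why an L/P of ~120 guarantees complete binding in quenching experiments.
With `noise_cv=0` / `noise_sd=0` every fit recovers the generating
parameters to machine precision.

The same analyses run from the shell on CSV inputs:

```sh
memquench simulate StnI_chol --kind quenching --seed 3 --out q.csv
memquench fit-exposure q.csv --out fit.json
memquench run --config pipeline.yaml --out report.json
```

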