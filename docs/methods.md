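# Methods

`memquench` quantifies how a pore-forming toxin engages a lipid bilayer from
tryptophan (Trp) fluorescence alone. It was built around the sticholysin
system — StnI and StnII from *Stichodactyla helianthus*, their inactive
double-cysteine mutants and single-Trp mutants, binding large unilamellar
vesicles (LUVs) of DOPC:PSM 80:20 or DOPC:PSM:Chol 70:15:15 — but every model
below is generic to membrane-protein fluorescence work.

## Binding isotherm

A monomer binds the vesicle surface occupying a patch of `n` lipids with
association constant `K_a` (per molar free lipid-site concentration
`L_T/n`). Mass action for P + site ⇌ complex gives a quadratic in the bound
concentration whose root, expressed as the bound fraction θ, is

```
θ(L_T, P_T) = 1 − ½ [ 1 − L_T/(n·P_T) − 1/(K_a·P_T)
                      + √( (L_T/(n·P_T) + 1/(K_a·P_T) − 1)² + 4/(K_a·P_T) ) ]
```

The measured emission is tied to θ through a two-state signal model,
`F = F_sol·(1 + (F_b/F_sol − 1)·θ)`: free protein emits `F_sol`, bound
protein is brighter by the factor `F_b/F_sol`. The signal model is a package
design choice — the bound/free emission ratio is reported alongside `n` and
`K_a`, which requires fitting intensity directly rather than a
pre-normalized bound fraction. Fitting is unweighted nonlinear least squares
(no replicate weighting scheme is assumed) with starting values `n` from the
lipid/protein (L/P) ratio at half-maximal signal rise, `K_a = 1e8 M⁻¹`,
`F_sol` from the zero-lipid point, and bounds `n ∈ (1, 1e4)`,
`K_a ∈ (1e4, 1e14) M⁻¹` — wide enough to cover every parameter row in the
scenario library with robust convergence. A curve whose fitted θ never
reaches 0.8 is flagged `no_saturation`; a flat curve is flagged
`no_response` with `F_b/F_sol ≈ 1`.

The closed form is cross-checked in the tests against an independent
bracketed root search of the mass-action equilibrium (`brentq` on
`K_a(P_T−B)(L_T/n−B) = B`); agreement is ~1e−12 in θ across a 20×20
(lipid, affinity) grid.

Dilution correction: for sequential vesicle-stock additions, per-point
concentrations are `P = P_0·V_0/V_cum` and `L = Σ(ΔV_i·stock_i)/V_cum`, so
protein mass `P·V_cum` is conserved exactly.

Derived quantities:

- **Saturation L/P** — the smallest L/P ratio with θ ≥ threshold, solved
  numerically in `L_T`. The package default threshold for "saturated" is
  0.95: at 0.95 the strongest-binding scenarios saturate below L/P ≈ 80,
  consistent with how saturation is judged on a titration curve by signal;
  θ = 0.99 is reached only near L/P ≈ 190 because the last percent of
  binding needs a large lipid excess (1−θ ≈ n/(K_a·P_T·L/P) in the
  saturating limit).
- **Inter-particle distance** — area per membrane particle
  `A = oligomer_size · (L/P) · lipid_area` (all lipids of both leaflets
  count by default; `leaflet="outer"` halves them), surface density
  σ = 1/A, mean center-to-center spacing `r_av = √(1/σ)/2 = √A/2`,
  edge-to-edge subtracts one protein diameter. Note the dimensionally
  consistent form `√(1/σ)/2` (a distance), not `√σ/2` (which is not); with
  L/P = 180 and 50 Å²/lipid it gives 47.4 Å center-to-center, ~25 Å
  edge-to-edge for an 11 Å protein radius, and >100 Å for octamers. The
  protein radius is a free parameter (11 Å default, the scale of a ~19 kDa
  actinoporin monomer).

## Boundary-lipid counting (contact quenching)

Replacing a mole fraction `[Q]` of the membrane PC with a doxyl- or
TEMPO-labeled PC quenches Trp emission on contact. If an accessible
fluorophore touches `L_n` lipids that exchange slowly on the excited-state
timescale, the chance that none carries the label is `(1−[Q])^{L_n}`, so

```
F([Q]) = (F_0 − F_min)·(1 − [Q])^{L_n} + F_min
```

with `F_min` the non-quenchable emission (shielded Trp plus residual
emission in pure quencher lipid). For normalized series `F_0` is fixed at 1
and only `(L_n, F_min)` are fitted (removing a redundant scale), with
`F_min` initialized at the smallest response, `L_n` at 2, and bounds
`L_n ∈ (0.01, 50)`, `F_min ∈ [0, 1)`. `[Q]` is a mole fraction internally;
the CSV reader accepts mol% and converts (override with `fraction=True`).
`F_min` itself is the accessible-fraction readout: an `F_min` of 0.72 means
72% of the emission is quencher-inaccessible.

Stern–Volmer representations are pointwise reciprocals (`F_0/F` from
intensities, `τ_0/τ` from intensity-weighted lifetimes); the transform is an
involution and is exposed as such. Static vs dynamic quenching is split per
point by the product rule `F_0/F = static × (τ_0/τ)`; the summary statistic
is the geometric mean of the static component over `[Q] > 0`. Values > 1
mean quenching beyond what lifetime shortening explains — apparent static
quenching, the regime where the contact model above applies. The model
predicts downward curvature of `F_0/F` vs `[Q]` whenever part of the
population is inaccessible; for `L_n` near 1 the curve is close to linear.

Identifiability: recovery of `L_n` degrades as `L_n` grows — at high `L_n`
the curve collapses onto `F_min` within a few points, so the data constrain
`L_n` mostly through the initial slope. Under additive noise σ = 0.01 the
median absolute error of `L_n` grows several-fold between `L_n = 2` and
`L_n = 9` (the relative error does not, because the denominator grows
faster); this mirrors the large absolute uncertainties that contact numbers
near 7–9 carry.

## Depth distribution analysis

Quencher lipids with the label at calibrated depths `h` from the bilayer
center probe the transverse position of the fluorophore. The quenching
profile `QP(h) = F_0/F − 1`, measured at fixed 30 mol% quencher, is fitted
with the distribution analysis: two mirrored Gaussians

```
QP(h) = S/(σ√(2π)) · [ exp(−(h−h_m)²/(2σ²)) + exp(−(h+h_m)²/(2σ²)) ]
```

where `h_m` is the mean fluorophore depth from the bilayer center (Å), σ the
transverse spread, and `S` an accessibility-related area; the mirror term
accounts for trans-leaflet quenching of deep fluorophores and the model
integrates to `2S` over the full axis. The exponent carries the squared
deviation — a non-squared deviation would not define a Gaussian and would
break both the QP(h) = QP(−h) symmetry and the 2S normalization. The
mirrored form makes ±`h_m` equivalent, so the non-negative branch is
canonical. The code refers to the model by name (mirrored-Gaussian
distribution analysis), not by an equation number.

Default label depths (Å from bilayer center): TEMPO-PC 18.2, 5-SLPC 12.1,
7-SLPC 11.5, 10-SLPC 10.1, 12-SLPC 6.4, 14-SLPC 2.9 — calibrated in pure
POPC bilayers, the best available approximation for mixed membranes;
override the catalog per composition since cholesterol may shift label
depths.

Fitting choices that matter:

- **Bounds.** `h_m ∈ [0, 25] Å`, σ ∈ [0.5, 16] Å by default — the physically
  meaningful half-bilayer span (including headgroups). Without them, weakly
  informative noisy profiles let `h_m` run to arbitrary depth under a
  near-flat wide-σ profile; those runaways are genuine global least-squares
  optima of the unconstrained problem, so the cure is the physical
  constraint, not the optimizer.
- **Multi-start.** The SSE surface has local minima (a centered single-hump
  solution competes with an off-center pair), so the fit restarts from a
  small set of mean depths and widths and keeps the lowest-SSE optimum. A
  brute-force 3-D grid search (0.1 Å steps) is packaged both as a
  convergence-failure fallback and as an independent cross-check oracle.
- **Point exclusion** is explicit: a mask plus a logged reason string per
  excluded point (trend deviation, or consistency with other variants), and
  the result carries the exclusion log in its flags. Warm-starting from
  another fit (e.g. the cholesterol-free system guiding a poorly
  constrained cholesterol fit) is exposed via `initial=`.

Precision: with the six-label catalog and per-replicate QP noise of
σ = 0.05, profiles averaged over 3 replicates localize `h_m` to a median of
~0.8 Å; single un-averaged profiles do not reach 1 Å — replicate averaging
before fitting is part of the intended workflow, not an optimization.

Depth differences between fits propagate uncertainties in quadrature,
`se(Δh) = √(se_a² + se_b²)`.

## Photophysics

**TCSPC decays.** Model: `(IRF ⊛ Σ α_i·exp(−t/τ_i)) + baseline`, fitted by
iterative reconvolution with the measured IRF (FFT convolution; tail fitting
available as a fallback mode when no IRF was recorded). Counting statistics
are handled by Poisson maximum likelihood through signed deviance residuals
— the default, because Neyman weighting (observed-count variances) biases
every lifetime low via the near-empty tail channels, and Pearson weighting
biases slightly high; both remain selectable for comparison. `chi2_red` is
then the reduced deviance (≈1 for a well-specified model). Initial lifetimes
spread geometrically around the mean photon arrival time minus the IRF
centroid (a moment estimate of the intensity-weighted lifetime); this keeps
the optimizer off the flat plateaus that defeat window-based starts.
Over-parameterized fits are returned flagged
(`component_collapse_consider_fewer_components` when adjacent lifetimes
come within a factor 1.2 or an amplitude fraction falls below 1%), not
raised, as long as the stalled iterate still describes the data.

Average lifetimes: intensity-weighted `τ̄ = Σα_iτ_i²/Σα_iτ_i` is the
quantity used in τ₀/τ comparisons against steady-state ratios; the
amplitude-weighted mean is also reported for transparency but never used
there. By Cauchy–Schwarz the intensity-weighted mean is never smaller.

**Binding kinetics.** Rise-to-plateau double exponential
`F(t) = F_∞ − A₁e^(−t/τ₁) − A₂e^(−t/τ₂)` (conventional sum-of-exponentials
form), τ₁ < τ₂ by sorting, amplitude fractions `α_i = A_i/(A₁+A₂)`.
Non-rising traces, vanishing second amplitudes and τ₁ below the sampling
interval are flagged.

**Spectra.** The scattering blank (same vesicles, no bindable protein) is
subtracted point-wise and floored at zero. λ_max comes from a local
quadratic fit within ±5 nm of the grid maximum — sub-nanometer resolution on
1 nm-sampled data, needed to resolve shifts of 0–2 nm; FWHM from linear
interpolation of the half-maximum crossings. Both metrics are exactly
invariant to intensity scaling and equivariant to wavelength translation;
edge maxima raise an error and ties resolve toward the blue with a flag.
This shape analysis is the package's own construction, documented here
because the choice (vs. log-normal band fitting or spectral moments) was
open; on a synthetic Gaussian band (center 335 nm, FWHM 55 nm) both metrics
are recovered within 0.2 nm.

## Synthetic data

Every generator is the exact forward model of its consuming fitter, so
noise-free output round-trips to the generating parameters (<1% everywhere,
machine precision in practice) and seeded noisy output tests recovery under
realistic conditions. The scenario library ships one parameter set per
studied toxin variant × membrane composition (11 in total; the W114→F
mutant has no cholesterol-free entries because it does not bind those
membranes).

Noise defaults, chosen to make the reported uncertainty magnitudes
qualitatively reproducible: multiplicative Gaussian CV 2% on steady-state
intensities, additive σ 0.05 on QP values (with optional n-replicate
averaging emulating the n = 2–3 replicate structure), Poisson counting
noise on TCSPC histograms. Grids: titrations over L/P 0–300 in 25 points at
100 nM protein; quencher series over `[Q]` 0–0.7 in 8 points; depth
profiles at the six catalog depths; kinetics over 0–300 s; spectra 305–450
nm at 1 nm. The TCSPC generator uses 4 ps channels × 16384 bins (~65 ns
window, the native resolution class of the photon-counting hardware
modelled), a Gaussian IRF of 0.5 ns FWHM centered at 2 ns, ~12,000 peak
counts for decays and ~10,000 for the IRF. A seed is mandatory for any
stochastic output; the same seed reproduces byte-identical data.

What the generators do **not** emulate: instrument drift, background from
stray light, vesicle scattering in decays, non-Gaussian IRF tails,
inner-filter effects, lipid-composition-dependent quencher depths, and any
lateral-diffusion physics (the contact model treats quencher occupancy as
static). Passing round-trip tests therefore demonstrates correctness of the
estimators under their own assumptions, not robustness to these real-data
effects.

## Numerical notes

- θ is clamped to [0,1] only against float round-off (tolerance 1e−9 guard;
  violations beyond that raise rather than mask a model error).
- All curve fits run through `lmfit` (Levenberg–Marquardt, or trust-region
  `least_squares` for the deviance-weighted decay fit with tolerances
  1e−10); standard errors come from the local covariance and are NaN when
  the information matrix is singular (e.g. exactly noise-free data).
- Degenerate inputs (flat curves, zero profiles, IRF-only decays, step
  kinetics) produce flagged results where a parameter is still well-defined
  and raise typed errors where nothing can be estimated.
- The grid-search depth oracle evaluates ~5×10⁶ parameter nodes chunked to
  bounded memory; ties inside one grid step along the correlated h_m/σ
  valley are inherent to quantized search, which is why oracle comparisons
  are made at the 0.1 Å resolution at which depth parameters are reported.

## Limitations

- The binding signal model assumes two emission states (free/bound); slow
  post-binding brightening is not modelled in the isotherm (it is visible
  to the kinetics module instead).
- The contact model's `L_n` is an effective count under the
  static-occupancy approximation; it is not a structural coordination
  number.
- Depth estimates inherit the POPC label-depth calibration; in
  cholesterol-rich membranes absolute depths (Å) are approximate even
  though between-composition comparisons remain meaningful.
- Lifetime analysis fits each trace independently; no global analysis
  across quencher concentrations is provided.
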