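# Methods

## Scope and model

`icglimit` estimates the minimum detectable concentration of a near-infrared
fluorophore (ICG as the concrete case) in a homogeneous turbid medium, given
the two optical backgrounds that survive spectral filtering: tissue
autofluorescence and backscattered excitation light leaking through the
emission filter.  The package has four computational layers:

1. **Excitation transport** (`mc_excitation`) — weighted-photon Monte Carlo
   in a cylinder (default 4 cm deep, 2 cm radius), MCML conventions:
   exponential free paths with `μt = μa + μs`, deposition `w·μa/μt` per
   interaction on an (r, z) grid, Henyey–Greenstein phase function,
   unpolarized Fresnel reflection/refraction at the top surface with specular
   loss deducted at launch, Russian roulette below weight 10⁻⁴ with survival
   factor 10.  Outputs the absorbed-energy map and diffuse reflectance `Rd`.
2. **Emission transport** (`mc_emission`) — every grid cell becomes an
   isotropic source with strength `a · nεQY`; launch cells are
   importance-sampled from the source map, launch points are uniform over the
   cell's annular volume, and transport reuses the excitation optical
   properties (the emission-wavelength properties are assumed equal, and
   fluorophore re-absorption is neglected — valid in the sub-nanomolar
   regime).  Outputs the relative fluorescence level `Rf` and `Rf/Rd`.
3. **Background separation** (`background_separation`) — the measured
   background of a fluorophore-free object splits into scatter and
   autofluorescence against a non-fluorescent reference:
   `Ssc = (Rd/Rd_ref)·Sbg_ref`, `Saf = Sbg − Ssc`, with quadrature error
   propagation; `Saf` is normalized by the reference fluorescence `Sf0`.
4. **Sensitivity model** (`sbr_sensitivity`) — `SBR = 1/(Saf/Sf + Ssc/Sf)`
   with `Ssc/Sf = (Rd/Rf)·Tex/Tem` and
   `Saf/Sf = (Saf/Sf0)·Rf_ref/Rf_target`; `Nmin` (the concentration where
   SBR = 1) is solved in closed form from the exact linearity of `Rf` in
   `n`, `ε`, `QY` rather than by root finding.

## Collection geometry

The surface tallies (`Rd`, `Rf`) count photons exiting the top surface
within a central *platform* of radius 1.2 cm, which suppresses edge effects
of the finite cylinder.  The default launch is a pencil beam on the axis;
by reciprocity, pencil-beam launch with extended collection approximates
laterally uniform (wide-field) illumination with localized collection.  A
uniform-disk launch mode (`beam_radius > 0`) emulates wide-field
illumination directly; in that mode the platform tallies are still expressed
per launched photon, so `Rf/Rd` — the quantity the sensitivity model
consumes — is unaffected by the overall geometric normalization.  The two
modes agree on `Rf/Rd` to ~3% at the tissue point; at the low-absorption
reference point the disk mode runs ~8% higher, because pencil-beam
collection clips the wide fluorescence halo slightly harder than the
reflectance halo.  The pencil beam is the default; the residual launch-mode
sensitivity is part of the model uncertainty at low absorption.

## Conventions that matter

* **Fluorophore absorption** is `ε·n` in decadic form without a ln(10)
  factor (so 10⁻¹⁰ M ICG with ε = 180,000 M⁻¹cm⁻¹ absorbs 1.8×10⁻⁵ cm⁻¹).
* **Source normalization.**  The emission source strength per cell is the
  absorbed weight times the brightness product `nεQY`, *not* the captured
  fraction `a·nεQY/μa`.  `Rf` is therefore a relative fluorescence level in
  a fixed unit convention rather than an absolute escape fraction; every
  downstream quantity uses `Rf` only inside ratios (`Rf/Rd`,
  `Rf_ref/Rf_target`), where the convention cancels.  This convention is the
  one under which the model's reference anchors (the Lipofundin `Rf/Rd`
  scale of ~1.4×10⁻⁷, and the tissue-over-reference ordering of `Rf/Rd`)
  are mutually consistent; the physically-normalized alternative (`/μa`)
  produces values two orders of magnitude larger and inverts the
  tissue/reference ordering, and is not what the calibrated sensitivity
  chain expects.
* **Refractive index**: `n_rel = 1.4` (typical soft tissue against air) by
  default, configurable.  Absolute `Rd` is sensitive to it (~10% across
  1.33–1.5); `Rf/Rd` moves by roughly ±8% over that range.
* **Anisotropy** g = 0.9; the sweep parameter is the *reduced* scattering
  coefficient, so `μs = μs′/(1−g)`.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `μa` grid | 0.01…1.28 cm⁻¹ (8 values) | absorption sweep |
| `μs′` grid | 5…160 cm⁻¹ (6 values) | reduced scattering sweep |
| reference medium | μa = 0.02, μs′ = 20 cm⁻¹ | ICG in 20% Lipofundin |
| reference photometry | n₀ = 6.5×10⁻¹⁰ M, ε₀ = 180,000, QY₀ = 0.02 | anchor for all scaling |
| tissue point | μa = 0.40, μs′ = 15 cm⁻¹, QY = 0.13 | canonical evaluation scenario |
| photometric intervals | ε ∈ [150k, 220k], QY ∈ [0.12, 0.14] | band evaluation (corner method) |
| filters | Tem = 0.28, OD = 9.2 | emission filter model |
| `Saf/Sf0` | 0.16 | measured AF-to-reference ratio (3200/20,000 counts) |
| grid | dr = dz = 0.01 cm | tally resolution (results stable to dr = 0.002) |
| photons | 10⁶ per stage (analysis), ~10⁴ (tests) | MC standard error ∝ 1/√N |
| roulette | threshold 10⁻⁴, survival ×10 | unbiased termination |

The band over (ε, QY) is evaluated at the four interval corners only; both
background ratios are monotone in `1/(εQY)`, so the corners bound the band
exactly (a test verifies corner = dense-sampling band).

## Numerical choices

* Seeds: every public entry point takes an integer seed; paired
  excitation/emission runs derive two child streams via `SeedSequence`.  The
  kernel uses an inlined xorshift128+ generator seeded through splitmix64;
  runs are bit-reproducible for a fixed seed.
* The energy budget (specular + reflected + transmitted + side loss +
  absorbed) closes to ≤10⁻³ relative on every run; with roulette disabled,
  termination deposits the residual weight and closure is exact to
  floating-point accumulation.
* `Rd` standard errors come from the per-photon exit-weight variance;
  `Rf` standard errors from the emission-photon variance at fixed absorbed
  map (the excitation-map uncertainty in `Rf` is second order and not
  propagated).
* Degenerate inputs: `μs′ = 0` is allowed (ballistic medium, spin skipped);
  an all-zero source map returns `Rf = 0` with a warning; negative separated
  autofluorescence (noise-driven) clips to zero with a flag.

## Validation

* Van de Hulst exact semi-infinite reflectance (albedo 0.9, isotropic,
  matched boundary): Rd = 0.41498; the kernel reproduces it within MC error.
* Mismatched boundary (n = 1.5): the kernel agrees with an independent
  unweighted analog simulation written against the same physics but sharing
  no code.
* High-albedo regime: total `Rd` matches the diffusion-theory plane albedo
  `a′/(1 + 2A(1−a′) + (1+2A/3)√(3(1−a′)))` within 2% for
  `μa/μs′ ≤ 0.01` (the test budget allows 10%).
* Exact linearity of `Rf` in photometry is verified against re-simulation
  under common random numbers (the sampling CDF is scale-invariant, so the
  trajectories coincide and the identity is exact).

## Synthetic data: what it does and does not show

The `synthetic_data` generator emulates the *structure* of the reference
measurements: a five-wavelength (650–792 nm) skin-like background series
with a known AF/scatter split, a non-fluorescent reference channel, the
reference fluorescence signal, and a dilution ladder of total signals.
Only measured anchor values seed the defaults — `Saf = 3200` and
`Sf0 = 20,000` counts at 785 nm, AF/scatter falling from 25× (650 nm) to 4×
(792 nm), ROI of 20,050 pixels, a 3.5% instrumental noise floor.  The
spectral shape *between* anchors (log-linear, AF falling ~8× across the
band) is a declared synthetic stand-in.  Noise is ROI-averaged shot noise
(per-pixel Poisson variance divided by the pixel count) plus the additive
floor; scalar mode injects the pre-divided equivalent, image mode writes
per-pixel Poisson TIFF frames — equivalent in distribution.

Consequently, passing recovery tests show that the separation arithmetic is
unbiased and its error propagation calibrated under this noise model; they
do not show robustness to real-skin confounders (chromophore structure,
spatial heterogeneity, flat-field errors), which the generator deliberately
omits.

## Known limitations

* Homogeneous media with uniformly distributed fluorophore; no layering,
  vessels, or depth-resolved targets.  Real targets at depth attenuate the
  signal but not the background, so computed `Nmin` values are lower bounds.
* Scalar filter model (`Tem`, `Tex`): no spectral resolution of emission or
  leak.
* The relative fluorescence level peaks at intermediate `μs′` even at low
  absorption (rising diffuse reflectance drains the absorbed fraction);
  claims of monotone growth of `Rf` with scattering hold only on the rising
  branch (`μs′ ≲ 20 cm⁻¹` at `μa = 0.02 cm⁻¹`).
* With 10⁶ photons per stage the MC standard error on `Rf/Rd` is ≈0.5%;
  analysis-scale runs use this budget, tests use ~10⁴–10⁵ photons where the
  checked property is budget-independent.
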