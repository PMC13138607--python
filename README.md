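# icglimit

**Detection-limit modelling for indocyanine green (ICG) fluorescence imaging
in turbid tissue.**

Fluorescence imaging with ICG guides surgery and diagnostics, but even a
perfect camera cannot see arbitrarily small amounts of dye: the image always
contains background from (i) tissue **autofluorescence** (AF) in the emission
band and (ii) backscattered excitation light **leaking** through the emission
filter.  `icglimit` quantifies how these backgrounds limit the minimum
detectable ICG concentration, combining a Monte Carlo model of light
transport in tissue with a signal-to-background model calibrated against
reference measurements.

## The model

The signal-to-background ratio of an image region containing the fluorophore
against fluorophore-free background tissue is

```
SBR = Sr/Sbg − 1 = 1 / (Saf/Sf + Ssc/Sf)
```

where `Sf` is the fluorophore signal, `Saf` the autofluorescence and `Ssc`
the filter leak.  The detection limit `Nmin` is the concentration at which
SBR = 1.  The two background ratios are obtained as

* `Ssc/Sf = (Rd/Rf) · Tex/Tem` — from the Monte Carlo diffuse reflectance
  `Rd` and relative fluorescence level `Rf` of the medium, and the emission
  filter's transmissions in the excitation (`Tex = 10^−OD`) and fluorescence
  (`Tem`) bands;
* `Saf/Sf = (Saf/Sf0) · Rf(reference)/Rf(tissue)` — a measured
  autofluorescence-to-reference ratio carried from a reference medium
  (ICG in 20% Lipofundin, `μa = 0.02 cm⁻¹`, `μs′ = 20 cm⁻¹`,
  `n₀ = 6.5×10⁻¹⁰ M`) to tissue optics through simulated `Rf` values.

Because the fluorophore contributes negligibly to bulk absorption, `Rf` is
exactly linear in concentration `n`, extinction coefficient `ε` and quantum
yield `QY`, which gives `Nmin` in closed form and lets one filter optical
density sweep produce the whole detection-limit curve, including the
AF-limited asymptote `Nmin(OD→∞) = n₀ · Saf/Sf(n₀)`.

The transport engine is a cylindrical-grid weighted-photon Monte Carlo
(MCML-style hop/drop/spin with Henyey–Greenstein scattering, Fresnel
boundaries and Russian roulette), followed by a second stage that re-emits
the absorbed-energy map as isotropic fluorescence sources.  It is validated
against the exact van de Hulst semi-infinite reflectance, an independent
analog simulation of the mismatched-boundary case, and a diffusion-theory
closed form at high albedo.

## Worked example

```python
from icglimit import (FilterSet, GridSpec, ICG_LIPOFUNDIN_REFERENCE,
                      LIPOFUNDIN_MEDIUM, TISSUE_MEDIUM, TissueScenario,
                      nmin_curve, simulate_fluorescence_pair)
from icglimit.mc_emission import Fluorophore
import pandas as pd

# Monte Carlo: reference medium and a tissue point (1e5 photons/stage here)
exc_lip, em_lip = simulate_fluorescence_pair(
    LIPOFUNDIN_MEDIUM, ICG_LIPOFUNDIN_REFERENCE, n_photons_excitation=100_000,
    n_photons_emission=100_000, seed=1)
exc_tis, em_tis = simulate_fluorescence_pair(
    TISSUE_MEDIUM, ICG_LIPOFUNDIN_REFERENCE, n_photons_excitation=100_000,
    n_photons_emission=100_000, seed=2)
print(f"Rf/Rd reference: {em_lip.ratio_rf_rd:.3e}")
print(f"Rf/Rd tissue:    {em_tis.ratio_rf_rd:.3e}")

grid = pd.DataFrame([
    {"mu_a": 0.02, "mu_s_reduced": 20.0,
     "rd_platform": exc_lip.rd_platform, "rf_platform": em_lip.rf_platform},
    {"mu_a": 0.40, "mu_s_reduced": 15.0,
     "rd_platform": exc_tis.rd_platform, "rf_platform": em_tis.rf_platform},
])
scenario = TissueScenario(
    medium=TISSUE_MEDIUM,
    fluorophore=Fluorophore(concentration=6.5e-10, epsilon=180_000, qy=0.13),
    af_ref_ratio=0.16)   # measured Saf/Sf0 = 3200 / 20,000 counts
sens = nmin_curve(scenario, FilterSet(t_em=0.28, od_ex=9.2), rf_rd_source=grid)
print(f"Ssc/Sf = {sens.ssc_over_sf:.2e}, Saf/Sf = {sens.saf_over_sf:.2e}")
print(f"Nmin = {sens.nmin:.2e} M, AF floor = {sens.nmin_floor:.2e} M")
```

prints (seeds as above)

```
Rf/Rd reference: 1.252e-07
Rf/Rd tissue:    8.116e-07
Ssc/Sf = 4.27e-04, Saf/Sf = 6.62e-03
Nmin = 4.58e-12 M, AF floor = 4.31e-12 M
```

Read: at this tissue optical point the autofluorescence term dominates the
filter leak by ~15×, so with an OD 9.2 emission filter the detection limit
(~4.5×10⁻¹² M, order 10⁻¹² M) sits essentially at the AF floor — a better
filter would no longer help.

A command-line pipeline covers the same ground from a YAML config
(`icglimit simulate-grid`, `separate`, `sensitivity`, `synth`, `all`);
synthetic skin-series and dilution-ladder fixtures with known ground truth
are generated by `icglimit.synthetic_data`.

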