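"""Signal-to-background model and minimum-detectable-concentration solver.

The signal-to-background ratio of a fluorescence image is

    SBR = Sr / Sbg - 1 = 1 / (Saf/Sf + Ssc/Sf),

where ``Sf`` is the fluorophore signal, ``Saf`` the tissue autofluorescence
and ``Ssc`` the excitation light leaking through the emission filter.  Both
background ratios are independent of excitation power and scale as ``1/n``
with fluorophore concentration, so the minimum detectable concentration
(defined by SBR = 1) has the closed form

    Nmin = n * (Saf/Sf(n) + Ssc/Sf(n))

for any evaluation concentration ``n``.  The two ratios come from the Monte
Carlo transport results:

    Ssc/Sf = (Rd / Rf) * Tex / Tem                      (filter leak)
    Saf/Sf = (Saf/Sf0) * Rf_reference / Rf_target       (AF recalibration)

with ``Tex = 10**(-OD)`` the emission filter's transmission at the excitation
wavelength and ``Saf/Sf0`` the measured autofluorescence-to-reference ratio.
As OD grows, the filter-leak term vanishes and ``Nmin`` levels off at the
autofluorescence floor ``n * Saf/Sf(n)`` — the fundamental sensitivity limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mc_excitation import OpticalMedium
from .mc_emission import ICG_LIPOFUNDIN_REFERENCE, LIPOFUNDIN_MEDIUM, Fluorophore

#: Default emission-filter OD sweep (optical densities at the excitation line).
DEFAULT_OD_GRID = tuple(np.arange(6.0, 14.0 + 1e-9, 0.25))


@dataclass(frozen=True)
class FilterSet:
    """Scalar emission-filter model.

    t_em : transmission in the fluorescence band (0 < t_em <= 1).
    od_ex : optical density at the excitation wavelength;
        ``Tex = 10**(-od_ex)``.  ``math.inf`` describes a perfect filter.
    """

    t_em: float = 0.28
    od_ex: float = 9.2

    def __post_init__(self) -> None:
        if not 0 < self.t_em <= 1:
            raise ValueError("t_em must be in (0, 1]")
        if self.od_ex < 0:
            raise ValueError("od_ex must be >= 0")

    @property
    def t_ex(self) -> float:
        return 10.0 ** (-self.od_ex)


@dataclass(frozen=True)
class TissueScenario:
    """A tissue evaluation point tied to the reference measurement.

    ``medium``/``fluorophore`` describe the tissue and the contrast agent at
    the evaluation point; the ``epsilon_interval`` and ``qy_interval``
    literature ranges bound the photometric uncertainty band; ``af_ref_ratio``
    is the measured ``Saf/Sf0``; the reference medium/fluorophore anchor all
    scaling (defaults: ICG in 20% Lipofundin).
    """

    medium: OpticalMedium
    fluorophore: Fluorophore
    epsilon_interval: tuple[float, float] = (150_000.0, 220_000.0)
    qy_interval: tuple[float, float] = (0.12, 0.14)
    af_ref_ratio: float = 0.16
    reference_medium: OpticalMedium = LIPOFUNDIN_MEDIUM
    reference_fluorophore: Fluorophore = ICG_LIPOFUNDIN_REFERENCE

    def __post_init__(self) -> None:
        if self.epsilon_interval[0] > self.epsilon_interval[1]:
            raise ValueError("epsilon_interval must be ordered (low, high)")
        if self.qy_interval[0] > self.qy_interval[1]:
            raise ValueError("qy_interval must be ordered (low, high)")
        if self.af_ref_ratio < 0:
            raise ValueError("af_ref_ratio must be >= 0")
        if self.reference_fluorophore.brightness <= 0:
            raise ValueError("reference fluorophore parameters must be positive")


#: Canonical tissue optical point of the sensitivity analysis.
TISSUE_MEDIUM = OpticalMedium(mu_a=0.40, mu_s_reduced=15.0)

#: ICG photometry in tissue (blood-like quantum yield).
ICG_TISSUE = Fluorophore(concentration=6.5e-10, epsilon=180_000.0, qy=0.13)


def ssc_over_sf(rd: float, rf: float, filters: FilterSet) -> float:
    """Filter-leak background ratio ``Ssc/Sf = (Rd/Rf) * Tex/Tem``."""
    if rf <= 0:
        raise ZeroDivisionError(
            "Rf must be > 0: the scenario has no fluorophore emission "
            "(zero concentration or quantum yield?)"
        )
    return (rd / rf) * filters.t_ex / filters.t_em


def saf_over_sf(af_ref_ratio: float, rf_reference: float, rf_target: float) -> float:
    """Autofluorescence ratio recalibrated from the reference medium.

    ``Saf/Sf = (Saf/Sf0) * Rf(reference) / Rf(target)`` — the measured ratio
    carried from the reference medium to a target medium/photometry through
    the simulated relative fluorescence levels.
    """
    if rf_target <= 0:
        raise ZeroDivisionError("target Rf must be > 0")
    return af_ref_ratio * rf_reference / rf_target


def sbr_at_concentration(
    saf_over_sf_at_n0: float,
    ssc_over_sf_at_n0: float,
    n: float,
    n0: float,
) -> float:
    """SBR at concentration ``n`` given background ratios evaluated at ``n0``.

    Both ratios scale as ``n0/n`` (the fluorophore signal is linear in
    concentration while the backgrounds are fixed), so
    ``SBR(n) = (n/n0) / (Saf/Sf + Ssc/Sf)|_{n0}``.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    total = (saf_over_sf_at_n0 + ssc_over_sf_at_n0) * (n0 / n)
    if total <= 0:
        return math.inf
    return 1.0 / total


@dataclass
class SensitivityResult:
    """Detection-limit summary at one tissue scenario.

    Ratios are evaluated at the scenario's fluorophore (concentration,
    epsilon, QY); ``nmin`` is concentration-invariant.  ``od_curve`` tabulates
    (od_ex, ssc_over_sf, nmin_low, nmin, nmin_high); ``nmin_floor`` is the
    OD -> infinity autofluorescence-limited asymptote.
    """

    ssc_over_sf: float
    saf_over_sf: float
    sbr: float
    nmin: float
    nmin_band: tuple[float, float]
    nmin_floor: float
    nmin_floor_band: tuple[float, float]
    od_curve: pd.DataFrame


# ---------------------------------------------------------------------------
# Monte Carlo grid lookup

def lookup_grid(
    grid_table: pd.DataFrame,
    medium: OpticalMedium,
    rtol: float = 1e-6,
) -> pd.Series:
    """Find the grid row for a medium's (mu_a, mu_s') pair.

    Raises ``LookupError`` naming the missing pair so sweep omissions are
    easy to diagnose.
    """
    sel = np.isclose(grid_table["mu_a"], medium.mu_a, rtol=rtol) & np.isclose(
        grid_table["mu_s_reduced"], medium.mu_s_reduced, rtol=rtol
    )
    rows = grid_table[sel]
    if len(rows) == 0:
        raise LookupError(
            f"no Monte Carlo grid entry for (mu_a={medium.mu_a:g}, "
            f"mu_s_reduced={medium.mu_s_reduced:g})"
        )
    return rows.iloc[0]


def nmin_curve(
    scenario: TissueScenario,
    filters: FilterSet,
    od_values: "np.ndarray | list[float] | tuple[float, ...]" = DEFAULT_OD_GRID,
    rf_rd_source: pd.DataFrame | None = None,
) -> SensitivityResult:
    """Solve the detection limit across an emission-filter OD sweep.

    ``rf_rd_source`` is the Monte Carlo grid table (columns mu_a,
    mu_s_reduced, rd_platform, rf_platform at reference photometry) and must
    contain both the scenario and the reference medium.  ``Nmin`` is solved in
    closed form from the linearity of the fluorescence signal; the band is
    evaluated at the four corners of the (epsilon, QY) rectangle, which bound
    it because both background ratios are monotone in ``1/(epsilon*QY)``.
    """
    if rf_rd_source is None:
        raise ValueError("rf_rd_source grid table is required")
    target_row = lookup_grid(rf_rd_source, scenario.medium)
    ref_row = lookup_grid(rf_rd_source, scenario.reference_medium)

    rd_t = float(target_row["rd_platform"])
    rf_t0 = float(target_row["rf_platform"])  # at reference photometry
    rf_ref0 = float(ref_row["rf_platform"])
    ref = scenario.reference_fluorophore

    def ratios(n: float, eps: float, qy: float) -> tuple[float, float]:
        """(Saf/Sf, Ssc/Sf at unit Tex/Tem aperture) at the given photometry."""
        scale = (n * eps * qy) / ref.brightness
        rf_t = rf_t0 * scale
        saf = saf_over_sf(scenario.af_ref_ratio, rf_ref0, rf_t)
        ssc_unit = rd_t / rf_t  # multiply by Tex/Tem for a concrete filter
        return saf, ssc_unit

    fl = scenario.fluorophore
    n_eval = fl.concentration
    if n_eval <= 0 or fl.qy <= 0:
        raise ValueError("scenario fluorophore must have positive n and QY")
    saf_pt, ssc_unit_pt = ratios(n_eval, fl.epsilon, fl.qy)
    ssc_pt = ssc_unit_pt * filters.t_ex / filters.t_em
    sbr_pt = 1.0 / (saf_pt + ssc_pt) if (saf_pt + ssc_pt) > 0 else math.inf

    corners = [
        (eps, qy)
        for eps in scenario.epsilon_interval
        for qy in scenario.qy_interval
    ]

    def nmin_at(eps: float, qy: float, t_ex: float) -> float:
        saf, ssc_unit = ratios(n_eval, eps, qy)
        return n_eval * (saf + ssc_unit * t_ex / filters.t_em)

    od_values = np.asarray(od_values, dtype=float)
    rows = []
    for od in od_values:
        t_ex = 10.0 ** (-od)
        nm = n_eval * (saf_pt + ssc_unit_pt * t_ex / filters.t_em)
        corner_vals = [nmin_at(eps, qy, t_ex) for eps, qy in corners]
        rows.append(
            {
                "od_ex": od,
                "ssc_over_sf": ssc_unit_pt * t_ex / filters.t_em * 1.0,
                "nmin_low": min(corner_vals),
                "nmin": nm,
                "nmin_high": max(corner_vals),
            }
        )
    od_curve = pd.DataFrame(rows)

    nmin_pt = n_eval * (saf_pt + ssc_pt)
    band_vals = [nmin_at(eps, qy, filters.t_ex) for eps, qy in corners]
    floor_pt = n_eval * saf_pt
    floor_band = [n_eval * ratios(n_eval, eps, qy)[0] for eps, qy in corners]
    return SensitivityResult(
        ssc_over_sf=ssc_pt,
        saf_over_sf=saf_pt,
        sbr=sbr_pt,
        nmin=nmin_pt,
        nmin_band=(min(band_vals), max(band_vals)),
        nmin_floor=floor_pt,
        nmin_floor_band=(min(floor_band), max(floor_band)),
        od_curve=od_curve,
    )


def sbr_concentration_curve(
    concentrations: "np.ndarray | list[float]",
    saf_over_sf_at_n0: float,
    ssc_over_sf_at_n0: float,
    n0: float,
) -> pd.DataFrame:
    """SBR vs concentration, with and without the autofluorescence term.

    The two curves differ by the constant factor ``1 + Saf/Ssc`` at every
    concentration.
    """
    rows = []
    for n in np.asarray(concentrations, dtype=float):
        rows.append(
            {
                "n": n,
                "sbr_with_af": sbr_at_concentration(
                    saf_over_sf_at_n0, ssc_over_sf_at_n0, n, n0
                ),
                "sbr_no_af": sbr_at_concentration(0.0, ssc_over_sf_at_n0, n, n0),
            }
        )
    return pd.DataFrame(rows)
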