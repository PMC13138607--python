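"""Fluorescence emission stage: absorbed-energy map -> escaping fluorescence.

Each grid cell of the excitation absorption map becomes an isotropic source
whose strength is the absorbed weight times the fluorophore brightness
``n * epsilon * QY`` (decadic convention: the fluorophore's absorption
coefficient is ``epsilon * n`` without a ln(10) factor).  Emission photons are
transported with the same optical properties as the excitation light and
tallied on the same collection platform, giving the relative fluorescence
level ``Rf`` and the setup-independent ratio ``Rf / Rd``.

``Rf`` here is a *relative* fluorescence level in the reference-anchored
convention of the SBR analysis: source strengths carry the brightness product
directly, so ``Rf`` is proportional to the escaping fluorescent energy per
unit incident excitation and only ever enters the downstream model through
ratios (``Rf/Rd``, ``Rf_reference/Rf_target``) where any fixed unit
convention cancels.

Because the medium absorption dominates and self-quenching is neglected,
``Rf`` is exactly linear in concentration, extinction coefficient and quantum
yield; :func:`scale_fluorescence` applies that scaling in closed form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernel
from .mc_excitation import AbsorptionMap, GridSpec, OpticalMedium, TransportResult


@dataclass(frozen=True)
class Fluorophore:
    """Photometric description of the contrast agent.

    concentration : molar concentration n (M); epsilon : molar extinction
    coefficient (1/M/cm); qy : fluorescence quantum yield.
    """

    concentration: float
    epsilon: float
    qy: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")
        if not 0 <= self.qy <= 1:
            raise ValueError("qy must be in [0, 1]")

    @property
    def brightness(self) -> float:
        """The product n * epsilon * QY that fluorescence output scales with."""
        return self.concentration * self.epsilon * self.qy


#: ICG in 20% Lipofundin at 785 nm — the reference photometry all scaling is
#: anchored to (n0 = 6.5e-10 M, eps0 = 180,000 / M / cm, QY0 = 0.02).
ICG_LIPOFUNDIN_REFERENCE = Fluorophore(concentration=6.5e-10, epsilon=180_000.0, qy=0.02)

#: Optical properties of the 20% Lipofundin reference medium at 785 nm.
LIPOFUNDIN_MEDIUM = OpticalMedium(mu_a=0.02, mu_s_reduced=20.0)


@dataclass
class SourceMap:
    """Fluorescence source weight per (r, z) cell, per unit incident weight."""

    s: np.ndarray
    grid: GridSpec

    @property
    def total_source(self) -> float:
        return float(self.s.sum())


def build_source_map(
    absorption_map: AbsorptionMap,
    fluorophore: Fluorophore,
    medium: OpticalMedium,
) -> SourceMap:
    """Convert absorbed excitation energy into fluorescence source strengths.

    Cell-wise ``s = a * (n * epsilon * QY)`` with ``a`` expressed per unit
    incident weight.  The brightness product enters the source directly (not
    as the captured fraction ``epsilon n / mu_a`` of the local absorption):
    this is the convention under which the reference measurements of the SBR
    model are calibrated, and since every downstream quantity is a ratio of
    two ``Rf`` values or of ``Rf`` to ``Rd``, the overall unit convention has
    no physical consequence.
    """
    if medium.mu_a <= 0:
        raise ValueError("mu_a must be > 0; the medium must dominate absorption")
    factor = fluorophore.brightness
    s = absorption_map.a * (factor / absorption_map.total_launched)
    return SourceMap(s=s, grid=absorption_map.grid)


@dataclass
class EmissionResult:
    """Relative fluorescence level from one emission run.

    ``rf_platform`` is the fluorescent weight escaping the top surface within
    the collection platform, per unit incident excitation weight;
    ``ratio_rf_rd`` divides it by the paired excitation run's platform Rd.
    """

    rf_platform: float
    rf_total: float
    rf_stderr: float
    ratio_rf_rd: float
    escaped_bottom: float
    escaped_side: float
    absorbed: float
    n_photons: int
    seed: int
    excitation_seed: int | None = None
    total_source: float = 0.0

    @property
    def launched(self) -> float:
        """Total emitted source weight (per unit incident excitation weight)."""
        return self.total_source


def propagate_emission(
    source_map: SourceMap,
    medium_emission: OpticalMedium,
    grid: GridSpec | None = None,
    n_photons: int = 1_000_000,
    seed: int = 0,
    excitation: TransportResult | None = None,
    use_roulette: bool = True,
) -> EmissionResult:
    """Transport emission photons launched from the source map.

    Cells are importance-sampled proportionally to their source weight; all
    photons carry equal weight and launch positions are uniform over the
    sampled cell's annular volume with isotropic initial direction.  Optical
    properties at the emission wavelength default to the excitation medium
    (pass ``medium_emission`` explicitly to override).

    If ``excitation`` is given, ``ratio_rf_rd`` is computed against its
    platform Rd and the pairing seed is recorded.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    grid = grid or source_map.grid
    total_source = source_map.total_source
    if total_source <= 0.0:
        warnings.warn("all-zero source map: no fluorescence to propagate")
        rd = excitation.rd_platform if excitation is not None else float("nan")
        return EmissionResult(
            rf_platform=0.0, rf_total=0.0, rf_stderr=0.0,
            ratio_rf_rd=0.0 if excitation is not None and rd > 0 else float("nan"),
            escaped_bottom=0.0, escaped_side=0.0, absorbed=0.0,
            n_photons=n_photons, seed=int(seed),
            excitation_seed=excitation.seed if excitation is not None else None,
            total_source=0.0,
        )
    cdf = np.cumsum(source_map.s.ravel())
    cdf /= cdf[-1]
    (esc_plat, esc_plat_sq, esc_top, esc_bottom, esc_side, absorbed,
     _roulette_lost) = _kernel.run_emission(
        cdf,
        medium_emission.mu_a, medium_emission.mu_s, medium_emission.g,
        medium_emission.n_rel, medium_emission.depth, medium_emission.radius,
        grid.dr, grid.dz, grid.nr, grid.nz,
        grid.platform_radius, n_photons, int(seed) % (2**31),
        use_roulette,
    )
    n = float(n_photons)
    mean = esc_plat / n
    var = max(esc_plat_sq / n - mean * mean, 0.0)
    stderr = math.sqrt(var / n) * total_source
    rf_platform = mean * total_source
    ratio = float("nan")
    exc_seed = None
    if excitation is not None:
        exc_seed = excitation.seed
        if excitation.rd_platform > 0:
            ratio = rf_platform / excitation.rd_platform
    return EmissionResult(
        rf_platform=rf_platform,
        rf_total=(esc_top / n) * total_source,
        rf_stderr=stderr,
        ratio_rf_rd=ratio,
        escaped_bottom=(esc_bottom / n) * total_source,
        escaped_side=(esc_side / n) * total_source,
        absorbed=(absorbed / n) * total_source,
        n_photons=n_photons,
        seed=int(seed),
        excitation_seed=exc_seed,
        total_source=total_source,
    )


def scale_fluorescence(rf_base: float, base: Fluorophore, target: Fluorophore) -> float:
    """Exact linear rescaling of Rf between photometric parameter sets.

    ``Rf(n, eps, QY) = Rf(n0, eps0, QY0) * (n eps QY) / (n0 eps0 QY0)`` —
    valid because the fluorophore contributes negligibly to bulk absorption.
    """
    if base.brightness <= 0:
        raise ValueError(
            "base fluorophore must have strictly positive n, epsilon and QY"
        )
    return rf_base * target.brightness / base.brightness


def simulate_fluorescence_pair(
    medium: OpticalMedium,
    fluorophore: Fluorophore,
    grid: GridSpec | None = None,
    n_photons_excitation: int = 1_000_000,
    n_photons_emission: int = 1_000_000,
    seed: int = 0,
    beam_radius: float = 0.0,
) -> tuple[TransportResult, EmissionResult]:
    """Convenience wrapper: run the matched excitation + emission pair.

    Derives two child seeds from ``seed`` so the stages use independent
    streams, and pairs the results so ``ratio_rf_rd`` is well defined.
    """
    from .mc_excitation import simulate_excitation

    grid = grid or GridSpec.for_medium(medium)
    seed_exc, seed_em = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    exc = simulate_excitation(
        medium, grid, n_photons_excitation, int(seed_exc), beam_radius=beam_radius
    )
    src = build_source_map(exc.absorption_map, fluorophore, medium)
    em = propagate_emission(
        src, medium, grid, n_photons_emission, int(seed_em), excitation=exc
    )
    return exc, em
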