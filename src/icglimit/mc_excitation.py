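"""Excitation-light transport in a homogeneous turbid cylinder.

Simulates a semi-infinite scattering/absorbing medium illuminated at the top
surface and produces (i) the map of absorbed excitation energy on an (r, z)
grid — the input to the fluorescence stage — and (ii) the diffuse reflectance
``Rd``, both in total and restricted to a central collection platform that
suppresses edge effects of the finite cylinder.

Units: lengths in cm, optical coefficients in 1/cm.  All tallies are
dimensionless fractions of the incident photon weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernel


@dataclass(frozen=True)
class OpticalMedium:
    """Homogeneous turbid medium.

    Parameters
    ----------
    mu_a : absorption coefficient (1/cm), > 0.
    mu_s_reduced : reduced scattering coefficient mu_s * (1 - g) (1/cm), >= 0.
    g : Henyey-Greenstein scattering anisotropy, 0 <= g < 1.
    n_rel : refractive index relative to the ambient medium, >= 1.
    depth, radius : extent of the simulated cylinder (cm); chosen large
        relative to the transport mean free path so the lateral and bottom
        boundaries are second order.
    """

    mu_a: float
    mu_s_reduced: float
    g: float = 0.9
    n_rel: float = 1.4
    depth: float = 4.0
    radius: float = 2.0

    def __post_init__(self) -> None:
        if not self.mu_a > 0:
            raise ValueError(f"mu_a must be > 0, got {self.mu_a}")
        if self.mu_s_reduced < 0:
            raise ValueError(f"mu_s_reduced must be >= 0, got {self.mu_s_reduced}")
        if not 0 <= self.g < 1:
            raise ValueError(f"g must be in [0, 1), got {self.g}")
        if self.n_rel < 1:
            raise ValueError(f"n_rel must be >= 1, got {self.n_rel}")
        if not (self.depth > 0 and self.radius > 0):
            raise ValueError("depth and radius must be > 0")

    @property
    def mu_s(self) -> float:
        """Full scattering coefficient mu_s_reduced / (1 - g)."""
        return self.mu_s_reduced / (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        return self.mu_a + self.mu_s

    @property
    def transport_mfp(self) -> float:
        """Transport mean free path 1 / (mu_a + mu_s_reduced) (cm)."""
        return 1.0 / (self.mu_a + self.mu_s_reduced)


@dataclass(frozen=True)
class GridSpec:
    """Cylindrical tally grid and collection geometry.

    dr, dz are bin widths (cm); nr, nz bin counts; ``platform_radius`` is the
    radius of the central collection disk on the top surface (cm).
    """

    dr: float = 0.01
    dz: float = 0.01
    nr: int = 200
    nz: int = 400
    platform_radius: float = 1.2

    def __post_init__(self) -> None:
        if not (self.dr > 0 and self.dz > 0):
            raise ValueError("dr and dz must be > 0")
        if not (self.nr >= 1 and self.nz >= 1):
            raise ValueError("nr and nz must be >= 1")
        if self.platform_radius <= 0:
            raise ValueError("platform_radius must be > 0")

    @classmethod
    def for_medium(cls, medium: OpticalMedium, dr: float = 0.01, dz: float = 0.01,
                   platform_radius: float = 1.2) -> "GridSpec":
        """Grid spanning the full medium geometry at the given resolution."""
        return cls(
            dr=dr, dz=dz,
            nr=int(math.ceil(medium.radius / dr)),
            nz=int(math.ceil(medium.depth / dz)),
            platform_radius=platform_radius,
        )

    def validate_against(self, medium: OpticalMedium) -> None:
        if self.nr * self.dr < medium.radius - 1e-12:
            raise ValueError(
                f"grid radial extent {self.nr * self.dr:g} cm smaller than "
                f"medium radius {medium.radius:g} cm"
            )
        if self.nz * self.dz < medium.depth - 1e-12:
            raise ValueError(
                f"grid axial extent {self.nz * self.dz:g} cm smaller than "
                f"medium depth {medium.depth:g} cm"
            )
        if self.platform_radius > medium.radius + 1e-12:
            raise ValueError("platform_radius exceeds the medium radius")


@dataclass
class AbsorptionMap:
    """Deposited excitation weight per (r, z) cell, as absolute photon weight.

    ``a[ir, iz]`` sums the weight absorbed in the annular cell
    [ir*dr, (ir+1)*dr) x [iz*dz, (iz+1)*dz).  ``total_launched`` is the total
    incident weight (one per photon); ``specular`` the weight lost to specular
    reflection at launch.
    """

    a: np.ndarray
    total_launched: float
    specular: float
    grid: GridSpec

    @property
    def total_absorbed(self) -> float:
        return float(self.a.sum())

    @property
    def fraction_absorbed(self) -> float:
        """Absorbed weight per unit incident weight."""
        return self.total_absorbed / self.total_launched


@dataclass
class TransportResult:
    """Outcome of one excitation run; all reflectances are per unit incident weight."""

    rd_platform: float
    rd_total: float
    transmitted: float
    side_loss: float
    rd_stderr: float
    n_photons: int
    seed: int
    absorption_map: AbsorptionMap
    roulette_lost: float = 0.0

    @property
    def specular(self) -> float:
        return self.absorption_map.specular / self.absorption_map.total_launched


def simulate_excitation(
    medium: OpticalMedium,
    grid: GridSpec,
    n_photons: int,
    seed: int,
    beam_radius: float = 0.0,
    use_roulette: bool = True,
) -> TransportResult:
    """Run the excitation Monte Carlo stage.

    Photons enter the top surface travelling along +z.  ``beam_radius = 0``
    (default) launches a pencil beam on the axis, relying on the reciprocity
    between a point source with extended collection and extended illumination
    with point collection; ``beam_radius > 0`` instead distributes launch
    points uniformly over a disk of that radius, which emulates wide-field
    (plane-wave) illumination of the finite cylinder directly.

    Deterministic for fixed ``seed``, ``n_photons`` and inputs.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    grid.validate_against(medium)
    if beam_radius < 0 or beam_radius > medium.radius:
        raise ValueError("beam_radius must be within [0, medium.radius]")
    (a_grid, rd_plat, rd_plat_sq, rd_total, transmitted, side_loss,
     specular, roulette_lost) = _kernel.run_excitation(
        medium.mu_a, medium.mu_s, medium.g, medium.n_rel,
        medium.depth, medium.radius,
        grid.dr, grid.dz, grid.nr, grid.nz,
        grid.platform_radius, n_photons, int(seed) % (2**31),
        beam_radius, use_roulette,
    )
    n = float(n_photons)
    mean = rd_plat / n
    var = max(rd_plat_sq / n - mean * mean, 0.0)
    stderr = math.sqrt(var / n)
    amap = AbsorptionMap(a=a_grid, total_launched=n, specular=specular, grid=grid)
    return TransportResult(
        rd_platform=mean,
        rd_total=rd_total / n,
        transmitted=transmitted / n,
        side_loss=side_loss / n,
        rd_stderr=stderr,
        n_photons=n_photons,
        seed=int(seed),
        absorption_map=amap,
        roulette_lost=roulette_lost / n,
    )


@dataclass
class EnergyBudget:
    """Per-channel weight fractions of one run and the closure residual."""

    specular: float
    rd_total: float
    transmitted: float
    side_loss: float
    absorbed: float
    residual: float
    relative_residual: float
    closed: bool
    tolerance: float = 1.0e-3


def energy_audit(result: TransportResult, tolerance: float = 1.0e-3) -> EnergyBudget:
    """Check weight conservation: launched = specular + Rd + T + side + absorbed.

    Russian roulette is unbiased but not pathwise-conserving, so the residual
    is only zero in expectation; ``closed`` flags
    ``|residual| / launched <= tolerance`` (default 1e-3).
    """
    amap = result.absorption_map
    total = amap.total_launched
    absorbed = amap.total_absorbed / total
    accounted = (
        result.specular + result.rd_total + result.transmitted
        + result.side_loss + absorbed
    )
    residual = 1.0 - accounted
    return EnergyBudget(
        specular=result.specular,
        rd_total=result.rd_total,
        transmitted=result.transmitted,
        side_loss=result.side_loss,
        absorbed=absorbed,
        residual=residual,
        relative_residual=abs(residual),
        closed=abs(residual) <= tolerance,
        tolerance=tolerance,
    )


def diffusion_theory_rd(mu_a: float, mu_s_reduced: float, n_rel: float = 1.4) -> float:
    """Closed-form diffusion estimate of total diffuse reflectance of a
    semi-infinite medium under normal-incidence illumination.

    Uses the similarity parameter a' = mu_s' / (mu_a + mu_s') and the standard
    internal-reflection boundary parameter A = (1 + r_d) / (1 - r_d) with the
    Egan-Hilgeman polynomial fit r_d(n).  Accurate to a few percent in the
    high-albedo regime (mu_a / mu_s' << 1); used as an independent cross-check
    of the Monte Carlo, not as part of it.
    """
    if mu_s_reduced <= 0:
        return 0.0
    a_prime = mu_s_reduced / (mu_a + mu_s_reduced)
    if n_rel == 1.0:
        big_a = 1.0
    else:
        r_d = -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
        big_a = (1.0 + r_d) / (1.0 - r_d)
    arg = math.sqrt(3.0 * (1.0 - a_prime))
    return a_prime / (
        1.0 + 2.0 * big_a * (1.0 - a_prime) + (1.0 + 2.0 * big_a / 3.0) * arg
    )
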