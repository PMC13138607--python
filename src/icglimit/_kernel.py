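"""Numba photon-transport kernels shared by the excitation and emission stages.

Cylindrically symmetric weighted-photon Monte Carlo in the MCML tradition:
exponential free paths with attenuation ``mu_t = mu_a + mu_s``, per-interaction
weight deposition ``w * mu_a / mu_t``, Henyey-Greenstein scattering, Fresnel
reflection/refraction at the top surface, Russian roulette termination.

Positions are tracked in 3-D Cartesian coordinates; absorbed weight is tallied
on an (r, z) grid.  The bottom and lateral boundaries are absorbing: weight
crossing them is recorded as transmitted / side loss and the photon is killed
(the simulated cylinder is large enough that these channels are second order).

Everything here is private plumbing; the public API lives in
:mod:`icglimit.mc_excitation` and :mod:`icglimit.mc_emission`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit, uint64

# Termination constants (MCML conventions).
WEIGHT_THRESHOLD = 1.0e-4
ROULETTE_SURVIVAL = 10.0

_INV_2_53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, fastmath=True, inline="always")
def _rng_next(state):
    """xorshift128+ step; returns a uniform double in [0, 1).

    A small counter-based-quality generator inlined for speed; seeded per run
    through splitmix64 so distinct seeds give independent streams.
    """
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << uint64(23)
    s1 ^= s1 >> uint64(17)
    s1 ^= s0
    s1 ^= s0 >> uint64(26)
    state[1] = s1
    return float((s0 + s1) >> uint64(11)) * _INV_2_53


@njit(cache=True, fastmath=True)
def _rng_seed(seed):
    """Expand an integer seed into xorshift128+ state via splitmix64."""
    state = np.empty(2, dtype=np.uint64)
    x = uint64(seed) + uint64(0x9E3779B97F4A7C15)
    for i in range(2):
        z = x
        z = (z ^ (z >> uint64(30))) * uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> uint64(27))) * uint64(0x94D049BB133111EB)
        z = z ^ (z >> uint64(31))
        state[i] = z
        x = x + uint64(0x9E3779B97F4A7C15)
    if state[0] == uint64(0) and state[1] == uint64(0):
        state[0] = uint64(1)
    return state


@njit(cache=True, fastmath=True)
def _fresnel_reflectance(n_rel: float, cos_i: float) -> float:
    """Unpolarized Fresnel reflectance for a photon hitting the top surface
    from inside a medium of relative index ``n_rel`` (medium/ambient)."""
    if cos_i > 0.9999999:
        r = (n_rel - 1.0) / (n_rel + 1.0)
        return r * r
    sin_i = math.sqrt(1.0 - cos_i * cos_i)
    sin_t = n_rel * sin_i
    if sin_t >= 1.0:  # total internal reflection
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True, inline="always")
def _unit_azimuth(rng):
    """Random unit vector in the plane, trig-free (rejection sampling)."""
    while True:
        a = 2.0 * _rng_next(rng) - 1.0
        b = 2.0 * _rng_next(rng) - 1.0
        s = a * a + b * b
        if 0.0 < s <= 1.0:
            inv = 1.0 / math.sqrt(s)
            return a * inv, b * inv


@njit(cache=True, fastmath=True, inline="always")
def _spin(ux: float, uy: float, uz: float, g: float, rng):
    """Sample a Henyey-Greenstein deflection and rotate the direction."""
    if g == 0.0:
        cos_t = 2.0 * _rng_next(rng) - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * _rng_next(rng))
        cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
        if cos_t > 1.0:
            cos_t = 1.0
        elif cos_t < -1.0:
            cos_t = -1.0
    sin_t = math.sqrt(1.0 - cos_t * cos_t)
    cos_p, sin_p = _unit_azimuth(rng)
    if abs(uz) > 0.99999:
        nx = sin_t * cos_p
        ny = sin_t * sin_p
        nz = cos_t if uz >= 0.0 else -cos_t
    else:
        den = math.sqrt(1.0 - uz * uz)
        inv_den = 1.0 / den
        nx = sin_t * (ux * uz * cos_p - uy * sin_p) * inv_den + ux * cos_t
        ny = sin_t * (uy * uz * cos_p + ux * sin_p) * inv_den + uy * cos_t
        nz = -sin_t * cos_p * den + uz * cos_t
    inv_norm = 1.0 / math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx * inv_norm, ny * inv_norm, nz * inv_norm


@njit(cache=True, fastmath=True)
def _trace(
    x: float,
    y: float,
    z: float,
    ux: float,
    uy: float,
    uz: float,
    w: float,
    mu_a: float,
    mu_s: float,
    g: float,
    n_rel: float,
    depth: float,
    radius: float,
    dr: float,
    dz: float,
    nr: int,
    nz: int,
    a_grid,
    use_roulette: bool,
    rng,
):
    """Propagate one photon until it dies.

    Returns ``(channel, exit_r, exit_w, lost)`` where channel is
    0 = escaped through the top surface, 1 = transmitted through the bottom,
    2 = escaped laterally, 3 = terminated by roulette.  ``lost`` is the
    weight discarded at a roulette kill (zero elsewhere); absorbed weight is
    tallied into ``a_grid`` in place.
    """
    mu_t = mu_a + mu_s
    inv_mu_t = 1.0 / mu_t
    albedo_drop = mu_a * inv_mu_t
    inv_dr = 1.0 / dr
    inv_dz = 1.0 / dz
    radius2 = radius * radius
    while True:
        s = -math.log(_rng_next(rng)) * inv_mu_t
        # Top-surface interaction (at most one per step: after an internal
        # reflection the photon moves away from the surface).
        if uz < 0.0:
            d_boundary = -z / uz
            if d_boundary <= s:
                x += ux * d_boundary
                y += uy * d_boundary
                z = 0.0
                s -= d_boundary
                if _rng_next(rng) > _fresnel_reflectance(n_rel, -uz):
                    return 0, math.sqrt(x * x + y * y), w, 0.0
                uz = -uz
        x += ux * s
        y += uy * s
        z += uz * s
        if z >= depth:
            return 1, 0.0, w, 0.0
        r2 = x * x + y * y
        if r2 >= radius2:
            return 2, 0.0, w, 0.0
        r = math.sqrt(r2)
        ir = int(r * inv_dr)
        if ir >= nr:
            ir = nr - 1
        iz = int(z * inv_dz)
        if iz >= nz:
            iz = nz - 1
        dw = w * albedo_drop
        a_grid[ir, iz] += dw
        w -= dw
        if mu_s > 0.0:
            ux, uy, uz = _spin(ux, uy, uz, g, rng)
        if w < WEIGHT_THRESHOLD:
            if not use_roulette:
                # absorbing termination: deposit the residue so the weight
                # budget closes exactly (used for conservation checks)
                a_grid[ir, iz] += w
                return 3, 0.0, 0.0, 0.0
            if _rng_next(rng) < 1.0 / ROULETTE_SURVIVAL:
                w *= ROULETTE_SURVIVAL
            else:
                return 3, 0.0, 0.0, w


@njit(cache=True, fastmath=True)
def run_excitation(
    mu_a: float,
    mu_s: float,
    g: float,
    n_rel: float,
    depth: float,
    radius: float,
    dr: float,
    dz: float,
    nr: int,
    nz: int,
    platform_radius: float,
    n_photons: int,
    seed: int,
    beam_radius: float,
    use_roulette: bool,
):
    """Excitation stage: photons enter the top surface travelling straight down.

    ``beam_radius == 0`` launches a pencil beam on the axis; otherwise launch
    points are sampled uniformly over a disk of that radius.  Each photon
    carries unit incident weight; specular reflection at normal incidence is
    deducted at launch.

    Returns ``(a_grid, rd_platform_sum, rd_platform_sumsq, rd_total,
    transmitted, side_loss, specular, roulette_lost)``.
    """
    rng = _rng_seed(seed)
    a_grid = np.zeros((nr, nz))
    rsp = ((n_rel - 1.0) / (n_rel + 1.0)) ** 2
    w0 = 1.0 - rsp
    rd_plat = 0.0
    rd_plat_sq = 0.0
    rd_total = 0.0
    transmitted = 0.0
    side_loss = 0.0
    roulette_lost = 0.0
    for _ in range(n_photons):
        if beam_radius > 0.0:
            r0 = beam_radius * math.sqrt(_rng_next(rng))
            cos_p, sin_p = _unit_azimuth(rng)
            x = r0 * cos_p
            y = r0 * sin_p
        else:
            x = 0.0
            y = 0.0
        channel, exit_r, exit_w, lost = _trace(
            x, y, 0.0, 0.0, 0.0, 1.0, w0,
            mu_a, mu_s, g, n_rel, depth, radius,
            dr, dz, nr, nz, a_grid, use_roulette, rng,
        )
        plat_w = 0.0
        if channel == 0:
            rd_total += exit_w
            if exit_r <= platform_radius:
                plat_w = exit_w
        elif channel == 1:
            transmitted += exit_w
        elif channel == 2:
            side_loss += exit_w
        else:
            roulette_lost += lost
        rd_plat += plat_w
        rd_plat_sq += plat_w * plat_w
    specular = rsp * n_photons
    return (
        a_grid, rd_plat, rd_plat_sq, rd_total,
        transmitted, side_loss, specular, roulette_lost,
    )


@njit(cache=True, fastmath=True)
def run_emission(
    source_cdf,
    mu_a: float,
    mu_s: float,
    g: float,
    n_rel: float,
    depth: float,
    radius: float,
    dr: float,
    dz: float,
    nr: int,
    nz: int,
    platform_radius: float,
    n_photons: int,
    seed: int,
    use_roulette: bool,
):
    """Emission stage: isotropic launches from grid cells sampled by source weight.

    ``source_cdf`` is the cumulative sum of the flattened (nr, nz) source map,
    normalized to end at 1.  Launch positions are uniform over the sampled
    cell's annular volume.  Every photon carries unit weight; the caller scales
    the escape fraction by the total source strength.

    Returns ``(escaped_platform_sum, escaped_platform_sumsq, escaped_top_total,
    escaped_bottom, escaped_side, absorbed, roulette_lost)``.
    """
    rng = _rng_seed(seed)
    # Scratch grid for absorbed emission weight (budget audit only).
    a_grid = np.zeros((nr, nz))
    esc_plat = 0.0
    esc_plat_sq = 0.0
    esc_top = 0.0
    esc_bottom = 0.0
    esc_side = 0.0
    roulette_lost = 0.0
    for _ in range(n_photons):
        idx = np.searchsorted(source_cdf, _rng_next(rng))
        if idx >= source_cdf.shape[0]:
            idx = source_cdf.shape[0] - 1
        ir = idx // nz
        iz = idx % nz
        r_lo = ir * dr
        r_hi = r_lo + dr
        r0 = math.sqrt(r_lo * r_lo + _rng_next(rng) * (r_hi * r_hi - r_lo * r_lo))
        z0 = (iz + _rng_next(rng)) * dz
        # Azimuthal symmetry: place the photon on the +x axis.
        uz0 = 2.0 * _rng_next(rng) - 1.0
        sin0 = math.sqrt(1.0 - uz0 * uz0)
        cos_p, sin_p = _unit_azimuth(rng)
        ux0 = sin0 * cos_p
        uy0 = sin0 * sin_p
        channel, exit_r, exit_w, lost = _trace(
            r0, 0.0, z0, ux0, uy0, uz0, 1.0,
            mu_a, mu_s, g, n_rel, depth, radius,
            dr, dz, nr, nz, a_grid, use_roulette, rng,
        )
        plat_w = 0.0
        if channel == 0:
            esc_top += exit_w
            if exit_r <= platform_radius:
                plat_w = exit_w
        elif channel == 1:
            esc_bottom += exit_w
        elif channel == 2:
            esc_side += exit_w
        else:
            roulette_lost += lost
        esc_plat += plat_w
        esc_plat_sq += plat_w * plat_w
    absorbed = a_grid.sum()
    return esc_plat, esc_plat_sq, esc_top, esc_bottom, esc_side, absorbed, roulette_lost
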