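"""Photon Monte Carlo in a homogeneous turbid slab.

Weight-propagation random walk under the similarity (reduced-scattering)
approximation: scattering is isotropic with coefficient ``mu_s_prime``, so the
walk reproduces diffuse transport at length scales beyond one transport mean
free path without requiring an anisotropy factor.  The output is a
cylindrically collapsed fluence grid (depth x radius) from which
wavelength-dependent penetration depths are derived.

The far-field decay of the laterally integrated fluence follows the effective
attenuation coefficient of diffusion theory, ``mu_eff = sqrt(3*mu_a*(mu_a +
mu_s_prime))``, which serves as the analytic cross-check for the walk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalProperties",
    "FluenceMap",
    "PHANTOM_OPTICAL_PROPERTIES",
    "diffusion_mu_eff",
    "run_mc",
    "penetration_depth",
    "sampling_depth_fraction",
]

#: Tissue-phantom optical properties per laser wavelength (mm^-1), from
#: published skin-mimicking phantom values: absorption and reduced scattering
#: both decrease from blue to near infrared, which is what makes longer
#: wavelengths probe deeper.
PHANTOM_OPTICAL_PROPERTIES: dict[int, "OpticalProperties"] = {}


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption / reduced-scattering pair for one wavelength.

    Coefficients are in mm^-1.  ``refractive_index`` is carried for
    completeness; the default boundary model is index-matched so it does not
    enter the walk.
    """

    wavelength_nm: float
    mu_a_per_mm: float
    mu_s_prime_per_mm: float
    refractive_index: float = 1.4

    def __post_init__(self) -> None:
        if self.mu_a_per_mm <= 0 or self.mu_s_prime_per_mm <= 0:
            raise ValueError("optical coefficients must be positive")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def mu_t_per_mm(self) -> float:
        """Total interaction coefficient of the isotropic-equivalent walk."""
        return self.mu_a_per_mm + self.mu_s_prime_per_mm

    @property
    def mu_eff_per_mm(self) -> float:
        return diffusion_mu_eff(self.mu_a_per_mm, self.mu_s_prime_per_mm)


for _wl, _mua, _musp in ((450, 0.015, 1.8), (515, 0.014, 1.7),
                         (658, 0.012, 1.1), (850, 0.010, 0.9)):
    PHANTOM_OPTICAL_PROPERTIES[_wl] = OpticalProperties(_wl, _mua, _musp)


def diffusion_mu_eff(mu_a: float, mu_s_prime: float) -> float:
    """Effective attenuation coefficient sqrt(3*mu_a*(mu_a+mu_s'))."""
    return math.sqrt(3.0 * mu_a * (mu_a + mu_s_prime))


@dataclass
class FluenceMap:
    """Cylindrical (depth x radius) fluence from one Monte Carlo run.

    ``grid[iz, ir]`` is fluence per unit incident power (mm^-2): absorbed
    weight in the ring voxel divided by ``mu_a`` and the ring volume.
    ``z_profile`` is the laterally integrated fluence-per-depth (absorbed
    weight per depth bin over all radii, divided by ``mu_a * voxel_mm``); it
    is the quantity whose decay defines penetration depth.

    The weight ledger is exact by construction: every launched unit of weight
    ends up in ``deposited_weight`` (all collisions, any radius/depth),
    ``escaped_weight`` (crossed the top surface), or the net Russian-roulette
    adjustment ``roulette_net`` (killed weight minus survivor boosts, zero in
    expectation).
    """

    grid: np.ndarray
    z_profile: np.ndarray
    voxel_mm: float
    n_photons: int
    seed: int
    props: OpticalProperties
    deposited_weight: float
    escaped_weight: float
    roulette_net: float
    escape_depth_hist: np.ndarray | None = field(default=None)
    truncated: bool = field(default=False)

    @property
    def z_centers_mm(self) -> np.ndarray:
        return (np.arange(self.z_profile.size) + 0.5) * self.voxel_mm

    @property
    def conservation_error(self) -> float:
        """Relative imbalance of the weight ledger (0 up to float rounding)."""
        total = self.deposited_weight + self.escaped_weight + self.roulette_net
        return abs(total - self.n_photons) / self.n_photons


def run_mc(
    props: OpticalProperties,
    slab_depth_mm: float = 20.0,
    lateral_mm: float = 10.0,
    voxel_mm: float = 0.05,
    n_photons: int = 100_000,
    seed: int = 0,
    roulette_threshold: float = 1e-4,
    roulette_survival: float = 0.1,
) -> FluenceMap:
    """Propagate ``n_photons`` from a surface point source into the slab.

    The source is a pencil beam entering at the origin along +z.  The medium
    is semi-infinite below z = 0 with an index-matched top surface: any
    photon whose step carries it above the surface escapes and its weight is
    banked.  At each collision a fraction ``mu_a/mu_t`` of the weight is
    deposited and the photon scatters isotropically.  Fixed seed gives a
    bit-identical map.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if slab_depth_mm <= 0 or lateral_mm <= 0 or voxel_mm <= 0:
        raise ValueError("geometry dimensions must be positive")
    if not 0 < roulette_survival < 1:
        raise ValueError("roulette_survival must be in (0, 1)")

    mu_a = props.mu_a_per_mm
    mu_t = props.mu_t_per_mm
    albedo = props.mu_s_prime_per_mm / mu_t

    nz = int(round(slab_depth_mm / voxel_mm))
    nr = int(round(lateral_mm / voxel_mm))
    dep_grid = np.zeros(nz * nr)
    dep_z = np.zeros(nz)

    rng = np.random.default_rng(seed)
    pos = np.zeros((n_photons, 3))
    direction = np.zeros((n_photons, 3))
    direction[:, 2] = 1.0
    w = np.ones(n_photons)
    z_deepest = np.zeros(n_photons)

    deposited = 0.0
    escaped = 0.0
    roulette_net = 0.0
    # escaped weight binned by the deepest point of the photon's path;
    # the trailing bin collects paths deeper than the grid
    esc_hist = np.zeros(nz + 1)

    while w.size:
        step = rng.exponential(1.0 / mu_t, size=w.size)
        pos = pos + direction * step[:, None]
        z_deepest = np.maximum(z_deepest, pos[:, 2])

        out = pos[:, 2] < 0.0
        if out.any():
            escaped += float(w[out].sum())
            iz_esc = np.minimum((z_deepest[out] / voxel_mm).astype(np.intp),
                                nz)
            np.add.at(esc_hist, iz_esc, w[out])
            keep = ~out
            pos, direction, w = pos[keep], direction[keep], w[keep]
            z_deepest = z_deepest[keep]
            if not w.size:
                break

        dep = w * (mu_a / mu_t)
        deposited += float(dep.sum())
        iz = (pos[:, 2] / voxel_mm).astype(np.intp)
        in_z = iz < nz
        if in_z.any():
            np.add.at(dep_z, iz[in_z], dep[in_z])
            r = np.hypot(pos[:, 0], pos[:, 1])
            ir = (r / voxel_mm).astype(np.intp)
            in_grid = in_z & (ir < nr)
            if in_grid.any():
                np.add.at(dep_grid, iz[in_grid] * nr + ir[in_grid],
                          dep[in_grid])
        w = w * albedo

        low = w < roulette_threshold
        if low.any():
            u = rng.random(low.sum())
            dies = u >= roulette_survival
            idx = np.flatnonzero(low)
            dead = idx[dies]
            roulette_net += float(w[dead].sum())
            boost = w[idx[~dies]]
            roulette_net -= float((boost / roulette_survival - boost).sum())
            w[idx[~dies]] /= roulette_survival
            keep = np.ones(w.size, dtype=bool)
            keep[dead] = False
            pos, direction, w = pos[keep], direction[keep], w[keep]
            z_deepest = z_deepest[keep]
            if not w.size:
                break

        # fresh isotropic direction for every surviving photon
        cos_t = 1.0 - 2.0 * rng.random(w.size)
        sin_t = np.sqrt(1.0 - cos_t**2)
        phi = 2.0 * np.pi * rng.random(w.size)
        direction = np.column_stack(
            (sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t))

    ring_r = np.arange(nr + 1) * voxel_mm
    ring_vol = np.pi * (ring_r[1:] ** 2 - ring_r[:-1] ** 2) * voxel_mm
    fluence = (dep_grid.reshape(nz, nr) / (mu_a * ring_vol[None, :])
               / n_photons)
    z_profile = dep_z / (mu_a * voxel_mm) / n_photons

    return FluenceMap(
        grid=fluence,
        z_profile=z_profile,
        voxel_mm=voxel_mm,
        n_photons=n_photons,
        seed=seed,
        props=props,
        deposited_weight=deposited,
        escaped_weight=escaped,
        roulette_net=roulette_net,
        escape_depth_hist=esc_hist,
    )


def sampling_depth_fraction(f: FluenceMap, depth_mm) -> np.ndarray:
    """Fraction of detected (back-escaped) weight that sampled below a depth.

    For each requested depth, returns the share of the escaped photon weight
    whose path reached at least that deep before leaving through the surface.
    This is the classic sampling-depth curve of diffuse reflectance: it is
    the fraction of a surface-detected signal that a moving scatterer at the
    given depth can modulate, and it decays with depth far faster than the
    fluence itself because most detected photons only graze the superficial
    layers.  Monotone non-increasing in depth by construction.
    """
    if f.escape_depth_hist is None or f.escaped_weight <= 0:
        raise ValueError("run carries no escape statistics")
    # reverse cumulative sum: weight with deepest point >= bin edge
    tail = np.cumsum(f.escape_depth_hist[::-1])[::-1] / f.escaped_weight
    edges = np.arange(tail.size) * f.voxel_mm
    return np.interp(np.asarray(depth_mm, dtype=float), edges, tail)


def penetration_depth(f: FluenceMap,
                      threshold_fraction: float = math.exp(-2.0)) -> float:
    """Depth at which the laterally integrated fluence decays to a fraction
    of its surface value, linearly interpolated between depth bins.

    If the profile never falls below the threshold inside the grid the grid
    depth is returned and ``f.truncated`` is set.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    prof = f.z_profile
    if prof[0] <= 0:
        raise ValueError("no fluence at the surface")
    z = f.z_centers_mm
    # extrapolate the first two bin centers back to z = 0 for the surface
    # value, so the threshold depth is not offset by half a voxel
    surface = prof[0] + (prof[0] - prof[1]) * z[0] / (z[1] - z[0]) \
        if prof.size > 1 else prof[0]
    rel = prof / max(surface, prof[0])
    below = np.flatnonzero(rel < threshold_fraction)
    if below.size == 0:
        f.truncated = True
        return float(z[-1])
    i = below[0]
    if i == 0:
        return float(z[0])
    # linear interpolation between the bracketing bin centers
    z0, z1 = z[i - 1], z[i]
    r0, r1 = rel[i - 1], rel[i]
    return float(z0 + (threshold_fraction - r0) * (z1 - z0) / (r1 - r0))
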