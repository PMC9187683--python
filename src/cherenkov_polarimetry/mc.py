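"""Simplified Monte Carlo of Cherenkov photon production in a water tank.

A condensed-history electron transport (tabulated collisional stopping
power, Highland Gaussian multiple scattering) emits Cherenkov photons along
the track according to the Frank–Tamm yield, on a cone at the instantaneous
Cherenkov angle around the instantaneous direction, with the polarization
vector in the particle–photon plane.  Photon beams interact once through
Compton scattering (exponential attenuation depth, Klein–Nishina electron
sampling) and hand the recoil electron to the electron transport.

The tank frame is: +z = depth (beam axis), +x = toward the camera,
+y = lateral (profile) direction; the beam enters at z = 0 on the tank
axis.  Tallied photon directions are summarized as polar (measured from
the beam axis) and azimuthal (measured from the camera axis, φ = 0 toward
the camera) histograms per scoring voxel.

This transport deliberately omits bremsstrahlung, pair production, delta
rays and optical photon propagation: it is a desk-scale generator of the
*angular distributions* of Cherenkov production, not a dose engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._tables import collisional_stopping_power, photon_attenuation_coefficient
from .physics import (
    ELECTRON_REST_MASS_KEV,
    ChargedParticleState,
    Medium,
    WATER,
    beta_from_kinetic_energy,
    cherenkov_photon_yield,
    cherenkov_threshold_energy,
)

__all__ = [
    "TANK_SIZE_CM",
    "EFFECTIVE_PHOTON_ENERGY_KEV",
    "BeamSpec",
    "CherenkovPhotonRecord",
    "PhotonTally",
    "ScoringRegion",
    "AngularDistribution",
    "transport_electron",
    "transport_photon_primary",
    "simulate_beam",
    "score_distributions",
]

#: (x, y, z) extent of the water tank in cm; z is depth.
TANK_SIZE_CM = (15.0, 15.0, 20.0)

#: Monoenergetic stand-ins for clinical photon spectra (~1/3 of the
#: accelerating potential, the conventional "effective energy").
EFFECTIVE_PHOTON_ENERGY_KEV = {"6MV": 2000.0, "18MV": 5000.0}


@dataclass(frozen=True)
class BeamSpec:
    """Incident beam description.

    ``energy_spectrum`` is either a single energy in keV or a list of
    (energy_kev, weight) pairs; weights are normalized internally.
    ``field_size`` is the (x, y) side length in cm of the uniform
    rectangular field at the surface.  A ``field_size`` of (0, 0) is a
    pencil beam on the tank axis.
    """

    particle: str  # "electron" | "photon"
    energy_spectrum: object
    field_size: tuple[float, float] = (0.0, 0.0)
    ssd: float = 100.0

    def __post_init__(self) -> None:
        if self.particle not in ("electron", "photon"):
            raise ValueError(f"unknown particle {self.particle!r}")

    @classmethod
    def preset(cls, name: str) -> "BeamSpec":
        """Clinical presets: '6MV', '18MV' photons; '6MeV', '18MeV' electrons."""
        name = name.strip()
        if name in EFFECTIVE_PHOTON_ENERGY_KEV:
            return cls("photon", EFFECTIVE_PHOTON_ENERGY_KEV[name],
                       field_size=(5.0, 5.0))
        if name.endswith("MeV"):
            return cls("electron", float(name[:-3]) * 1000.0,
                       field_size=(6.0, 6.0))
        raise ValueError(f"unknown beam preset {name!r}")

    def sample_energy(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if np.isscalar(self.energy_spectrum):
            return np.full(size, float(self.energy_spectrum))
        pairs = np.asarray(self.energy_spectrum, dtype=float)
        w = pairs[:, 1] / pairs[:, 1].sum()
        return rng.choice(pairs[:, 0], size=size, p=w)


@dataclass
class CherenkovPhotonRecord:
    """A single tallied Cherenkov photon (tank-frame cm / unit vectors)."""

    position: np.ndarray
    direction: np.ndarray
    polarization: np.ndarray
    generation_depth: float


class PhotonTally:
    """Column store of tallied Cherenkov photons.

    Vectorized container used throughout scoring; iterate to obtain
    individual :class:`CherenkovPhotonRecord` objects.
    """

    def __init__(self, positions, directions, polarizations):
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        self.directions = np.asarray(directions, dtype=float).reshape(-1, 3)
        self.polarizations = np.asarray(polarizations, dtype=float).reshape(-1, 3)

    @classmethod
    def empty(cls) -> "PhotonTally":
        z = np.zeros((0, 3))
        return cls(z, z, z)

    @classmethod
    def concatenate(cls, tallies) -> "PhotonTally":
        tallies = [t for t in tallies if len(t)]
        if not tallies:
            return cls.empty()
        return cls(
            np.concatenate([t.positions for t in tallies]),
            np.concatenate([t.directions for t in tallies]),
            np.concatenate([t.polarizations for t in tallies]),
        )

    @property
    def generation_depths(self) -> np.ndarray:
        return self.positions[:, 2]

    def __len__(self) -> int:
        return self.positions.shape[0]

    def __iter__(self):
        for i in range(len(self)):
            yield CherenkovPhotonRecord(
                position=self.positions[i],
                direction=self.directions[i],
                polarization=self.polarizations[i],
                generation_depth=self.positions[i, 2],
            )


@dataclass(frozen=True)
class ScoringRegion:
    """Cubic tally voxel centered at (x=0, y=off_axis, z=depth)."""

    depth: float
    off_axis: float = 0.0
    size: float = 1.0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("voxel size must be positive")


@dataclass
class AngularDistribution:
    """Polar/azimuthal histograms of Cherenkov photon directions in a voxel.

    Polar angle is measured from the beam axis (+z), binned on [0°, 180°];
    azimuth from the camera axis (+x) in the transverse plane, binned on
    (−180°, 180°].  Both histograms sum to ``n_photons``.
    """

    region: ScoringRegion
    polar_edges: np.ndarray
    polar_hist: np.ndarray
    azimuth_edges: np.ndarray
    azimuth_hist: np.ndarray
    n_photons: int
    empty: bool = False

    def polar_density(self, theta_deg) -> np.ndarray:
        """Normalized polar density (per degree) by bin-center interpolation."""
        return _hist_density(theta_deg, self.polar_edges, self.polar_hist)

    def azimuth_density(self, phi_deg) -> np.ndarray:
        """Normalized azimuthal density (per degree), periodic in 360°."""
        phi = (np.asarray(phi_deg, dtype=float) + 180.0) % 360.0 - 180.0
        return _hist_density(phi, self.azimuth_edges, self.azimuth_hist)


def _hist_density(x, edges, hist):
    widths = np.diff(edges)
    total = hist.sum()
    if total == 0:
        return np.zeros_like(np.asarray(x, dtype=float))
    density = hist / (total * widths)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return np.interp(np.asarray(x, dtype=float), centers, density)


def _inside_tank(position: np.ndarray) -> bool:
    hx, hy = TANK_SIZE_CM[0] / 2.0, TANK_SIZE_CM[1] / 2.0
    x, y, z = position
    return (-hx <= x <= hx) and (-hy <= y <= hy) and (0.0 <= z <= TANK_SIZE_CM[2])


def _orthonormal_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # any two unit vectors completing d to a right-handed frame
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def _deflect(d: np.ndarray, polar: float, azimuth: float) -> np.ndarray:
    e1, e2 = _orthonormal_basis(d)
    out = (math.cos(polar) * d
           + math.sin(polar) * (math.cos(azimuth) * e1 + math.sin(azimuth) * e2))
    return out / np.linalg.norm(out)


def _highland_sigma(energy_kev: float, m0c2: float, step_cm: float,
                    radiation_length_cm: float) -> float:
    """RMS projected multiple-scattering angle (radians) for one step."""
    e_tot = energy_kev + m0c2
    p_mev = math.sqrt(e_tot**2 - m0c2**2) / 1000.0
    beta = beta_from_kinetic_energy(energy_kev, m0c2)
    t = step_cm / radiation_length_cm
    return 13.6 / (beta * p_mev) * math.sqrt(t) * (1.0 + 0.038 * math.log(t))


def transport_electron(
    state: ChargedParticleState,
    medium: Medium = WATER,
    rng: np.random.Generator | int | None = None,
    *,
    step_cm: float = 0.1,
    scattering: bool = True,
    lambda_band_nm: tuple[float, float] = (400.0, 800.0),
) -> PhotonTally:
    """Condensed-history electron transport tallying Cherenkov photons.

    Per step of length ``step_cm``: energy is deducted from the tabulated
    collisional stopping power, the direction is deflected by a Gaussian
    multiple-scattering angle (Highland formula, disabled with
    ``scattering=False``), and a Poisson number of Cherenkov photons is
    emitted on the instantaneous cone with uniform cone azimuth.  Transport
    terminates below the Cherenkov threshold or when the electron leaves
    the tank.
    """
    rng = np.random.default_rng(rng)
    n = medium.refractive_index
    threshold = cherenkov_threshold_energy(n, state.m0c2)
    energy = float(state.kinetic_energy)
    direction = np.array(state.direction, dtype=float)
    position = np.array(state.position, dtype=float)
    if not _inside_tank(position):
        raise ValueError(f"initial position {position} is outside the tank")

    pos_out: list[np.ndarray] = []
    dir_out: list[np.ndarray] = []
    pol_out: list[np.ndarray] = []

    while energy > threshold and _inside_tank(position):
        beta = beta_from_kinetic_energy(energy, state.m0c2)
        cos_c = 1.0 / (beta * n)
        sin_c = math.sqrt(max(0.0, 1.0 - cos_c**2))
        mean_yield = cherenkov_photon_yield(
            beta, n, lambda_band_nm[0], lambda_band_nm[1], step_cm)
        n_emit = rng.poisson(mean_yield)
        midpoint = position + 0.5 * step_cm * direction
        if n_emit > 0 and _inside_tank(midpoint):
            psi = rng.uniform(0.0, 2.0 * math.pi, size=n_emit)
            e1, e2 = _orthonormal_basis(direction)
            photon_dirs = (cos_c * direction[None, :]
                           + sin_c * (np.cos(psi)[:, None] * e1[None, :]
                                      + np.sin(psi)[:, None] * e2[None, :]))
            # polarization: normalized (u.k)k - u, in the u-k plane, outward
            udotk = photon_dirs @ direction
            pol = udotk[:, None] * photon_dirs - direction[None, :]
            pol /= np.linalg.norm(pol, axis=1, keepdims=True)
            pos_out.append(np.broadcast_to(midpoint, (n_emit, 3)).copy())
            dir_out.append(photon_dirs)
            pol_out.append(pol)

        position = position + step_cm * direction
        energy -= float(collisional_stopping_power(energy, medium.density)) * step_cm
        if scattering and energy > 0:
            sigma = _highland_sigma(energy, state.m0c2, step_cm,
                                    medium.radiation_length_cm)
            gx, gy = rng.normal(0.0, sigma, size=2)
            space_angle = math.hypot(gx, gy)
            direction = _deflect(direction, space_angle,
                                 rng.uniform(0.0, 2.0 * math.pi))

    if not pos_out:
        return PhotonTally.empty()
    return PhotonTally(np.concatenate(pos_out), np.concatenate(dir_out),
                       np.concatenate(pol_out))


def _sample_klein_nishina(energy_kev: float, rng: np.random.Generator
                          ) -> tuple[float, float]:
    """Sample a Compton interaction; returns (electron_kev, photon_polar_rad).

    Rejection sampling of the scattered-photon energy fraction ε = E'/E from
    the Klein–Nishina differential cross-section.
    """
    k = energy_kev / ELECTRON_REST_MASS_KEV
    eps_min = 1.0 / (1.0 + 2.0 * k)
    # envelope: f(eps) <= 1/eps_min + 1
    f_max = 1.0 / eps_min + 1.0
    while True:
        eps = rng.uniform(eps_min, 1.0)
        cos_t = 1.0 + 1.0 / k - 1.0 / (k * eps)
        cos_t = min(1.0, max(-1.0, cos_t))
        sin2 = 1.0 - cos_t**2
        f = (1.0 / eps + eps) * (1.0 - eps * sin2 / (1.0 + eps**2))
        if rng.uniform(0.0, f_max) <= f:
            break
    electron_kev = energy_kev * (1.0 - eps)
    theta_gamma = math.acos(cos_t)
    return electron_kev, theta_gamma


def transport_photon_primary(
    energy_kev: float,
    medium: Medium = WATER,
    rng: np.random.Generator | int | None = None,
    *,
    entry_point: np.ndarray | None = None,
    follow_scattered: bool = False,
    step_cm: float = 0.1,
    scattering: bool = True,
) -> PhotonTally:
    """Transport one primary beam photon and tally Cherenkov light.

    Samples the interaction depth from exponential attenuation with the
    tabulated μ(E) of water, produces a Compton recoil electron from
    Klein–Nishina kinematics, and hands it to :func:`transport_electron`.
    The scattered photon is discarded by default (single-scatter
    approximation) or followed recursively with ``follow_scattered=True``.
    """
    if energy_kev <= 0:
        raise ValueError("photon energy must be positive")
    rng = np.random.default_rng(rng)
    position = np.zeros(3) if entry_point is None else np.array(entry_point, dtype=float)
    direction = np.array([0.0, 0.0, 1.0])
    return _transport_photon(energy_kev, position, direction, medium, rng,
                             follow_scattered, step_cm, scattering)


def _transport_photon(energy_kev, position, direction, medium, rng,
                      follow_scattered, step_cm, scattering) -> PhotonTally:
    mu = float(photon_attenuation_coefficient(energy_kev, medium.density))
    path = rng.exponential(1.0 / mu)
    interaction = position + path * direction
    if not _inside_tank(interaction):
        return PhotonTally.empty()

    electron_kev, theta_gamma = _sample_klein_nishina(energy_kev, rng)
    k = energy_kev / ELECTRON_REST_MASS_KEV
    # electron polar angle from Compton kinematics: cot(theta_e) = (1+k) tan(theta_gamma/2)
    half = theta_gamma / 2.0
    theta_e = math.pi / 2.0 if half == 0 else math.atan(1.0 / ((1.0 + k) * math.tan(half)))
    psi = rng.uniform(0.0, 2.0 * math.pi)
    electron_dir = _deflect(direction, theta_e, psi)

    tallies = []
    if electron_kev > 1.0:
        state = ChargedParticleState(kinetic_energy=electron_kev,
                                     direction=electron_dir,
                                     position=interaction)
        tallies.append(transport_electron(state, medium, rng, step_cm=step_cm,
                                          scattering=scattering))
    if follow_scattered:
        scattered_kev = energy_kev - electron_kev
        if scattered_kev > 100.0:
            scattered_dir = _deflect(direction, theta_gamma, psi + math.pi)
            tallies.append(_transport_photon(scattered_kev, interaction,
                                             scattered_dir, medium, rng,
                                             follow_scattered, step_cm,
                                             scattering))
    return PhotonTally.concatenate(tallies)


def simulate_beam(
    beam: BeamSpec,
    n_primaries: int,
    seed: int | np.random.Generator | None = None,
    medium: Medium = WATER,
    *,
    step_cm: float = 0.1,
    scattering: bool = True,
    follow_scattered: bool = False,
) -> PhotonTally:
    """Run ``n_primaries`` beam particles and pool their Cherenkov photons.

    Primaries start at the tank surface (z = 0), directed along +z, with
    entry points uniform over the beam's surface field.
    """
    rng = np.random.default_rng(seed)
    energies = beam.sample_energy(rng, n_primaries)
    wx, wy = beam.field_size
    xs = rng.uniform(-wx / 2.0, wx / 2.0, size=n_primaries) if wx > 0 else np.zeros(n_primaries)
    ys = rng.uniform(-wy / 2.0, wy / 2.0, size=n_primaries) if wy > 0 else np.zeros(n_primaries)

    tallies = []
    for i in range(n_primaries):
        entry = np.array([xs[i], ys[i], 0.0])
        if beam.particle == "electron":
            state = ChargedParticleState(kinetic_energy=float(energies[i]),
                                         position=entry)
            tallies.append(transport_electron(state, medium, rng,
                                              step_cm=step_cm,
                                              scattering=scattering))
        else:
            tallies.append(transport_photon_primary(
                float(energies[i]), medium, rng, entry_point=entry,
                follow_scattered=follow_scattered, step_cm=step_cm,
                scattering=scattering))
    return PhotonTally.concatenate(tallies)


def score_distributions(
    photons: PhotonTally,
    regions,
    camera_side_filter: bool = True,
    *,
    polar_bin_deg: float = 1.0,
    azimuth_bin_deg: float = 5.0,
) -> list[AngularDistribution]:
    """Bin photon directions into per-region polar/azimuthal histograms.

    Polar angle is measured from the beam axis; azimuth from the camera
    axis with φ = 0 toward the camera.  With ``camera_side_filter`` only
    photons whose direction has a positive component toward the camera are
    scored, emulating the one-sided collection efficiency of the imaging
    system.  Empty regions yield zero histograms flagged ``empty``.
    """
    regions = [r if isinstance(r, ScoringRegion) else ScoringRegion(*r)
               for r in regions]
    pos = photons.positions
    dirs = photons.directions
    if camera_side_filter and len(photons):
        keep = dirs[:, 0] > 0.0
        pos, dirs = pos[keep], dirs[keep]

    theta = np.degrees(np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))) if len(dirs) else np.empty(0)
    phi = np.degrees(np.arctan2(dirs[:, 1], dirs[:, 0])) if len(dirs) else np.empty(0)

    polar_edges = np.arange(0.0, 180.0 + polar_bin_deg, polar_bin_deg)
    az_edges = np.arange(-180.0, 180.0 + azimuth_bin_deg, azimuth_bin_deg)

    out = []
    for region in regions:
        half = region.size / 2.0
        sel = (
            (np.abs(pos[:, 0]) <= half)
            & (np.abs(pos[:, 1] - region.off_axis) <= half)
            & (np.abs(pos[:, 2] - region.depth) <= half)
        ) if len(pos) else np.zeros(0, dtype=bool)
        th, ph = theta[sel], phi[sel]
        polar_hist, _ = np.histogram(th, bins=polar_edges)
        az_hist, _ = np.histogram(ph, bins=az_edges)
        out.append(AngularDistribution(
            region=region,
            polar_edges=polar_edges,
            polar_hist=polar_hist,
            azimuth_edges=az_edges,
            azimuth_hist=az_hist,
            n_photons=int(sel.sum()),
            empty=not bool(sel.any()),
        ))
    return out
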