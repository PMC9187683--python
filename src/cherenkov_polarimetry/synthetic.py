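"""Forward simulator of polarized Cherenkov imaging measurements.

Generates four-angle polarizer frame stacks (plus background and flat
frames) from a known ground truth: a parametric projected dose model
(photon build-up + exponential attenuation, or electron plateau + sigmoid
falloff), per-pixel DoLP/AoLP fields, and an angular emission weighting
that is exactly the reciprocal of the correction maps the analysis will
compute from the same angular distributions.  Running the full analysis
chain on a rendered scenario therefore recovers the ground truth up to the
injected noise, which is the property the test-suite exercises.

Beam presets carry the characteristic megavoltage values: central-region
DoLP of 42/47/29/33 % for 6 MeV/18 MeV/6 MV/18 MV, AoLP near 0° on the
beam axis rising in the penumbra, photon d_max at 1.2 cm (6 MV) and
3.05 cm (18 MV), a 5×5 cm² photon / 6×6 cm² electron field, cos⁴
vignetting, additive background, Poisson + Gaussian read noise, and rare
transient spikes emulating stray-radiation hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .correction import CameraGeometry, ProjectedDoseImage, build_correction_maps
from .image_prep import VignetteModel
from .mc import AngularDistribution, ScoringRegion
from .polarimetry import PolarizedStack, malus_intensity

__all__ = [
    "Scenario",
    "RenderedMeasurement",
    "generate_ground_truth",
    "render_stack",
    "analytic_distributions",
]

#: Central-region DoLP (percent) per beam preset; "unpolarized" emulates a
#: pure-scintillation source.
DOLP_PRESETS = {"6MeV": 42.0, "18MeV": 47.0, "6MV": 29.0, "18MV": 33.0,
                "unpolarized": 0.0}

_PHOTON_DMAX = {"6MV": 1.2, "18MV": 3.05}
_PHOTON_MU = {"6MV": 0.055, "18MV": 0.038}  # 1/cm effective falloff
_ELECTRON_R50 = {"6MeV": 2.4, "18MeV": 7.5}
_ELECTRON_FALLOFF_W = {"6MeV": 0.22, "18MeV": 0.65}
_ELECTRON_SLOPE = {"6MeV": 0.10, "18MeV": 0.03}  # mild build-up of the plateau


@dataclass(frozen=True)
class Scenario:
    """Everything needed to render one synthetic measurement.

    ``aolp_penumbra_deg`` is the AoLP magnitude reached at the outer edge
    of the penumbra (0° on the beam axis, linear ramp in between,
    antisymmetric in the lateral coordinate).
    """

    beam: str = "6MeV"
    dolp_percent: float | None = None  # None -> preset value
    aolp_penumbra_deg: float = 35.0
    field_width: float | None = None  # cm; None -> preset
    penumbra_sigma: float = 0.3  # cm
    image_shape: tuple[int, int] = (150, 110)
    pixel_scale: float = 1.3  # mm/px (a binned sensor keeps tests light)
    camera_distance: float = 50.0
    peak_total_counts: float = 3.0e4
    background_counts: float = 50.0
    read_noise: float = 5.0
    spike_rate: float = 10.0  # expected spikes per frame
    spike_amplitude: float = 2.0e4
    vignette_f: float | None = 400.0  # px; None disables vignetting
    n_frames: int = 10
    n_background_frames: int = 10
    noise: bool = True
    exposure: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beam not in DOLP_PRESETS and self.beam != "custom":
            raise ValueError(f"unknown beam preset {self.beam!r}")

    @property
    def beam_kind(self) -> str:
        if self.beam in ("6MV", "18MV"):
            return "photon"
        return "electron"  # electron presets and the unpolarized stand-in

    @property
    def dolp(self) -> float:
        if self.dolp_percent is not None:
            return self.dolp_percent
        return DOLP_PRESETS[self.beam]

    @property
    def field_size(self) -> float:
        if self.field_width is not None:
            return self.field_width
        return 5.0 if self.beam_kind == "photon" else 6.0

    def geometry(self) -> CameraGeometry:
        return CameraGeometry(distance=self.camera_distance,
                              pixel_scale=self.pixel_scale,
                              image_shape=self.image_shape)

    def vignette(self) -> VignetteModel | None:
        if self.vignette_f is None:
            return None
        center = ((self.image_shape[0] - 1) / 2.0,
                  (self.image_shape[1] - 1) / 2.0)
        return VignetteModel(center=center, f=self.vignette_f, amplitude=1.0)

    def distributions(self) -> list[AngularDistribution]:
        depth_max = self.geometry().depth_axis()[-1]
        if self.beam_kind == "photon":
            depths = [self.geometry().tank_size[2] / 2.0]
        else:
            depths = list(np.arange(0.5, depth_max + 1.0, 1.0))
        half_lat = self.geometry().lateral_axis()[-1]
        off_axes = list(np.linspace(-half_lat, half_lat, 7))
        return analytic_distributions(self.beam_kind, depths, off_axes)


@dataclass
class RenderedMeasurement:
    """Output of :func:`render_stack`: frames plus the generating truth."""

    frames: dict[float, list[np.ndarray]]  # polarizer angle -> frame list
    background_frames: list[np.ndarray]
    flat_frame: np.ndarray
    truth_dose: ProjectedDoseImage
    truth_dolp: np.ndarray
    truth_aolp: np.ndarray
    truth_i_pol: np.ndarray
    distributions: list[AngularDistribution]
    geometry: CameraGeometry
    scenario: Scenario

    def stack(self, reduce: str = "median") -> PolarizedStack:
        """Collapse the frame lists into a PolarizedStack (median or first)."""
        if reduce == "median":
            frames = {a: np.median(np.stack(fs), axis=0)
                      for a, fs in self.frames.items()}
        else:
            frames = {a: fs[0] for a, fs in self.frames.items()}
        return PolarizedStack(frames=frames,
                              pixel_scale=self.geometry.pixel_scale,
                              exposure=self.scenario.exposure)


def _photon_depth_dose(z: np.ndarray, d_max: float, mu: float) -> np.ndarray:
    """Build-up times exponential attenuation with the stated d_max."""

    def dmax_of_b(b):
        # stationary point of (1 - exp(-b z)) exp(-mu z)
        return math.log((b + mu) / mu) / b

    b = brentq(lambda b: dmax_of_b(b) - d_max, 1e-3, 1e3)
    curve = (1.0 - np.exp(-b * np.clip(z, 0.0, None))) * np.exp(-mu * z)
    return np.clip(curve, 0.0, None)


def _electron_depth_dose(z: np.ndarray, r50: float, w: float, slope: float
                         ) -> np.ndarray:
    curve = (1.0 + slope * np.clip(z, 0.0, None)) / (1.0 + np.exp((z - r50) / w))
    return np.clip(curve, 0.0, None)


def _lateral_profile(x: np.ndarray, width: float, sigma: float) -> np.ndarray:
    from scipy.special import erf
    half = width / 2.0
    s = sigma * math.sqrt(2.0)
    return 0.5 * (erf((x + half) / s) - erf((x - half) / s))


def generate_ground_truth(scenario: Scenario
                          ) -> tuple[ProjectedDoseImage, np.ndarray, np.ndarray]:
    """Ground-truth projected dose, DoLP field and AoLP field for a scenario.

    Deterministic: the truth is purely parametric (the seed only affects
    rendering noise).
    """
    geom = scenario.geometry()
    z = geom.depth_axis()
    x = geom.lateral_axis()

    if scenario.beam in _PHOTON_DMAX:
        depth_curve = _photon_depth_dose(z, _PHOTON_DMAX[scenario.beam],
                                         _PHOTON_MU[scenario.beam])
    elif scenario.beam in _ELECTRON_R50:
        depth_curve = _electron_depth_dose(z, _ELECTRON_R50[scenario.beam],
                                           _ELECTRON_FALLOFF_W[scenario.beam],
                                           _ELECTRON_SLOPE[scenario.beam])
    else:  # unpolarized / custom: a broad featureless blob
        depth_curve = _electron_depth_dose(z, 3.0, 0.4, 0.0)

    profile = _lateral_profile(x, scenario.field_size, scenario.penumbra_sigma)
    dose = np.outer(depth_curve, profile)
    dose /= dose.max()
    truth = ProjectedDoseImage(dose=dose, depth_axis=z, lateral_axis=x,
                               pixel_scale=geom.pixel_scale)

    dolp = np.full(geom.image_shape, scenario.dolp)

    # AoLP: 0 on-axis, linear ramp across the penumbra (between the 80% and
    # 20% profile levels), capped at the penumbra value, antisymmetric in x.
    half = scenario.field_size / 2.0
    r80 = half - 0.84 * scenario.penumbra_sigma
    r20 = half + 0.84 * scenario.penumbra_sigma
    u = np.clip((np.abs(x) - r80) / (r20 - r80), 0.0, 1.0)
    aolp_cols = scenario.aolp_penumbra_deg * u * np.sign(x)
    aolp = np.broadcast_to(aolp_cols, geom.image_shape).copy()
    return truth, dolp, aolp


def analytic_distributions(beam_kind: str, depths, off_axes=(0.0,),
                           polar_bin_deg: float = 1.0,
                           azimuth_bin_deg: float = 5.0,
                           ) -> list[AngularDistribution]:
    """Synthetic stand-in angular distributions (no Monte Carlo run).

    Emulates the qualitative behaviour of scored Cherenkov distributions:
    a polar density peaked near the 41° cone angle that broadens with
    depth for electron beams (multiple scattering randomizes the electron
    directions) but is depth-independent for photon beams past build-up,
    and an azimuthal density that tilts mildly with off-axis position.
    These are synthetic stand-ins for scored tallies; real distributions
    come from :mod:`cherenkov_polarimetry.mc`.
    """
    polar_edges = np.arange(0.0, 180.0 + polar_bin_deg, polar_bin_deg)
    az_edges = np.arange(-180.0, 180.0 + azimuth_bin_deg, azimuth_bin_deg)
    pc = 0.5 * (polar_edges[:-1] + polar_edges[1:])
    ac = 0.5 * (az_edges[:-1] + az_edges[1:])
    total = 10_000_000

    dists = []
    for depth in depths:
        if beam_kind == "photon":
            sigma = 28.0
        else:
            sigma = min(14.0 + 10.0 * depth, 60.0)
        polar = np.exp(-0.5 * ((pc - 41.0) / sigma) ** 2) + 1e-3
        polar_hist = np.round(total * polar / polar.sum()).astype(int)
        az_hist = _azimuth_hist(ac, 0.0, total)
        dists.append(AngularDistribution(
            region=ScoringRegion(depth=float(depth), off_axis=0.0),
            polar_edges=polar_edges, polar_hist=polar_hist,
            azimuth_edges=az_edges, azimuth_hist=az_hist,
            n_photons=int(polar_hist.sum())))
    mid_depth = float(np.median(np.asarray(depths)))
    for off in off_axes:
        if abs(off) < 1e-9:
            continue
        if beam_kind == "photon":
            sigma = 28.0
        else:
            sigma = min(14.0 + 10.0 * mid_depth, 60.0)
        polar = np.exp(-0.5 * ((pc - 41.0) / sigma) ** 2) + 1e-3
        polar_hist = np.round(total * polar / polar.sum()).astype(int)
        az_hist = _azimuth_hist(ac, 3.0 * off, total)
        dists.append(AngularDistribution(
            region=ScoringRegion(depth=mid_depth, off_axis=float(off)),
            polar_edges=polar_edges, polar_hist=polar_hist,
            azimuth_edges=az_edges, azimuth_hist=az_hist,
            n_photons=int(polar_hist.sum())))
    return dists


def _azimuth_hist(centers: np.ndarray, phi0: float, total: int) -> np.ndarray:
    dens = np.exp(-0.5 * (((centers - phi0 + 180.0) % 360.0 - 180.0) / 80.0) ** 2) + 1e-3
    return np.round(total * dens / dens.sum()).astype(int)


def render_stack(truth=None, scenario: Scenario | None = None,
                 distributions: list[AngularDistribution] | None = None,
                 ) -> RenderedMeasurement:
    """Render polarizer frame stacks (plus background/flat) from a truth.

    Per pixel: the polarized amplitude is the ground-truth dose divided by
    the correction maps that :func:`build_correction_maps` derives from the
    scenario's angular distributions (so correcting undoes the weighting
    exactly); the unpolarized term follows from the DoLP field; frames at
    each polarizer angle follow the Malus model, then vignetting,
    background, Poisson/read noise and transient spikes are applied.
    """
    if scenario is None:
        scenario = Scenario()
    if truth is None:
        truth = generate_ground_truth(scenario)
    truth_dose, dolp, aolp = truth
    geom = scenario.geometry()
    rng = np.random.default_rng(scenario.seed)

    if distributions is None:
        distributions = scenario.distributions()
    maps = build_correction_maps(distributions, geom, scenario.beam_kind)
    weight = 1.0 / (maps.c_theta * maps.c_phi)

    signal = truth_dose.dose * weight  # unscaled polarized-signal shape
    polarized = dolp > 0
    # scale so that the peak *total* intensity hits the requested counts
    dolp_frac = np.clip(dolp, 1e-6, 100.0) / 100.0
    itot_unscaled = np.where(polarized, signal / dolp_frac, signal)
    scale = scenario.peak_total_counts / itot_unscaled.max()
    i_pol = np.where(polarized, scale * signal, 0.0)
    i_unpol = np.where(polarized, i_pol * (100.0 - dolp) / np.where(polarized, dolp, 1.0),
                       scale * signal)

    vignette = scenario.vignette()
    falloff = (vignette.evaluate(geom.image_shape) / vignette.amplitude
               if vignette is not None else 1.0)

    frames: dict[float, list[np.ndarray]] = {}
    for alpha0 in (0.0, 45.0, 90.0, 135.0):
        clean = malus_intensity(i_pol, i_unpol, alpha0, aolp)
        clean = clean * falloff + scenario.background_counts
        frames[alpha0] = [_apply_noise(clean, scenario, rng)
                          for _ in range(scenario.n_frames)]

    bg_clean = np.full(geom.image_shape, scenario.background_counts)
    background = [_apply_noise(bg_clean, scenario, rng, spikes=False)
                  for _ in range(scenario.n_background_frames)]

    flat_clean = 2.0e4 * np.asarray(falloff) * np.ones(geom.image_shape)
    flat = _apply_noise(flat_clean, scenario, rng, spikes=False)

    return RenderedMeasurement(
        frames=frames, background_frames=background, flat_frame=flat,
        truth_dose=truth_dose, truth_dolp=dolp, truth_aolp=aolp,
        truth_i_pol=i_pol, distributions=distributions, geometry=geom,
        scenario=scenario)


def _apply_noise(clean: np.ndarray, scenario: Scenario,
                 rng: np.random.Generator, spikes: bool = True) -> np.ndarray:
    if not scenario.noise:
        return clean.copy()
    img = rng.poisson(np.clip(clean, 0.0, None)).astype(float)
    if scenario.read_noise > 0:
        img += rng.normal(0.0, scenario.read_noise, size=img.shape)
    if spikes and scenario.spike_rate > 0:
        n = rng.poisson(scenario.spike_rate)
        if n:
            ii = rng.integers(0, img.shape[0], size=n)
            jj = rng.integers(0, img.shape[1], size=n)
            img[ii, jj] += rng.uniform(0.5, 1.5, size=n) * scenario.spike_amplitude
    return np.clip(img, 0.0, None)
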