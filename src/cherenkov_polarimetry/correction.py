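"""Anisotropy correction of the polarized Cherenkov image.

Each image pixel views its tank mid-plane voxel from a slightly different
direction.  Mapping pixels to viewing angles (polar θ_cam relative to the
beam axis, azimuth φ_cam relative to the camera axis) and dividing by the
normalized Cherenkov angular densities evaluated at those angles removes
the geometric signal dependence:

    D(x, y) ∝ C_θ(x, y) · C_φ(x, y) · I_pol(x, y)

with C = ⟨P⟩ / P, normalized so the correction averages to one over the
field — only proportionality to dose is claimed, and this convention keeps
corrected and raw images directly comparable.

Photon beams in electronic equilibrium share one depth distribution; for
electron beams the polar density varies with depth and is linearly
interpolated between scored depths.  The azimuthal correction interpolates
between scored off-axis positions.  Parallax along the optical axis is
neglected (each pixel is assigned its mid-plane angles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mc import AngularDistribution

__all__ = [
    "CameraGeometry",
    "CorrectionMaps",
    "ProjectedDoseImage",
    "pixel_to_viewing_angles",
    "build_correction_maps",
    "apply_correction",
]

#: Cap applied where a sampled angular density vanishes; such pixels are
#: flagged rather than blown up.
MAX_CORRECTION = 100.0


@dataclass(frozen=True)
class CameraGeometry:
    """Side-viewing camera imaging the tank mid-plane.

    The optical axis hits the tank center; image rows map to depth and
    columns to the lateral direction through ``pixel_scale``.  ``distance``
    is lens-to-mid-plane in cm.
    """

    distance: float = 50.0
    tank_size: tuple[float, float, float] = (15.0, 15.0, 20.0)
    pixel_scale: float = 0.26  # mm per pixel
    image_shape: tuple[int, int] = (200, 150)
    axis_target_pixel: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.distance <= self.tank_size[0] / 2.0:
            raise ValueError("camera distance must exceed the tank half-thickness")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")

    @property
    def target(self) -> tuple[float, float]:
        if self.axis_target_pixel is not None:
            return self.axis_target_pixel
        return ((self.image_shape[0] - 1) / 2.0, (self.image_shape[1] - 1) / 2.0)

    def pixel_to_tank(self, i, j):
        """Pixel indices → (depth, lateral) cm in the tank mid-plane."""
        ti, tj = self.target
        depth_center = self.tank_size[2] / 2.0
        scale_cm = self.pixel_scale / 10.0
        depth = depth_center + (np.asarray(i, dtype=float) - ti) * scale_cm
        lateral = (np.asarray(j, dtype=float) - tj) * scale_cm
        return depth, lateral

    def depth_axis(self) -> np.ndarray:
        """Depth (cm) of each image row."""
        return self.pixel_to_tank(np.arange(self.image_shape[0]), 0)[0]

    def lateral_axis(self) -> np.ndarray:
        """Lateral position (cm) of each image column."""
        return self.pixel_to_tank(0, np.arange(self.image_shape[1]))[1]


@dataclass
class CorrectionMaps:
    """Per-pixel polar and azimuthal correction factors (mean ≈ 1)."""

    c_theta: np.ndarray
    c_phi: np.ndarray
    normalization: str = "field-mean-one"
    qa_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.qa_mask is None:
            self.qa_mask = np.zeros(self.c_theta.shape, dtype=bool)
        for name, arr in (("c_theta", self.c_theta), ("c_phi", self.c_phi)):
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"{name} must be finite and positive everywhere")


@dataclass
class ProjectedDoseImage:
    """Dose-proportional image summed along the optical axis.

    Rows run with depth, columns with the lateral direction; ``depth_axis``
    and ``lateral_axis`` give physical coordinates in cm.
    """

    dose: np.ndarray
    depth_axis: np.ndarray
    lateral_axis: np.ndarray
    pixel_scale: float = 0.26

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.depth_axis = np.asarray(self.depth_axis, dtype=float)
        self.lateral_axis = np.asarray(self.lateral_axis, dtype=float)
        if self.dose.shape != (self.depth_axis.size, self.lateral_axis.size):
            raise ValueError("dose shape does not match axes")
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative")


def pixel_to_viewing_angles(i, j, geometry: CameraGeometry):
    """Viewing angles (θ_cam, φ_cam) in degrees for pixel (i, j).

    θ_cam = 90° + arctan((depth − depth_center)/L) — the polar angle,
    relative to the beam axis, of the ray from the voxel to the camera;
    φ_cam = arctan(lateral/L), with φ = 0 toward the camera.  For a 50 cm
    camera and depths 0–17 cm in a 20 cm tank this spans roughly 79°–98°.
    Pixels whose mid-plane point falls outside the tank map to NaN.
    """
    depth, lateral = geometry.pixel_to_tank(i, j)
    depth_center = geometry.tank_size[2] / 2.0
    theta = 90.0 + np.degrees(np.arctan((depth - depth_center) / geometry.distance))
    phi = np.degrees(np.arctan(lateral / geometry.distance))
    outside = (depth < 0) | (depth > geometry.tank_size[2]) \
        | (np.abs(lateral) > geometry.tank_size[1] / 2.0)
    theta = np.where(outside, np.nan, theta)
    phi = np.where(outside, np.nan, phi)
    return theta, phi


def _interp_weights(value: float, knots: np.ndarray) -> list[tuple[int, float]]:
    """Linear interpolation weights over sorted knots, clamped at the ends."""
    if value <= knots[0]:
        return [(0, 1.0)]
    if value >= knots[-1]:
        return [(len(knots) - 1, 1.0)]
    hi = int(np.searchsorted(knots, value))
    lo = hi - 1
    w = (value - knots[lo]) / (knots[hi] - knots[lo])
    return [(lo, 1.0 - w), (hi, w)]


def build_correction_maps(
    dists: list[AngularDistribution],
    geometry: CameraGeometry,
    beam_kind: str,
) -> CorrectionMaps:
    """Build per-pixel C_θ and C_φ maps from scored angular distributions.

    Photon beams use the single central-axis distribution for the polar
    correction at all depths (their post-buildup distributions are mutually
    consistent); electron beams interpolate the polar density linearly
    between scored depths.  The azimuthal correction interpolates between
    scored off-axis positions for both beam kinds.  Corrections are
    normalized to average 1 over the (unmasked) field; pixels hitting a
    vanishing density are capped and flagged.
    """
    if beam_kind not in ("electron", "photon"):
        raise ValueError(f"unknown beam kind {beam_kind!r}")
    if not dists:
        raise ValueError("need at least one angular distribution")

    shape = geometry.image_shape
    ii, jj = np.indices(shape)
    theta, phi = pixel_to_viewing_angles(ii, jj, geometry)
    depth, lateral = geometry.pixel_to_tank(ii, jj)

    on_axis = sorted((d for d in dists if abs(d.region.off_axis) < 1e-9),
                     key=lambda d: d.region.depth)
    if not on_axis:
        on_axis = sorted(dists, key=lambda d: d.region.depth)

    # -- polar density per pixel --
    if beam_kind == "photon" or len(on_axis) == 1:
        center_depth = geometry.tank_size[2] / 2.0
        central = min(on_axis, key=lambda d: abs(d.region.depth - center_depth))
        p_theta = central.polar_density(theta)
    else:
        depths = np.array([d.region.depth for d in on_axis])
        p_theta = np.zeros(shape)
        rows = np.arange(shape[0])
        row_theta = theta[:, 0]
        row_depth = depth[:, 0]
        for r in rows:
            acc = 0.0
            for idx, w in _interp_weights(row_depth[r], depths):
                acc += w * on_axis[idx].polar_density(row_theta[r])
            p_theta[r, :] = acc

    # -- azimuthal density per pixel --
    by_off = sorted(dists, key=lambda d: d.region.off_axis)
    offs = np.array([d.region.off_axis for d in by_off])
    col_phi = phi[0, :] if np.all(np.isfinite(phi[0, :])) else np.nanmean(phi, axis=0)
    col_lat = lateral[0, :]
    p_phi_cols = np.zeros(shape[1])
    for c in range(shape[1]):
        acc = 0.0
        for idx, w in _interp_weights(col_lat[c], offs):
            acc += w * by_off[idx].azimuth_density(col_phi[c])
        p_phi_cols[c] = acc
    p_phi = np.broadcast_to(p_phi_cols, shape).copy()

    c_theta, flag_theta = _normalize_reciprocal(p_theta)
    c_phi, flag_phi = _normalize_reciprocal(p_phi)
    return CorrectionMaps(c_theta=c_theta, c_phi=c_phi,
                          qa_mask=flag_theta | flag_phi)


def _normalize_reciprocal(density: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1/density, capped where the density vanishes, scaled to mean 1."""
    density = np.where(np.isfinite(density), density, 0.0)
    with np.errstate(divide="ignore"):
        raw = np.where(density > 0, 1.0 / np.where(density > 0, density, 1.0),
                       np.inf)
    flagged = ~np.isfinite(raw)
    finite = raw[~flagged]
    cap = MAX_CORRECTION * (np.median(finite) if finite.size else 1.0)
    raw = np.where(flagged, cap, raw)
    return raw / raw.mean(), flagged


def apply_correction(
    i_pol: np.ndarray,
    maps: CorrectionMaps,
    geometry: CameraGeometry | None = None,
) -> ProjectedDoseImage:
    """Pixelwise D ∝ C_θ · C_φ · I_pol; masked (NaN) pixels propagate as 0."""
    i_pol = np.asarray(i_pol, dtype=float)
    if i_pol.shape != maps.c_theta.shape:
        raise ValueError(
            f"shape mismatch: image {i_pol.shape} vs maps {maps.c_theta.shape}")
    dose = maps.c_theta * maps.c_phi * i_pol
    dose = np.where(np.isfinite(dose), dose, 0.0)
    dose = np.clip(dose, 0.0, None)
    if geometry is None:
        geometry = CameraGeometry(image_shape=i_pol.shape)
    return ProjectedDoseImage(
        dose=dose,
        depth_axis=geometry.depth_axis(),
        lateral_axis=geometry.lateral_axis(),
        pixel_scale=geometry.pixel_scale,
    )
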