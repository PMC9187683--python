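"""Per-pixel Malus-law decomposition of four-angle polarizer stacks.

A rotating linear polarizer in front of the camera modulates each pixel as

    I(α0) = I_pol cos²(α0 − α) + I_unpol

where α0 is the polarizer transmission axis, α the angle of linear
polarization (AoLP) of the light and I_pol/I_unpol the polarized amplitude
and the unpolarized DC term.  The degree of linear polarization is
DoLP = I_pol / (I_pol + I_unpol) × 100.

With the standard two-orthogonal-pair angle set {0°, 45°, 90°, 135°} the
decomposition has the closed form of linear Stokes polarimetry:

    Q = I(0) − I(90),  U = I(45) − I(135)
    I_pol = √(Q² + U²),  α = ½ atan2(U, Q)
    I_unpol = (I(0) + I(90) − I_pol) / 2

The fitted DC term is taken *as* the unpolarized contribution: the physical
factor-½ transmission of unpolarized light through an ideal polarizer is
absorbed into I_unpol, matching the DoLP definition above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FOUR_ANGLES",
    "PolarizedStack",
    "PolarimetryMaps",
    "malus_intensity",
    "solve_four_angles",
    "fit_general",
    "dolp_map",
    "aolp_map",
    "region_dolp_stats",
]

FOUR_ANGLES = (0.0, 45.0, 90.0, 135.0)


@dataclass
class PolarizedStack:
    """Co-registered intensity frames indexed by polarizer angle.

    Parameters
    ----------
    frames : dict[float, numpy.ndarray]
        Polarizer transmission-axis angle in degrees → 2D non-negative
        intensity image.  All frames must share one shape; at least three
        angles distinct modulo 180° are required for a decomposition.
    pixel_scale : float
        mm per pixel.
    exposure : float
        Integration time in seconds (bookkeeping only).
    """

    frames: dict[float, np.ndarray]
    pixel_scale: float = 0.26
    exposure: float = 30.0

    def __post_init__(self) -> None:
        self.frames = {
            float(a) % 180.0: np.asarray(img, dtype=float)
            for a, img in self.frames.items()
        }
        if len(self.frames) < 3:
            raise ValueError(
                f"need >=3 distinct polarizer angles (mod 180°), got {len(self.frames)}"
            )
        shapes = {img.shape for img in self.frames.values()}
        if len(shapes) != 1:
            raise ValueError(f"frames are not co-registered: shapes {shapes}")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")

    @property
    def angles(self) -> tuple[float, ...]:
        return tuple(sorted(self.frames))

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.frames.values())).shape

    @property
    def has_four_standard_angles(self) -> bool:
        return set(self.angles) == set(FOUR_ANGLES)


@dataclass
class PolarimetryMaps:
    """Per-pixel output of the Malus decomposition.

    ``aolp`` is reported in (−90°, 90°], 0° being the first polarizer axis;
    it is NaN where the signal carries no polarized component.  ``qa_mask``
    flags pixels whose fitted DC term was negative before clamping (a noise
    signature).  ``fit_residual`` holds the model-consistency defect
    |I(0)+I(90) − I(45)−I(135)| for the four-angle solver, or the RMS fit
    residual for the general solver.
    """

    i_pol: np.ndarray
    i_unpol: np.ndarray
    aolp: np.ndarray
    fit_residual: np.ndarray
    qa_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.qa_mask is None:
            self.qa_mask = np.zeros(self.i_pol.shape, dtype=bool)

    @property
    def dolp(self) -> np.ndarray:
        return dolp_map(self)

    @property
    def i_total(self) -> np.ndarray:
        return self.i_pol + self.i_unpol


def malus_intensity(i_pol, i_unpol, alpha0, alpha):
    """Forward Malus model I = I_pol cos²(α0 − α) + I_unpol (degrees in)."""
    i_pol = np.asarray(i_pol, dtype=float)
    i_unpol = np.asarray(i_unpol, dtype=float)
    if np.any(i_pol < 0) or np.any(i_unpol < 0):
        raise ValueError("intensity components must be non-negative")
    delta = np.deg2rad(np.asarray(alpha0, dtype=float) - np.asarray(alpha, dtype=float))
    return i_pol * np.cos(delta) ** 2 + i_unpol


def solve_four_angles(stack: PolarizedStack) -> PolarimetryMaps:
    """Closed-form per-pixel Malus decomposition for the {0,45,90,135} set.

    Round-trips exactly on noiseless model-generated stacks.  Falls back to
    :func:`fit_general` pixelwise when the stack carries a different angle
    set.  Negative unpolarized estimates (possible under noise) are clamped
    to zero and flagged in ``qa_mask``.
    """
    if not stack.has_four_standard_angles:
        return _fit_stack_general(stack)

    i0 = stack.frames[0.0]
    i45 = stack.frames[45.0]
    i90 = stack.frames[90.0]
    i135 = stack.frames[135.0]

    q = i0 - i90
    u = i45 - i135
    i_pol = np.hypot(q, u)
    aolp = 0.5 * np.degrees(np.arctan2(u, q))
    i_unpol = 0.5 * (i0 + i90 - i_pol)
    residual = np.abs((i0 + i90) - (i45 + i135))

    qa = i_unpol < 0
    i_unpol = np.clip(i_unpol, 0.0, None)
    # wrap AoLP into (-90, 90]
    aolp = np.where(aolp <= -90.0, aolp + 180.0, aolp)
    aolp = np.where(i_pol == 0, np.nan, aolp)
    return PolarimetryMaps(i_pol=i_pol, i_unpol=i_unpol, aolp=aolp,
                           fit_residual=residual, qa_mask=qa)


def fit_general(intensities, start=None):
    """Bounded nonlinear least squares on the Malus model for one pixel.

    Parameters
    ----------
    intensities : sequence of (alpha0_degrees, value)
        At least three angles distinct modulo 180°.
    start : (i_pol, i_unpol, alpha) or None
        Initial guess; defaults to the quadrature estimate from the data.

    Returns
    -------
    (i_pol, i_unpol, alpha_degrees, rms_residual)
        ``alpha`` is NaN when the polarized amplitude vanishes.
    """
    pts = [(float(a), float(v)) for a, v in intensities]
    angles = np.array([a for a, _ in pts])
    values = np.array([v for _, v in pts])
    if len({round(a % 180.0, 9) for a in angles}) < 3:
        raise ValueError("underdetermined: need >=3 distinct angles modulo 180°")

    # Linear pre-solve in the Stokes-like parameters (a, b, c):
    # I = a + b cos(2α0) + c sin(2α0)  with a = I_unpol + I_pol/2,
    # b = (I_pol/2) cos 2α, c = (I_pol/2) sin 2α.
    two = np.deg2rad(2.0 * angles)
    design = np.column_stack([np.ones_like(two), np.cos(two), np.sin(two)])
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    a, b, c = coef
    i_pol0 = 2.0 * np.hypot(b, c)
    alpha0 = 0.5 * np.degrees(np.arctan2(c, b))
    i_unpol0 = a - i_pol0 / 2.0
    if start is not None:
        i_pol0, i_unpol0, alpha0 = start

    def resid(p):
        return malus_intensity(max(p[0], 0.0), max(p[1], 0.0), angles, p[2]) - values

    x0 = np.array([max(i_pol0, 0.0), max(i_unpol0, 0.0), alpha0])
    sol = least_squares(
        resid, x0,
        bounds=([0.0, 0.0, -1e3], [np.inf, np.inf, 1e3]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    i_pol, i_unpol, alpha = sol.x
    alpha = ((alpha + 90.0) % 180.0) - 90.0
    if alpha == -90.0:
        alpha = 90.0
    if i_pol <= 1e-8 * max(1.0, i_unpol):
        alpha = np.nan
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return float(i_pol), float(i_unpol), float(alpha), rms


def _fit_stack_general(stack: PolarizedStack) -> PolarimetryMaps:
    shape = stack.shape
    i_pol = np.empty(shape)
    i_unpol = np.empty(shape)
    aolp = np.empty(shape)
    residual = np.empty(shape)
    angles = stack.angles
    frames = [stack.frames[a] for a in angles]
    for idx in np.ndindex(shape):
        vals = [(a, f[idx]) for a, f in zip(angles, frames)]
        i_pol[idx], i_unpol[idx], aolp[idx], residual[idx] = fit_general(vals)
    return PolarimetryMaps(i_pol=i_pol, i_unpol=i_unpol, aolp=aolp,
                           fit_residual=residual)


def dolp_map(maps: PolarimetryMaps) -> np.ndarray:
    """Degree of linear polarization in percent, DoLP = I_pol/I_tot × 100.

    Pixels with zero total intensity are defined to carry DoLP 0.
    """
    total = maps.i_pol + maps.i_unpol
    with np.errstate(invalid="ignore", divide="ignore"):
        dolp = np.where(total > 0, 100.0 * maps.i_pol / np.where(total > 0, total, 1.0), 0.0)
    return np.clip(dolp, 0.0, 100.0)


def aolp_map(maps: PolarimetryMaps) -> np.ndarray:
    """Angle of linear polarization in degrees, (−90, 90], NaN when undefined."""
    return maps.aolp


def region_dolp_stats(maps: PolarimetryMaps, roi) -> tuple[float, float]:
    """Mean ± standard deviation of DoLP (percent) over a rectangular ROI.

    ``roi`` is ``(row_slice, col_slice)``; an empty selection is an error.
    """
    dolp = dolp_map(maps)[roi]
    if dolp.size == 0:
        raise ValueError("empty region of interest")
    return float(np.mean(dolp)), float(np.std(dolp))
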