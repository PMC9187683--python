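"""Dose-curve extraction from projected dose images.

Projected percent depth dose (PPDD): lateral sum over a window per depth
row, normalized to 100 at the maximum.  Lateral profiles are drawn at a
chosen depth (usually d_max) and normalized to 100 on the central axis.
Field size is the full width at half maximum of a profile; agreement with
a reference curve is summarized as mean ± std of (measured − reference)
in percentage points of the normalized dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correction import ProjectedDoseImage

__all__ = [
    "DoseCurve",
    "extract_ppdd",
    "extract_profile",
    "fwhm_field_size",
    "difference_stats",
]


@dataclass
class DoseCurve:
    """A 1D normalized dose curve (percent) over physical positions (cm)."""

    positions: np.ndarray
    values: np.ndarray
    kind: str = "ppdd"  # "ppdd" | "profile"
    normalization: str = "max=100"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.values.shape:
            raise ValueError("positions and values must be matching 1D arrays")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def d_max(self) -> float:
        """Position of the curve maximum."""
        return float(self.positions[int(np.argmax(self.values))])

    def resample(self, positions) -> "DoseCurve":
        positions = np.asarray(positions, dtype=float)
        lo, hi = self.positions[0], self.positions[-1]
        if positions[-1] < lo or positions[0] > hi:
            raise ValueError("resampling grid does not overlap the curve support")
        vals = np.interp(positions, self.positions, self.values)
        return DoseCurve(positions, vals, kind=self.kind,
                         normalization=self.normalization)


def extract_ppdd(dose: ProjectedDoseImage, lateral_window: float | None = None
                 ) -> DoseCurve:
    """Projected percent depth dose: lateral sum per depth, max = 100.

    ``lateral_window`` is the full width (cm) of the summation band around
    the beam axis; by default the whole image width (the beam width) is
    summed.
    """
    lat = dose.lateral_axis
    if lateral_window is None:
        cols = np.ones(lat.size, dtype=bool)
    else:
        cols = np.abs(lat) <= lateral_window / 2.0
    if not cols.any():
        raise ValueError("lateral summation window selects no columns")
    raw = dose.dose[:, cols].sum(axis=1)
    peak = raw.max()
    if peak <= 0:
        raise ValueError("image carries no signal in the summation window")
    return DoseCurve(dose.depth_axis, 100.0 * raw / peak, kind="ppdd")


def extract_profile(dose: ProjectedDoseImage, depth: float,
                    averaging_window: float = 0.5) -> DoseCurve:
    """Lateral profile at a depth, window-averaged, central axis = 100."""
    z = dose.depth_axis
    if depth < z[0] or depth > z[-1]:
        raise ValueError(f"depth {depth} cm outside the imaged range "
                         f"[{z[0]:.2f}, {z[-1]:.2f}] cm")
    rows = np.abs(z - depth) <= averaging_window / 2.0
    if not rows.any():
        rows = np.zeros(z.size, dtype=bool)
        rows[int(np.argmin(np.abs(z - depth)))] = True
    raw = dose.dose[rows, :].mean(axis=0)
    center = np.interp(0.0, dose.lateral_axis, raw)
    if center <= 0:
        raise ValueError("no signal on the central axis at this depth")
    return DoseCurve(dose.lateral_axis, 100.0 * raw / center, kind="profile")


def fwhm_field_size(profile: DoseCurve) -> float:
    """Full width at half the central-axis value, by linear interpolation."""
    x, y = profile.positions, profile.values
    half = np.interp(0.0, x, y) / 2.0
    above = y >= half
    if not above.any() or above.all():
        raise ValueError("profile does not cross the 50% level on both sides")
    idx = np.flatnonzero(above)
    left, right = idx[0], idx[-1]
    if left == 0 or right == y.size - 1:
        raise ValueError("profile does not cross the 50% level on both sides")

    def cross(i0, i1):
        x0, x1, y0, y1 = x[i0], x[i1], y[i0], y[i1]
        return x0 + (half - y0) * (x1 - x0) / (y1 - y0)

    return float(cross(right, right + 1) - cross(left - 1, left))


def difference_stats(measured: DoseCurve, reference: DoseCurve,
                     region: tuple[float, float] | None = None
                     ) -> tuple[float, float]:
    """Mean ± std of (measured − reference), percentage points.

    The measured curve is resampled onto the reference grid by linear
    interpolation; ``region`` restricts positions to [lo, hi].
    """
    pos = reference.positions
    lo = max(pos[0], measured.positions[0])
    hi = min(pos[-1], measured.positions[-1])
    if lo >= hi:
        raise ValueError("curves have disjoint supports")
    mask = (pos >= lo) & (pos <= hi)
    if region is not None:
        mask &= (pos >= region[0]) & (pos <= region[1])
    if not mask.any():
        raise ValueError("comparison region selects no points")
    diff = measured.resample(pos[mask]).values - reference.values[mask]
    return float(np.mean(diff)), float(np.std(diff))
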