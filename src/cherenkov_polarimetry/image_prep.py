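"""Raw-frame conditioning: temporal median, background subtraction, flat field.

The fixed pipeline order is median → background subtraction → cos⁴
flat-field division, mirroring how long-exposure CCD frames of a radiation
environment are usually cleaned: the temporal median across repeated
exposures suppresses transient spikes from stray radiation hitting the
sensor, the averaged dark/ambient background is subtracted, and the radial
sensitivity falloff of the lens (vignetting) is divided out using a
cos⁴(θ_ij) model fitted to a uniform-emitter flat frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "FrameSequence",
    "VignetteModel",
    "temporal_median",
    "subtract_background",
    "fit_vignette",
    "apply_flat",
    "preprocess",
]


@dataclass
class FrameSequence:
    """A list of same-shaped raw frames of one kind (signal/background/flat)."""

    frames: list
    kind: str = "signal"
    exposure: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in ("signal", "background", "flat"):
            raise ValueError(f"unknown frame kind {self.kind!r}")
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        if len(self.frames) == 0:
            raise ValueError("need at least one frame")
        shapes = {f.shape for f in self.frames}
        if len(shapes) != 1:
            raise ValueError(f"frame shape mismatch: {shapes}")


@dataclass
class VignetteModel:
    """cos⁴ lens falloff: amplitude · cos⁴(arctan(r/f)) around an optical center.

    ``f`` is the focal-length-like scale parameter in pixels; r is pixel
    distance to the center.  Correction divides by the model normalized to
    1.0 at the center.
    """

    center: tuple[float, float]
    f: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("scale parameter f must be positive")

    def evaluate(self, shape: tuple[int, int]) -> np.ndarray:
        ii, jj = np.indices(shape)
        r = np.hypot(ii - self.center[0], jj - self.center[1])
        return self.amplitude * np.cos(np.arctan(r / self.f)) ** 4


def temporal_median(frames) -> np.ndarray:
    """Pixelwise median across frames; removes isolated radiation spikes."""
    if isinstance(frames, FrameSequence):
        frames = frames.frames
    arr = np.stack([np.asarray(f, dtype=float) for f in frames])
    return np.median(arr, axis=0)


def subtract_background(signal, background_frames, *, signal_exposure=None,
                        background_exposure=None) -> np.ndarray:
    """Subtract the mean background frame, clamping the result at zero.

    If both exposures are supplied and differ, the background is scaled by
    the exposure ratio (with a warning); the fraction of clamped pixels is
    logged as a data-quality hint.
    """
    signal = np.asarray(signal, dtype=float)
    if isinstance(background_frames, FrameSequence):
        if background_exposure is None:
            background_exposure = background_frames.exposure
        background_frames = background_frames.frames
    bg = np.mean(np.stack([np.asarray(f, dtype=float) for f in background_frames]), axis=0)
    if bg.shape != signal.shape:
        raise ValueError(f"shape mismatch: signal {signal.shape} vs background {bg.shape}")
    if signal_exposure is not None and background_exposure is not None \
            and signal_exposure != background_exposure:
        ratio = signal_exposure / background_exposure
        logger.warning(
            "exposure mismatch (signal %.3gs, background %.3gs); scaling background by %.4f",
            signal_exposure, background_exposure, ratio)
        bg = bg * ratio
    out = signal - bg
    negative = out < 0
    if negative.any():
        logger.info("background subtraction clamped %.2f%% of pixels at zero",
                    100.0 * negative.mean())
    return np.clip(out, 0.0, None)


def fit_vignette(flat_image, *, center_guess=None) -> VignetteModel:
    """Least-squares fit of A·cos⁴(arctan(r/f)) to a uniform-emitter flat.

    The optical center is a fitted parameter; the initial guess defaults to
    the image center.
    """
    flat = np.asarray(flat_image, dtype=float)
    shape = flat.shape
    if center_guess is None:
        center_guess = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    ii, jj = np.indices(shape)

    def model(p):
        ci, cj, f, amp = p
        r = np.hypot(ii - ci, jj - cj)
        return amp * np.cos(np.arctan(r / f)) ** 4

    def resid(p):
        return (model(p) - flat).ravel()

    f0 = max(shape)  # mild vignetting start
    x0 = np.array([center_guess[0], center_guess[1], f0, float(flat.max())])
    sol = least_squares(resid, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not sol.success:
        raise RuntimeError(f"vignette fit failed to converge: {sol.message}")
    ci, cj, f, amp = sol.x
    if f <= 0:
        raise RuntimeError(f"vignette fit produced non-physical scale f={f}")
    return VignetteModel(center=(float(ci), float(cj)), f=float(f), amplitude=float(amp))


def apply_flat(image, model: VignetteModel) -> np.ndarray:
    """Divide by the vignette model normalized to 1 at the optical center."""
    image = np.asarray(image, dtype=float)
    falloff = model.evaluate(image.shape) / model.amplitude
    return image / falloff


def preprocess(signal: FrameSequence, background: FrameSequence | None = None,
               flat: FrameSequence | np.ndarray | None = None,
               vignette: VignetteModel | None = None) -> np.ndarray:
    """Run the fixed median → background → flat-field pipeline on one stack.

    Either a flat frame (fitted here) or a pre-fitted vignette model may be
    supplied; with neither, no flat-field correction is applied.
    """
    img = temporal_median(signal)
    if background is not None:
        img = subtract_background(img, background,
                                  signal_exposure=signal.exposure,
                                  background_exposure=background.exposure)
    if vignette is None and flat is not None:
        flat_img = temporal_median(flat) if isinstance(flat, FrameSequence) else np.asarray(flat)
        vignette = fit_vignette(flat_img)
    if vignette is not None:
        img = apply_flat(img, vignette)
    return img
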