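"""File layer: TIFF/NPZ image stacks with YAML sidecars, HDF5 distributions.

A measurement directory holds one multi-page TIFF (or NPZ) per polarizer
angle plus ``stack.yaml`` describing angles, pixel scale and exposure;
angular distributions travel in a single HDF5 file with one group per
scoring region.  Curves and reports are plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .correction import ProjectedDoseImage
from .mc import AngularDistribution, ScoringRegion
from .metrics import DoseCurve
from .polarimetry import PolarimetryMaps, PolarizedStack

__all__ = [
    "write_stack", "read_stack",
    "write_frames", "read_frames",
    "write_distributions", "read_distributions",
    "write_maps", "read_maps",
    "write_dose_image", "read_dose_image",
    "write_curve", "read_curve",
]


def write_frames(path, frames) -> None:
    """Write a list of 2D frames as a multi-page TIFF (or .npz)."""
    path = Path(path)
    arr = np.stack([np.asarray(f, dtype=np.float32) for f in frames])
    if path.suffix == ".npz":
        np.savez_compressed(path, frames=arr)
    else:
        tifffile.imwrite(path, arr, photometric="minisblack")


def read_frames(path) -> list[np.ndarray]:
    path = Path(path)
    if path.suffix == ".npz":
        arr = np.load(path)["frames"]
    else:
        arr = tifffile.imread(path)
    arr = np.atleast_3d(arr)
    if arr.ndim == 2:
        arr = arr[None, ...]
    return [a.astype(float) for a in arr]


def write_stack(directory, stack_frames: dict, pixel_scale: float,
                exposure: float, *, background=None, flat=None,
                fmt: str = "tiff") -> Path:
    """Write a polarizer stack directory with its YAML sidecar.

    ``stack_frames`` maps polarizer angle → frame list (or single frame).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = "npz" if fmt == "npz" else "tiff"
    meta = {"pixel_scale_mm": float(pixel_scale),
            "exposure_s": float(exposure), "angles": {}}
    for angle, frames in stack_frames.items():
        if isinstance(frames, np.ndarray) and frames.ndim == 2:
            frames = [frames]
        name = f"angle_{int(round(float(angle))):03d}.{ext}"
        write_frames(directory / name, frames)
        meta["angles"][float(angle)] = name
    if background is not None:
        write_frames(directory / f"background.{ext}", background)
        meta["background"] = f"background.{ext}"
    if flat is not None:
        flat = [flat] if isinstance(flat, np.ndarray) and np.ndim(flat) == 2 else flat
        write_frames(directory / f"flat.{ext}", flat)
        meta["flat"] = f"flat.{ext}"
    sidecar = directory / "stack.yaml"
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))
    return sidecar


def read_stack(directory, reduce: str | None = None):
    """Read a stack directory; returns (frames_by_angle, meta dict).

    With ``reduce="median"`` each angle's frame list is collapsed into a
    single temporal-median frame and a :class:`PolarizedStack` is returned
    instead of the raw frame lists.
    """
    directory = Path(directory)
    meta = yaml.safe_load((directory / "stack.yaml").read_text())
    frames = {float(a): read_frames(directory / name)
              for a, name in meta["angles"].items()}
    extras = {}
    if "background" in meta:
        extras["background"] = read_frames(directory / meta["background"])
    if "flat" in meta:
        extras["flat"] = read_frames(directory / meta["flat"])
    if reduce == "median":
        collapsed = {a: np.median(np.stack(fs), axis=0) for a, fs in frames.items()}
        stack = PolarizedStack(frames=collapsed,
                               pixel_scale=meta["pixel_scale_mm"],
                               exposure=meta["exposure_s"])
        return stack, {**meta, **extras}
    return frames, {**meta, **extras}


def write_distributions(path, dists: list[AngularDistribution]) -> None:
    with h5py.File(path, "w") as f:
        for i, d in enumerate(dists):
            g = f.create_group(f"region_{i:03d}")
            g.attrs["depth_cm"] = d.region.depth
            g.attrs["off_axis_cm"] = d.region.off_axis
            g.attrs["voxel_cm"] = d.region.size
            g.attrs["n_photons"] = d.n_photons
            g.create_dataset("polar_edges", data=d.polar_edges)
            g.create_dataset("polar_hist", data=d.polar_hist)
            g.create_dataset("azimuth_edges", data=d.azimuth_edges)
            g.create_dataset("azimuth_hist", data=d.azimuth_hist)


def read_distributions(path) -> list[AngularDistribution]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f):
            g = f[key]
            out.append(AngularDistribution(
                region=ScoringRegion(depth=float(g.attrs["depth_cm"]),
                                     off_axis=float(g.attrs["off_axis_cm"]),
                                     size=float(g.attrs["voxel_cm"])),
                polar_edges=g["polar_edges"][:],
                polar_hist=g["polar_hist"][:],
                azimuth_edges=g["azimuth_edges"][:],
                azimuth_hist=g["azimuth_hist"][:],
                n_photons=int(g.attrs["n_photons"]),
            ))
    return out


def write_maps(path, maps: PolarimetryMaps) -> None:
    np.savez_compressed(path, i_pol=maps.i_pol, i_unpol=maps.i_unpol,
                        aolp=maps.aolp, fit_residual=maps.fit_residual,
                        qa_mask=maps.qa_mask)


def read_maps(path) -> PolarimetryMaps:
    data = np.load(path)
    return PolarimetryMaps(i_pol=data["i_pol"], i_unpol=data["i_unpol"],
                           aolp=data["aolp"], fit_residual=data["fit_residual"],
                           qa_mask=data["qa_mask"])


def write_dose_image(path, dose: ProjectedDoseImage) -> None:
    np.savez_compressed(path, dose=dose.dose, depth_axis=dose.depth_axis,
                        lateral_axis=dose.lateral_axis,
                        pixel_scale=dose.pixel_scale)


def read_dose_image(path) -> ProjectedDoseImage:
    data = np.load(path)
    return ProjectedDoseImage(dose=data["dose"], depth_axis=data["depth_axis"],
                              lateral_axis=data["lateral_axis"],
                              pixel_scale=float(data["pixel_scale"]))


def write_curve(path, curve: DoseCurve) -> None:
    pd.DataFrame({"position_cm": curve.positions,
                  "dose_percent": curve.values}).to_csv(path, index=False)


def read_curve(path, kind: str = "ppdd") -> DoseCurve:
    df = pd.read_csv(path)
    return DoseCurve(df["position_cm"].to_numpy(),
                     df["dose_percent"].to_numpy(), kind=kind)
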