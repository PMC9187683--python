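"""Log-log interpolation over the bundled water transport tables."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = ["collisional_stopping_power", "photon_attenuation_coefficient"]


@lru_cache(maxsize=None)
def _load(name: str) -> tuple[np.ndarray, np.ndarray]:
    path = resources.files("cherenkov_polarimetry.data").joinpath(name)
    rows = np.loadtxt(path.open(), delimiter=",", comments="#")
    return rows[:, 0], rows[:, 1]


def _loglog_interp(x: float | np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    x = np.clip(x, xs[0], xs[-1])
    return np.exp(np.interp(np.log(x), np.log(xs), np.log(ys)))


def collisional_stopping_power(energy_kev, density: float = 1.0):
    """Collisional stopping power of water in keV/cm at the given energy."""
    xs, ys = _load("water_electron_stopping_power.csv")
    # table is MeV cm^2/g -> keV/cm
    return _loglog_interp(energy_kev, xs, ys) * density * 1000.0


def photon_attenuation_coefficient(energy_kev, density: float = 1.0):
    """Total linear attenuation coefficient of water in 1/cm."""
    xs, ys = _load("water_photon_attenuation.csv")
    return _loglog_interp(energy_kev, xs, ys) * density
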