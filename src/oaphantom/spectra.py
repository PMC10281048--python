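"""Embedded chromophore spectra for the near-infrared window (700-1100 nm).

The optical absorption model needs molar extinction coefficients of oxy-
and deoxy-hemoglobin and absorption coefficients of pure water, fat, and
melanosome. The tables below are compact 25-nm digitizations compiled
from the standard literature compilations used throughout tissue optics
(the Prahl hemoglobin compilation, Hale & Querry water data, van Veen fat
measurements, and the Jacques melanosome power law). Absolute values of
such digitizations differ by a few percent between sources; the tables
are swappable via :class:`ChromophoreTable` for users with their own
calibrated spectra.

Units: extinction coefficients in mm^-1 M^-1; absorption coefficients of
pure chromophores in mm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["ChromophoreTable", "DEFAULT_CHROMOPHORES", "WATER_SCATTERING_TABLE"]

# wavelength grid, nm
_WL = np.arange(700.0, 1101.0, 25.0)

# molar extinction, cm^-1 M^-1 (converted to mm^-1 M^-1 below)
_EPS_HBO2_CM = np.array([
    290.0,   # 700
    414.0,   # 725
    518.0,   # 750
    660.0,   # 775
    816.0,   # 800
    938.0,   # 825
    1058.0,  # 850
    1130.0,  # 875
    1198.0,  # 900
    1214.0,  # 925
    1207.0,  # 950
    1193.0,  # 975
    1138.0,  # 1000
    1090.0,  # 1025
    1024.0,  # 1050
    968.0,   # 1075
    910.0,   # 1100
])
_EPS_HB_CM = np.array([
    1794.3,  # 700
    1165.0,  # 725
    1405.2,  # 750
    1155.0,  # 775
    761.7,   # 800
    693.0,   # 825
    691.3,   # 850
    713.0,   # 875
    761.8,   # 900
    790.0,   # 925
    813.0,   # 950
    822.0,   # 975
    846.0,   # 1000
    900.0,   # 1025
    980.0,   # 1050
    1065.0,  # 1075
    1150.0,  # 1100
])

# pure-water absorption, mm^-1
_MUA_WATER = np.array([
    0.00060, 0.00157, 0.00261, 0.00248, 0.00206, 0.00298, 0.00433,
    0.00551, 0.00679, 0.01480, 0.03880, 0.04860, 0.03630, 0.02640,
    0.01800, 0.01400, 0.01600,
])

# pure-fat absorption, mm^-1 (soybean-oil-like lipid spectrum; 930 nm band)
_MUA_FAT = np.array([
    0.00080, 0.00065, 0.00055, 0.00060, 0.00075, 0.00085, 0.00090,
    0.00120, 0.00380, 0.01050, 0.00480, 0.00300, 0.00330, 0.00500,
    0.00570, 0.00450, 0.00280,
])

# melanosome absorption power law: mua ~ 1.70e12 * lambda[nm]^-3.48 cm^-1
_MUA_MEL = 1.70e11 * _WL ** (-3.48)


@dataclass(frozen=True)
class ChromophoreTable:
    """Wavelength-indexed chromophore data with linear interpolation."""

    wavelengths: np.ndarray = field(default_factory=lambda: _WL.copy())
    eps_hbo2: np.ndarray = field(default_factory=lambda: _EPS_HBO2_CM / 10.0)
    eps_hb: np.ndarray = field(default_factory=lambda: _EPS_HB_CM / 10.0)
    mua_water: np.ndarray = field(default_factory=lambda: _MUA_WATER.copy())
    mua_fat: np.ndarray = field(default_factory=lambda: _MUA_FAT.copy())
    mua_melanosome: np.ndarray = field(default_factory=lambda: _MUA_MEL.copy())

    def __post_init__(self):
        wl = self.wavelengths
        if np.any(np.diff(wl) <= 0):
            raise InvalidArgumentError("wavelength grid must be strictly increasing")
        for name in ("eps_hbo2", "eps_hb", "mua_water", "mua_fat",
                     "mua_melanosome"):
            arr = getattr(self, name)
            if len(arr) != len(wl):
                raise InvalidArgumentError(f"{name} length mismatch")
            if np.any(np.asarray(arr) < 0):
                raise InvalidArgumentError(f"{name} must be non-negative")

    def check_wavelength(self, wl: float) -> None:
        if not (self.wavelengths[0] <= wl <= self.wavelengths[-1]):
            raise InvalidArgumentError(
                f"wavelength {wl} nm outside the table range "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}] nm")

    def _interp(self, arr: np.ndarray, wl: float) -> float:
        self.check_wavelength(wl)
        return float(np.interp(wl, self.wavelengths, arr))

    def eps_hbo2_at(self, wl: float) -> float:
        return self._interp(self.eps_hbo2, wl)

    def eps_hb_at(self, wl: float) -> float:
        return self._interp(self.eps_hb, wl)

    def mua_water_at(self, wl: float) -> float:
        return self._interp(self.mua_water, wl)

    def mua_fat_at(self, wl: float) -> float:
        return self._interp(self.mua_fat, wl)

    def mua_melanosome_at(self, wl: float) -> float:
        return self._interp(self.mua_melanosome, wl)


DEFAULT_CHROMOPHORES = ChromophoreTable()

# Pure-water scattering coefficient measurements (mm^-1). Synthetic
# reference table generated from the lambda^-4.32 molecular-scattering law
# anchored at 0.0029 m^-1 @ 500 nm; magnitudes are physically negligible
# for the phantom but keep the background medium well-defined. The
# scattering power-law parameters of water are obtained by fitting this
# table (see optical.fit_water_scattering).
_WS_WL = np.arange(700.0, 1101.0, 50.0)
WATER_SCATTERING_TABLE = (
    _WS_WL,
    2.9e-6 * (500.0 / _WS_WL) ** 4.32,
)
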