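"""Multi-wavelength optical property maps.

Absorption is a linear mix of the pure-chromophore spectra weighted by
the voxel's volume fractions:

    mua(r, lam) = sum_i f_i(r) * mua_i(lam),

with oxygenated/deoxygenated blood fractions fb*s and fb*(1-s) and
mua_oxy/deoxy = ln(10) * ctHb_blood * eps_HbO2/Hb(lam).

Scattering follows the reduced-scattering power law

    mus(r, lam) = mus'(r, lam_ref) / (1 - g(r)) * (lam / lam_ref)^(-b),

with lam_ref = 500 nm. For tissues whose literature ranges are intervals,
mus'(lam_ref) and b are positively correlated; a single uniform variate X
drives both ends of the interval jointly, one draw per tissue per
phantom. Anisotropy g and refractive index n are piecewise constant per
tissue and wavelength-independent over the NIR window. The peripheral
angiogenesis region inherits mus, g, and n from its recorded underlying
tissue (fat-group or glandular).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import labels as L
from .anatomy import LabelVolume
from .errors import InvalidArgumentError
from .functional import FunctionalMaps
from .spectra import ChromophoreTable, DEFAULT_CHROMOPHORES, WATER_SCATTERING_TABLE

__all__ = [
    "LAMBDA_REF",
    "TissueOpticalSpec",
    "OPTICAL_TABLE",
    "OpticalMaps",
    "compute_mua",
    "sample_scattering_params",
    "compute_mus",
    "fit_water_scattering",
    "assemble_optical_maps",
]

LAMBDA_REF = 500.0  # nm


@dataclass(frozen=True)
class TissueOpticalSpec:
    """Reduced-scattering bounds at lambda_ref, power-law exponent bounds,
    anisotropy, refractive index. Equal bounds denote a fixed value."""

    mus_ref_low: float
    mus_ref_high: float
    b_low: float
    b_high: float
    g: float
    n: float

    def __post_init__(self):
        if self.mus_ref_low > self.mus_ref_high or self.b_low > self.b_high:
            raise InvalidArgumentError("bounds must be ordered")
        if not (0 <= self.g < 1):
            raise InvalidArgumentError("g must be in [0, 1)")
        if self.n < 1:
            raise InvalidArgumentError("n must be >= 1")


def fit_water_scattering() -> tuple[float, float]:
    """Fit (mus'_ref, b) of the scattering power law to the embedded
    pure-water scattering table by log-log least squares."""
    wl, mus = WATER_SCATTERING_TABLE
    slope, intercept = np.polyfit(np.log(wl / LAMBDA_REF), np.log(mus), 1)
    return float(math.exp(intercept)), float(-slope)


_WATER_MUS_REF, _WATER_B = fit_water_scattering()

#: Table keyed by tissue group: scattering bounds, g, n. Water's power-law
#: parameters come from the fit above; its scattering is effectively
#: isotropic (g = 0) and n is that of water.
OPTICAL_TABLE: dict[str, TissueOpticalSpec] = {
    "fat": TissueOpticalSpec(0.83, 0.83, 0.617, 0.617, 0.98, 1.44),
    "glandular": TissueOpticalSpec(1.06, 1.06, 0.52, 0.52, 0.96, 1.36),
    "skin": TissueOpticalSpec(3.72, 4.78, 1.39, 2.453, 0.65, 1.37),
    "vessel": TissueOpticalSpec(2.2, 2.295, 0.66, 0.872, 0.976, 1.35),
    "VTC": TissueOpticalSpec(2.0, 2.07, 0.725, 1.487, 0.955, 1.39),
    "water": TissueOpticalSpec(_WATER_MUS_REF, _WATER_MUS_REF,
                               _WATER_B, _WATER_B, 0.0, 1.33),
}

#: tissue code -> optical table group (PA handled via underlying tissue)
_GROUP_OF_CODE = {
    L.WATER: "water",
    L.FAT: "fat", L.LIGAMENT: "fat", L.TDLU: "fat", L.DUCT: "fat",
    L.GLANDULAR: "glandular",
    L.SKIN: "skin", L.NIPPLE: "skin",
    L.ARTERY: "vessel", L.VEIN: "vessel",
    L.VTC: "VTC", L.NECROTIC_CORE: "VTC",
}


def compute_mua(
    functional: FunctionalMaps,
    table: ChromophoreTable,
    wavelength: float,
) -> np.ndarray:
    """Voxel-wise absorption coefficient (mm^-1) at one wavelength."""
    table.check_wavelength(wavelength)
    ln10 = math.log(10.0)
    cthb_molar = functional.ctHb_blood * 1e-6  # uM -> M
    mua_oxy = ln10 * cthb_molar * table.eps_hbo2_at(wavelength)
    mua_deoxy = ln10 * cthb_molar * table.eps_hb_at(wavelength)
    s = functional.s.astype(np.float64) / 100.0
    fb = functional.fb.astype(np.float64) / 100.0
    fw = functional.fw.astype(np.float64) / 100.0
    ff = functional.ff.astype(np.float64) / 100.0
    fm = functional.fm.astype(np.float64) / 100.0
    mua = (
        fb * s * mua_oxy
        + fb * (1.0 - s) * mua_deoxy
        + fw * table.mua_water_at(wavelength)
        + ff * table.mua_fat_at(wavelength)
        + fm * table.mua_melanosome_at(wavelength)
    )
    return mua.astype(np.float32)


def sample_scattering_params(
    spec: TissueOpticalSpec,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Jointly sample (mus'(lambda_ref), b) from the spec's intervals.

    A single X ~ U(0,1) drives both interval positions, producing the
    observed positive correlation between the two parameters. Degenerate
    intervals return their fixed values without consuming randomness.
    """
    if spec.mus_ref_low == spec.mus_ref_high and spec.b_low == spec.b_high:
        return spec.mus_ref_low, spec.b_low
    x = rng.uniform()
    mus_ref = (spec.mus_ref_high - spec.mus_ref_low) * x + spec.mus_ref_low
    b = (spec.b_high - spec.b_low) * x + spec.b_low
    return float(mus_ref), float(b)


def compute_mus(
    mus_ref: float,
    b: float,
    g: float,
    wavelength: float,
) -> float:
    """Scattering coefficient (mm^-1) from the reduced-scattering power law."""
    if g >= 1:
        raise InvalidArgumentError("anisotropy g must be < 1")
    if wavelength <= 0:
        raise InvalidArgumentError("wavelength must be > 0")
    return mus_ref / (1.0 - g) * (wavelength / LAMBDA_REF) ** (-b)


@dataclass
class OpticalMaps:
    """Per-voxel optical maps at each wavelength.

    ``mua`` and ``mus`` have shape (n_wavelengths, nx, ny, nz); ``g`` and
    ``n`` are wavelength-independent per-voxel maps.
    """

    wavelengths: tuple[float, ...]
    mua: np.ndarray
    mus: np.ndarray
    g: np.ndarray
    n: np.ndarray
    scattering_draws: dict[str, tuple[float, float]] = field(default_factory=dict)

    def index_of(self, wavelength: float) -> int:
        for i, wl in enumerate(self.wavelengths):
            if abs(wl - wavelength) < 1e-9:
                return i
        raise InvalidArgumentError(
            f"wavelength {wavelength} nm not among computed wavelengths "
            f"{self.wavelengths}")

    def mua_at(self, wavelength: float) -> np.ndarray:
        return self.mua[self.index_of(wavelength)]

    def mus_at(self, wavelength: float) -> np.ndarray:
        return self.mus[self.index_of(wavelength)]


def assemble_optical_maps(
    volume: LabelVolume,
    functional: FunctionalMaps,
    wavelengths,
    rng: np.random.Generator,
    table: ChromophoreTable = DEFAULT_CHROMOPHORES,
    optical_table: dict[str, TissueOpticalSpec] | None = None,
) -> OpticalMaps:
    """Build mua/mus/g/n maps for a phantom.

    One (mus'_ref, b) pair is drawn per tissue group per phantom (in a
    fixed group order for reproducibility). PA voxels inherit mus, g, and
    n from their recorded underlying tissue; their mua comes from their
    own functional values, which carry the angiogenesis signature.
    """
    if optical_table is None:
        optical_table = OPTICAL_TABLE
    wavelengths = tuple(float(w) for w in wavelengths)
    for wl in wavelengths:
        table.check_wavelength(wl)
    lab = volume.labels
    draws = {grp: sample_scattering_params(optical_table[grp], rng)
             for grp in ("fat", "glandular", "skin", "vessel", "VTC", "water")}

    # effective group per voxel, resolving PA to its underlying tissue
    group_idx = np.zeros(lab.shape, dtype=np.uint8)
    groups = list(optical_table.keys())
    code_map = dict(_GROUP_OF_CODE)
    pa_under = volume.meta.get("pa_underlying")
    for code, grp in code_map.items():
        group_idx[lab == code] = groups.index(grp)
    pa_vox = lab == L.PA
    if pa_vox.any():
        under = pa_under[pa_vox] if pa_under is not None \
            else np.full(int(pa_vox.sum()), L.FAT, dtype=np.uint8)
        under_groups = np.array(
            [groups.index(code_map.get(int(u), "fat")) for u in
             np.arange(256)], dtype=np.uint8)
        group_idx[pa_vox] = under_groups[under]

    g_map = np.zeros(lab.shape, dtype=np.float32)
    n_map = np.zeros(lab.shape, dtype=np.float32)
    for gi, grp in enumerate(groups):
        m = group_idx == gi
        g_map[m] = optical_table[grp].g
        n_map[m] = optical_table[grp].n

    nwl = len(wavelengths)
    mua = np.zeros((nwl,) + lab.shape, dtype=np.float32)
    mus = np.zeros((nwl,) + lab.shape, dtype=np.float32)
    for i, wl in enumerate(wavelengths):
        mua[i] = compute_mua(functional, table, wl)
        mus_of_group = {
            gi: compute_mus(draws[grp][0], draws[grp][1],
                            optical_table[grp].g, wl)
            for gi, grp in enumerate(groups)
        }
        lut = np.zeros(len(groups), dtype=np.float32)
        for gi, v in mus_of_group.items():
            lut[gi] = v
        mus[i] = lut[group_idx]

    return OpticalMaps(wavelengths=wavelengths, mua=mua, mus=mus,
                       g=g_map, n=n_map, scattering_draws=draws)
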