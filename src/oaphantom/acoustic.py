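"""Acoustic property maps: sound speed c (mm/us), density rho (g/mm^3),
and attenuation coefficient alpha0 (dB/MHz^y mm) with a power-law
exponent y.

Properties are drawn once per tissue per phantom — the distributions
model inter-subject variability, not intra-tissue texture — and broadcast
to the tissue's voxels. Water properties are fixed at their 37 degC
values (warm-bowl imaging). Time-domain wave solvers in common use assume
a spatially homogeneous attenuation exponent, so y is a per-phantom
scalar set by breast density type: 1.1151, 1.1642, 1.2563, 1.3635 for
types A through D. The peripheral-angiogenesis region inherits its
recorded underlying tissue's draws. Muscle has no published row in this
model; ingested volumes containing muscle must be cropped first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import labels as L
from .anatomy import LabelVolume
from .errors import InvalidArgumentError
from .sampling import FixedSpec, TruncatedGaussianSpec

__all__ = [
    "AcousticMaps",
    "ACOUSTIC_TABLE",
    "Y_BY_TYPE",
    "sample_acoustic_draws",
    "assemble_acoustic_maps",
]

#: Per-tissue-group distributions of (c, rho, alpha0).
ACOUSTIC_TABLE: dict[str, dict] = {
    "water": {
        "c": FixedSpec(1.521),
        "rho": FixedSpec(0.993e-3),
        "alpha0": FixedSpec(2.2e-4),
    },
    "fat": {
        "c": TruncatedGaussianSpec(1.44, 0.021, 1.41, 1.49),
        "rho": TruncatedGaussianSpec(0.911e-3, 0.053e-3, 0.812e-3, 0.961e-3),
        "alpha0": TruncatedGaussianSpec.normal(0.038, 0.004),
    },
    "glandular": {  # glandular / TDLU / duct
        "c": TruncatedGaussianSpec(1.54, 0.015, 1.517, 1.567),
        "rho": TruncatedGaussianSpec(1.041e-3, 0.045e-3, 0.99e-3, 1.092e-3),
        "alpha0": TruncatedGaussianSpec.normal(0.075, 0.008),
    },
    "ligament": {
        "c": TruncatedGaussianSpec(1.457, 0.019, 1.422, 1.496),
        "rho": TruncatedGaussianSpec(1.142e-3, 0.045e-3, 1.1e-3, 1.174e-3),
        "alpha0": TruncatedGaussianSpec.normal(0.126, 0.013),
    },
    "skin": {  # skin / nipple
        "c": TruncatedGaussianSpec(1.555, 0.01, 1.53, 1.58),
        "rho": TruncatedGaussianSpec(1.109e-3, 0.014e-3, 1.1e-3, 1.125e-3),
        "alpha0": TruncatedGaussianSpec.normal(0.184, 0.019),
    },
    "vessel": {  # artery / vein
        "c": TruncatedGaussianSpec(1.578, 0.011, 1.559, 1.59),
        "rho": TruncatedGaussianSpec(1.05e-3, 0.017e-3, 1.025e-3, 1.06e-3),
        "alpha0": FixedSpec(0.021),
    },
    "VTC": {  # VTC / necrotic core
        "c": TruncatedGaussianSpec(1.548, 0.01, 1.531, 1.565),
        "rho": TruncatedGaussianSpec(0.945e-3, 0.02e-3, 0.911e-3, 0.999e-3),
        "alpha0": TruncatedGaussianSpec.normal(0.269, 0.02),
    },
}

#: Homogeneous attenuation power-law exponent per breast density type.
Y_BY_TYPE = {"A": 1.1151, "B": 1.1642, "C": 1.2563, "D": 1.3635}

_GROUP_OF_CODE = {
    L.WATER: "water",
    L.FAT: "fat",
    L.GLANDULAR: "glandular", L.TDLU: "glandular", L.DUCT: "glandular",
    L.LIGAMENT: "ligament",
    L.SKIN: "skin", L.NIPPLE: "skin",
    L.ARTERY: "vessel", L.VEIN: "vessel",
    L.VTC: "VTC", L.NECROTIC_CORE: "VTC",
}

_GROUP_ORDER = ("water", "fat", "glandular", "ligament", "skin", "vessel", "VTC")


@dataclass
class AcousticMaps:
    """Per-voxel c/rho/alpha0 maps and the scalar attenuation exponent."""

    c: np.ndarray
    rho: np.ndarray
    alpha0: np.ndarray
    y: float
    draws: dict | None = None


def sample_acoustic_draws(
    rng: np.random.Generator,
    table: dict | None = None,
) -> dict:
    """One (c, rho, alpha0) draw per tissue group, in a fixed group order."""
    if table is None:
        table = ACOUSTIC_TABLE
    out = {}
    for grp in _GROUP_ORDER:
        row = table[grp]
        out[grp] = {prop: float(row[prop].sample(rng))
                    for prop in ("c", "rho", "alpha0")}
    return out


def assemble_acoustic_maps(
    volume: LabelVolume,
    breast_type: str,
    rng: np.random.Generator,
    table: dict | None = None,
) -> AcousticMaps:
    """Broadcast per-tissue draws to voxels; PA inherits its underlying
    tissue; y is the breast-type scalar."""
    if breast_type not in Y_BY_TYPE:
        raise InvalidArgumentError(f"unknown breast type {breast_type!r}")
    lab = volume.labels
    if (lab == L.MUSCLE).any():
        raise InvalidArgumentError(
            "volume contains muscle, which has no acoustic model; crop it "
            "before property assignment")
    draws = sample_acoustic_draws(rng, table=table)

    group_idx = np.zeros(lab.shape, dtype=np.uint8)
    for code, grp in _GROUP_OF_CODE.items():
        group_idx[lab == code] = _GROUP_ORDER.index(grp)
    pa_vox = lab == L.PA
    if pa_vox.any():
        pa_under = volume.meta.get("pa_underlying")
        under = pa_under[pa_vox] if pa_under is not None \
            else np.full(int(pa_vox.sum()), L.FAT, dtype=np.uint8)
        lut = np.array([_GROUP_ORDER.index(_GROUP_OF_CODE.get(int(u), "fat"))
                        for u in np.arange(256)], dtype=np.uint8)
        group_idx[pa_vox] = lut[under]

    def lut_for(prop):
        lut = np.zeros(len(_GROUP_ORDER), dtype=np.float32)
        for gi, grp in enumerate(_GROUP_ORDER):
            lut[gi] = draws[grp][prop]
        return lut

    return AcousticMaps(
        c=lut_for("c")[group_idx],
        rho=lut_for("rho")[group_idx],
        alpha0=lut_for("alpha0")[group_idx],
        y=Y_BY_TYPE[breast_type],
        draws=draws,
    )
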