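"""Phantom validation statistics.

Two quantities tie generated phantoms back to clinical observations: the
breast-volume percentage occupied by blood vessels (clinical optoacoustic
estimates put the mean near 0.44%) and the spatially averaged effective
optical attenuation mueff. For phantom-side validation mueff is computed
from the optical maps with the diffusion-approximation closed form

    mueff = sqrt(3 * mua * (mua + mus')),    mus' = mus * (1 - g),

averaged over breast tissue; clinical reference values are estimated from
reconstructed images by Beer-Lambert fits to depth-resolved signal decay,
so comparisons against them are qualitative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import labels as L
from .anatomy import (
    LabelVolume,
    ShapeParams,
    VesselTreeConfig,
    SHAPE_PARAM_TABLE,
    generate_fixture_anatomy,
    grow_vessel_trees,
)
from .errors import EmptyVolumeError, InvalidArgumentError
from .optical import OpticalMaps
from .subskin import SubskinParams, embed_subskin_vessels, generate_subskin_vessels

__all__ = [
    "EnsembleSummary",
    "vessel_volume_percentage",
    "estimate_mueff",
    "ensemble_summary",
    "hemispherical_vessel_phantom",
    "ensemble_vessel_volume_study",
]


def vessel_volume_percentage(volume: LabelVolume) -> float:
    """100 x (artery + vein voxels) / (all breast voxels)."""
    lab = volume.labels
    n_breast = int((lab != L.WATER).sum())
    if n_breast == 0:
        raise EmptyVolumeError("volume contains no breast voxels")
    n_vessel = int(np.isin(lab, np.array(L.VESSEL_CODES, dtype=np.uint8)).sum())
    return 100.0 * n_vessel / n_breast


def estimate_mueff(
    optical: OpticalMaps,
    volume: LabelVolume,
    wavelength: float,
) -> float:
    """Spatially averaged effective attenuation (mm^-1) over breast tissue."""
    i = optical.index_of(wavelength)
    mua = optical.mua[i].astype(np.float64)
    mus_red = optical.mus[i].astype(np.float64) * (1.0 - optical.g.astype(np.float64))
    mueff = np.sqrt(3.0 * mua * (mua + mus_red))
    breast = volume.breast_mask()
    if not breast.any():
        raise EmptyVolumeError("volume contains no breast voxels")
    return float(mueff[breast].mean())


@dataclass
class EnsembleSummary:
    metric: str
    values: list[float]
    median: float
    q1: float
    q3: float


def ensemble_summary(values, metric: str = "") -> EnsembleSummary:
    """Median and quartiles by linear interpolation between order statistics."""
    values = [float(v) for v in values]
    if len(values) == 0:
        raise InvalidArgumentError("need at least one value")
    if not np.all(np.isfinite(values)):
        raise InvalidArgumentError("values must be finite")
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    return EnsembleSummary(metric=metric, values=values,
                           median=float(med), q1=float(q1), q3=float(q3))


def hemispherical_vessel_phantom(
    seed_seq: np.random.SeedSequence,
    breast_type: str = "A",
    voxel_size: float = 0.5,
    tree_config: VesselTreeConfig | None = None,
    subskin_params: SubskinParams | None = None,
) -> LabelVolume:
    """One hemispherical (cup-stabilized shape) phantom with full default
    vasculature: interior trees plus sub-skin vessels. Radius is drawn
    from the breast-type's a1t distribution."""
    s_shape, s_tree, s_sub = seed_seq.spawn(3)
    rng = np.random.default_rng(s_shape)
    radius = float(SHAPE_PARAM_TABLE["a1t"][breast_type].sample(rng))
    shape = ShapeParams.hemisphere(radius)
    vol = generate_fixture_anatomy(shape, breast_type, voxel_size, rng)
    vol = grow_vessel_trees(vol, tree_config, np.random.default_rng(s_tree))
    mask_no_skin = ~np.isin(
        vol.labels, np.array((L.WATER, L.SKIN, L.NIPPLE), dtype=np.uint8))
    params = subskin_params or SubskinParams()
    art, vein = generate_subskin_vessels(
        mask_no_skin, params, voxel_size, np.random.default_rng(s_sub))
    return embed_subskin_vessels(vol, art, vein)


def ensemble_vessel_volume_study(
    n_phantoms: int = 20,
    voxel_size: float = 0.5,
    seed: int = 0,
    breast_types=("A", "B", "C", "D"),
) -> EnsembleSummary:
    """Vessel volume percentage over an ensemble of hemispherical phantoms
    generated with default vessel parameters, cycling through the breast
    types."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_phantoms)
    values = []
    for i in range(n_phantoms):
        btype = breast_types[i % len(breast_types)]
        vol = hemispherical_vessel_phantom(children[i], breast_type=btype,
                                           voxel_size=voxel_size)
        values.append(vessel_volume_percentage(vol))
    return ensemble_summary(values, metric="vessel_volume_percentage")
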