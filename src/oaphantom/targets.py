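"""Reference measurements on canonical toy configurations.

These drive the quantitative self-checks that tie the generator back to
its published anchors: lesion shell thicknesses on a spherical toy
lesion, sub-skin vessel diameter at full resolution, the per-phantom
hemoglobin-concentration support, and the ensemble vessel-volume median.
Both the test suite and ``scripts/acceptance.py`` call these functions so
the numbers are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from . import labels as L
from .anatomy import ShapeParams, generate_fixture_anatomy
from .functional import sample_tissue_functionals
from .lesion import CORE_CODE, PA_CODE, VTC_CODE, add_necrosis_and_pa
from .subskin import SubskinParams, generate_subskin_vessels
from .validation import ensemble_vessel_volume_study

__all__ = [
    "spherical_lesion_thicknesses",
    "subskin_mean_diameter",
    "min_cthb_over_draws",
    "vessel_volume_median",
]


def _sphere_mask(radius_mm: float, voxel_size: float) -> np.ndarray:
    n = 2 * int(np.ceil(radius_mm / voxel_size)) + 5
    c = (n - 1) / 2.0
    g = (np.indices((n, n, n)) - c) * voxel_size
    return np.sqrt((g ** 2).sum(axis=0)) <= radius_mm


def spherical_lesion_thicknesses(
    radius_mm: float = 5.0,
    voxel_size: float = 0.125,
) -> tuple[float, float]:
    """(PA shell thickness, viable-ring thickness) in mm, measured by
    distance transform on a spherical toy VTC run through the default
    erosion/dilation morphology."""
    lp = add_necrosis_and_pa(_sphere_mask(radius_mm, voxel_size),
                             voxel_size=voxel_size)
    m = lp.mask
    vtc_all = (m == VTC_CODE) | (m == CORE_CODE)
    dist_out = ndimage.distance_transform_edt(~vtc_all, sampling=voxel_size)
    dist_in = ndimage.distance_transform_edt(vtc_all, sampling=voxel_size)
    pa_thickness = float(dist_out[m == PA_CODE].max())
    ring_thickness = float(dist_in[m == VTC_CODE].max())
    return pa_thickness, ring_thickness


def subskin_mean_diameter(
    n_seeds: int = 10,
    voxel_size: float = 0.125,
    fixture_radius: float = 12.0,
    seed: int = 0,
) -> float:
    """Mean sub-skin vessel diameter (mm): twice the mean distance-
    transform value at vessel-skeleton voxels, averaged over seeds, with
    the default thickness blur on a small hemispherical fixture."""
    root = np.random.SeedSequence(seed)
    fixture_rng = np.random.default_rng(root.spawn(1)[0])
    vol = generate_fixture_anatomy(ShapeParams.hemisphere(fixture_radius), "B",
                                   voxel_size, fixture_rng)
    mask = ~np.isin(vol.labels,
                    np.array((L.WATER, L.SKIN, L.NIPPLE), dtype=np.uint8))
    diameters = []
    for child in root.spawn(n_seeds + 1)[1:]:
        art, vein = generate_subskin_vessels(
            mask, SubskinParams(), voxel_size, np.random.default_rng(child))
        vessels = art | vein
        if not vessels.any():
            continue
        sk = skeletonize(vessels)
        dt = ndimage.distance_transform_edt(vessels, sampling=voxel_size)
        diameters.append(2.0 * float(dt[sk].mean()))
    return float(np.mean(diameters))


def min_cthb_over_draws(n_draws: int = 10_000, seed: int = 0) -> float:
    """Minimum per-phantom blood hemoglobin concentration (uM) over
    independently seeded functional draws."""
    root = np.random.SeedSequence(seed)
    lo = np.inf
    for child in root.spawn(n_draws):
        d = sample_tissue_functionals(np.random.default_rng(child))
        lo = min(lo, d["ctHb_blood"])
    return float(lo)


def vessel_volume_median(
    n_phantoms: int = 20,
    voxel_size: float = 0.5,
    seed: int = 0,
) -> float:
    """Ensemble median breast-volume percentage occupied by vessels."""
    return ensemble_vessel_volume_study(
        n_phantoms=n_phantoms, voxel_size=voxel_size, seed=seed).median
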