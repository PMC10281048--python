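"""Lesion morphology and insertion."""

import numpy as np
import pytest
from scipy import ndimage

import oaphantom as oa
from oaphantom import labels as L
from oaphantom.errors import (
    InvalidArgumentError,
    PlacementConflictError,
    PlacementFailureError,
)
from oaphantom.lesion import (
    CORE_CODE,
    PA_CODE,
    VTC_CODE,
    _feret_diameter,
)


def _sphere(radius_mm, h):
    n = 2 * int(np.ceil(radius_mm / h)) + 5
    c = (n - 1) / 2.0
    g = (np.indices((n, n, n)) - c) * h
    return np.sqrt((g ** 2).sum(axis=0)) <= radius_mm


def test_zero_irregularity_gives_sphere(rng):
    m = oa.generate_vtc_mask(8.0, 0.0, 0.5, rng)
    n = m.shape[0]
    c = (n - 1) / 2.0
    g = (np.indices(m.shape) - c) * 0.5
    r = np.sqrt((g ** 2).sum(axis=0))
    assert np.array_equal(m, r <= 4.0)


def test_small_diameter_rejected(rng):
    with pytest.raises(InvalidArgumentError):
        oa.generate_vtc_mask(1.0, 0.5, 0.5, rng)


def test_vtc_mask_connected_and_sized():
    """Irregular masks stay single-component with Feret extent within 10%
    of the requested diameter."""
    for seed in range(12):
        m = oa.generate_vtc_mask(8.0, 0.7, 0.5, np.random.default_rng(seed))
        _, n_comp = ndimage.label(m)
        assert n_comp == 1
        feret = _feret_diameter(m, 0.5)
        assert abs(feret - 8.0) / 8.0 < 0.10


def test_sphere_morphology_radii():
    """Spherical VTC of radius 5 mm: core radius 4.25 mm, viable ring
    0.75 mm, PA shell 5 mm, all within one voxel."""
    h = 0.25
    lp = oa.add_necrosis_and_pa(_sphere(5.0, h), voxel_size=h)
    m = lp.mask
    vtc_all = (m == VTC_CODE) | (m == CORE_CODE)
    din = ndimage.distance_transform_edt(vtc_all, sampling=h)
    dout = ndimage.distance_transform_edt(~vtc_all, sampling=h)
    core_radius = ndimage.distance_transform_edt(m == CORE_CODE, sampling=h).max()
    assert abs(core_radius - 4.25) <= h + 1e-9
    assert abs(din[m == VTC_CODE].max() - 0.75) <= h + 1e-9
    assert abs(dout[m == PA_CODE].max() - 5.0) <= h + 1e-9
    assert lp.has_core_and_pa


def test_small_vtc_has_empty_core(rng):
    """A VTC no larger than the erosion element is entirely viable tumor."""
    h = 0.25
    lp = oa.add_necrosis_and_pa(_sphere(0.6, h), voxel_size=h)
    assert (lp.mask == CORE_CODE).sum() == 0
    assert (lp.mask == VTC_CODE).sum() > 0


def test_pa_count_is_exact_set_difference():
    h = 0.25
    vtc = _sphere(3.0, h)
    lp = oa.add_necrosis_and_pa(vtc, voxel_size=h)
    vtc_all = (lp.mask == VTC_CODE) | (lp.mask == CORE_CODE)
    dout = ndimage.distance_transform_edt(~vtc_all, sampling=h)
    dilated = vtc_all | (dout <= 5.0)
    assert (lp.mask == PA_CODE).sum() == dilated.sum() - vtc_all.sum()


def test_erosion_dilation_duality():
    """Re-deriving the ring from core+ring reproduces the original
    partition (erode-then-subtract is consistent with the stored codes)."""
    h = 0.25
    vtc = _sphere(4.0, h)
    lp = oa.add_necrosis_and_pa(vtc, voxel_size=h)
    vtc_all = (lp.mask == VTC_CODE) | (lp.mask == CORE_CODE)
    din = ndimage.distance_transform_edt(vtc_all, sampling=h)
    core = din > 0.75
    assert np.array_equal(core, lp.mask == CORE_CODE)
    assert np.array_equal(vtc_all & ~core, lp.mask == VTC_CODE)


def test_empty_vtc_rejected():
    with pytest.raises(InvalidArgumentError):
        oa.add_necrosis_and_pa(np.zeros((5, 5, 5), bool))


# --- insertion -------------------------------------------------------------

def test_zero_lesions_empty_sites(small_volume, rng):
    assert oa.select_insertion_sites(small_volume, 0, [], rng) == []


def test_sites_carry_candidate_labels(small_volume, rng):
    sites = oa.select_insertion_sites(small_volume, 2, [4.0, 4.0], rng)
    for s in sites:
        assert small_volume.labels[s] in (L.TDLU, L.DUCT)


def test_four_small_lesions_do_not_overlap(small_volume):
    """Four lesions under 10 mm: pairwise center distances exceed the sum
    of bounding radii."""
    extents = [9.0, 8.0, 6.0, 4.0]
    sites = oa.select_insertion_sites(small_volume, 4, extents,
                                      np.random.default_rng(21))
    radii = sorted((e / 2 for e in extents), reverse=True)
    h = small_volume.voxel_size
    for i in range(4):
        for j in range(i + 1, 4):
            d = np.linalg.norm((np.array(sites[i]) - np.array(sites[j])) * h)
            assert d > radii[i] + radii[j]


def test_pool_exhaustion_reports_progress(small_volume, rng):
    with pytest.raises(PlacementFailureError) as exc:
        oa.select_insertion_sites(small_volume, 50, [30.0] * 50, rng)
    assert exc.value.requested == 50


def test_insert_conserves_counts_and_underlying(lesioned_volume, small_volume):
    les_counts = {c: int((lesioned_volume.labels == c).sum())
                  for c in (L.VTC, L.NECROTIC_CORE, L.PA)}
    manifest = lesioned_volume.meta["lesions"][0]
    assert les_counts[L.PA] == manifest["counts"].get(PA_CODE, 0)
    assert les_counts[L.VTC] == manifest["counts"].get(VTC_CODE, 0)
    assert les_counts[L.NECROTIC_CORE] == manifest["counts"].get(CORE_CODE, 0)
    # PA underlying-tissue memory equals the pre-insertion labels
    pa_vox = lesioned_volume.labels == L.PA
    under = lesioned_volume.meta["pa_underlying"]
    assert np.array_equal(under[pa_vox], small_volume.labels[pa_vox])
    assert set(np.unique(under[pa_vox])) <= set(L.LESION_OVERWRITABLE)


def test_insert_on_skin_conflicts(small_volume, rng):
    lesion = oa.add_necrosis_and_pa(_sphere(2.0, 0.5), voxel_size=0.5)
    skin_site = tuple(np.argwhere(small_volume.labels == L.SKIN)[0])
    with pytest.raises(PlacementConflictError):
        oa.insert_lesion(small_volume, lesion, skin_site)


def test_no_lesion_voxel_outside_breast(lesioned_volume):
    lesion_vox = np.isin(lesioned_volume.labels,
                         np.array(L.LESION_CODES, dtype=np.uint8))
    assert not (lesion_vox & (lesioned_volume.labels == L.WATER)).any()
    # every lesion voxel replaced interior tissue, so none on the old shell
    assert not np.isin(lesioned_volume.labels[lesion_vox],
                       (L.SKIN, L.NIPPLE)).any()
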