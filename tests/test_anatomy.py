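"""Anatomy: shape sampling, fixture generation, vessel tree growth."""

import math

import numpy as np
import pytest
from scipy import ndimage

import oaphantom as oa
from oaphantom import labels as L
from oaphantom.anatomy import (
    DEFAULT_ENTRIES,
    SHAPE_PARAM_TABLE,
    VesselTreeConfig,
    vessel_entry_point,
)
from oaphantom.errors import InvalidArgumentError


def test_unknown_breast_type_rejected():
    with pytest.raises(InvalidArgumentError):
        oa.sample_shape_params("E", np.random.default_rng(0))


def test_shape_params_supports():
    """a1t always falls in its truncated support; extents stay positive."""
    rng = np.random.default_rng(3)
    for _ in range(300):
        p = oa.sample_shape_params("A", rng)
        assert 50.77 <= p.a1t <= 71.5
        assert min(p.a1b, p.a2l, p.a2r, p.a3) > 0
    spec = SHAPE_PARAM_TABLE["a1t"]["C"]
    for _ in range(300):
        p = oa.sample_shape_params("D", rng)
        assert spec.low <= p.a1t <= spec.high


def test_degenerate_extents_rejected():
    with pytest.raises(InvalidArgumentError):
        oa.ShapeParams(-1, 50, 50, 50, 40)


def test_fixture_labels_all_known(small_volume):
    small_volume.validate()
    counts = small_volume.counts()
    # all structural tissues present
    for code in (L.WATER, L.FAT, L.SKIN, L.GLANDULAR, L.NIPPLE, L.TDLU):
        assert counts.get(code, 0) > 0, L.LABEL_TABLE[code]


def test_fixture_volume_matches_analytic_half_ellipsoid():
    """Voxel count of a pure half-ellipsoid fixture is within 2% of
    (pi/6) * a3 * (a2l + a2r) * (a1t + a1b)."""
    shape = oa.ShapeParams(a1t=18, a1b=16, a2l=17, a2r=15, a3=14)
    vol = oa.generate_fixture_anatomy(shape, "B", 0.4, np.random.default_rng(0))
    n_inside = int((vol.labels != L.WATER).sum())
    analytic = (math.pi / 6) * shape.a3 * (shape.a2l + shape.a2r) \
        * (shape.a1t + shape.a1b)
    assert abs(n_inside * 0.4 ** 3 - analytic) / analytic < 0.02


def test_skin_forms_closed_shell(small_volume):
    """Water flood-filled from the boundary never reaches interior tissue
    without crossing the skin/nipple shell."""
    lab = small_volume.labels
    passable = ~np.isin(lab, np.array((L.SKIN, L.NIPPLE), dtype=np.uint8))
    seed = np.zeros_like(passable)
    seed[0, 0, 0] = True
    assert lab[0, 0, 0] == L.WATER
    reached = ndimage.binary_propagation(seed, mask=passable)
    interior = ~np.isin(lab, np.array((L.WATER, L.SKIN, L.NIPPLE),
                                      dtype=np.uint8))
    assert not (reached & interior).any()


def test_fixture_determinism():
    shape = oa.ShapeParams.hemisphere(12.0)
    a = oa.generate_fixture_anatomy(shape, "C", 0.5, np.random.default_rng(9))
    b = oa.generate_fixture_anatomy(shape, "C", 0.5, np.random.default_rng(9))
    assert np.array_equal(a.labels, b.labels)


# --- vessel trees ----------------------------------------------------------

def test_max_branch_zero_only_root_seeds(small_volume):
    cfg = VesselTreeConfig(max_branch=0)
    out = oa.grow_vessel_trees(small_volume, cfg, np.random.default_rng(0))
    changed = out.labels != small_volume.labels
    # only small root seed blobs appear
    n_roots = len(out.meta["vessel_trees"])
    assert n_roots > 0
    assert 0 < int(changed.sum()) <= n_roots * 30
    for tree in out.meta["vessel_trees"]:
        assert tree["segments"] == []


def test_trees_never_touch_protected_tissue(small_volume):
    out = oa.grow_vessel_trees(small_volume, None, np.random.default_rng(1))
    for code in (L.SKIN, L.NIPPLE, L.WATER):
        assert np.array_equal(out.labels == code, small_volume.labels == code)


def test_tree_radii_taper_and_bound(small_volume):
    """Along any root-to-leaf path radii never increase, and every segment
    radius respects the minRadFrac^depth lower bound."""
    cfg = VesselTreeConfig()
    out = oa.grow_vessel_trees(small_volume, cfg, np.random.default_rng(2))
    n_segments = 0
    for tree in out.meta["vessel_trees"]:
        for (p0, p1, r_start, r_end, depth) in tree["segments"]:
            n_segments += 1
            assert r_end <= r_start + 1e-12
            assert r_start >= cfg.min_rad_frac ** depth * cfg.init_rad - 1e-9
    assert n_segments > 0


def test_tree_determinism(small_volume):
    a = oa.grow_vessel_trees(small_volume, None, np.random.default_rng(5))
    b = oa.grow_vessel_trees(small_volume, None, np.random.default_rng(5))
    assert np.array_equal(a.labels, b.labels)


def test_internal_mammary_entry_geometry(small_volume):
    """The internal-mammary artery root (theta = 11pi/15, d_edge = 2 mm)
    sits ~2 mm inside the breast edge at the requested polar angle."""
    theta = 11 * math.pi / 15
    root = vessel_entry_point(small_volume, theta, 2.0)
    assert root is not None
    lab = small_volume.labels
    h = small_volume.voxel_size
    # distance from the root to the breast edge within its chest-wall slice
    sl_inside = lab[root[0]] != L.WATER
    assert sl_inside[root[1], root[2]]
    dist = ndimage.distance_transform_edt(sl_inside, sampling=h)
    assert abs(dist[root[1], root[2]] - 2.0) <= 1.5 * h
    # azimuth of the root about the slice centroid matches theta
    idx = np.argwhere(sl_inside)
    cy, cz = idx.mean(axis=0)
    phi = math.atan2(root[1] - cy, root[2] - cz)
    assert abs(phi - theta) < 0.15


def test_entry_outside_breast_skipped(caplog):
    """Intercostal entries (d_edge = 24 mm) cannot fit in a 15 mm fixture
    and are skipped with a warning rather than failing."""
    import logging

    vol = oa.generate_fixture_anatomy(oa.ShapeParams.hemisphere(15.0), "B",
                                      1.0, np.random.default_rng(0))
    with caplog.at_level(logging.WARNING):
        out = oa.grow_vessel_trees(vol, None, np.random.default_rng(0))
    names = {t["name"] for t in out.meta["vessel_trees"]}
    assert "intercostal" not in names
    assert any("skipped" in r.message for r in caplog.records)


def test_default_entries_cover_five_vessel_sets():
    names = {e.name for e in DEFAULT_ENTRIES}
    assert names == {"internal_mammary", "thoraco_acromial", "lateral_thoracic",
                     "subscapular_thoraco_dorsal", "intercostal"}
    assert sum(1 for e in DEFAULT_ENTRIES if e.code == L.ARTERY) == 7
    assert sum(1 for e in DEFAULT_ENTRIES if e.code == L.VEIN) == 7
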