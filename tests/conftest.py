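"""Shared fixtures: small phantoms generated programmatically at test time."""

import numpy as np
import pytest

import oaphantom as oa
from oaphantom import labels as L


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_volume():
    """A small hemispherical type-C fixture at 0.5 mm voxels."""
    rng = np.random.default_rng(7)
    shape = oa.ShapeParams.hemisphere(25.0)
    return oa.generate_fixture_anatomy(shape, "C", 0.5, rng)


@pytest.fixture(scope="session")
def lesioned_volume(small_volume):
    """Small volume with one core+PA lesion inserted near the center."""
    rng = np.random.default_rng(11)
    vtc = oa.generate_vtc_mask(5.0, 0.0, 0.5, rng)  # 5 mm sphere
    lesion = oa.add_necrosis_and_pa(vtc, voxel_size=0.5)
    sites = oa.select_insertion_sites(
        small_volume, 1, [lesion.nominal_diameter + 10.0], rng)
    return oa.insert_lesion(small_volume, lesion, sites[0])


@pytest.fixture(scope="session")
def lesioned_functional(lesioned_volume):
    return oa.assemble_functional_maps(lesioned_volume, np.random.default_rng(5))


def breast_interior_mask(volume):
    return ~np.isin(volume.labels,
                    np.array((L.WATER, L.SKIN, L.NIPPLE), dtype=np.uint8))
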