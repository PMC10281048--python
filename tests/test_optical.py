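"""Optical property computation: absorption mixing, scattering power law,
joint sampling, and map assembly."""

import math

import numpy as np
import pytest
from scipy import stats

import oaphantom as oa
from oaphantom import labels as L
from oaphantom.errors import InvalidArgumentError
from oaphantom.functional import FunctionalMaps
from oaphantom.optical import (
    LAMBDA_REF,
    OPTICAL_TABLE,
    compute_mua,
    compute_mus,
    fit_water_scattering,
    sample_scattering_params,
)
from oaphantom.spectra import DEFAULT_CHROMOPHORES


def _uniform_functional(s, fb, fw, ff, fm, cthb=2000.0, shape=(2, 2, 2)):
    full = lambda v: np.full(shape, v, dtype=np.float32)
    return FunctionalMaps(s=full(s), fb=full(fb), fw=full(fw), ff=full(ff),
                          fm=full(fm), ctHb_blood=cthb)


def test_zero_fractions_zero_absorption():
    f = _uniform_functional(50, 0, 0, 0, 0)
    assert np.all(compute_mua(f, DEFAULT_CHROMOPHORES, 800.0) == 0)


def test_pure_water_voxel():
    f = _uniform_functional(0, 0, 100, 0, 0)
    mua = compute_mua(f, DEFAULT_CHROMOPHORES, 800.0)
    assert mua.flat[0] == pytest.approx(
        DEFAULT_CHROMOPHORES.mua_water_at(800.0), rel=1e-6)


def test_artery_voxel_against_scalar_oracle():
    """Blood-only voxel at 800 nm matches an independent scalar evaluation
    of the chromophore-mixing formula with the same embedded table."""
    t = DEFAULT_CHROMOPHORES
    f = _uniform_functional(97.0, 100.0, 0, 0, 0, cthb=2000.0)
    mua = compute_mua(f, t, 800.0)
    expected = math.log(10) * 2000e-6 * (
        0.97 * t.eps_hbo2_at(800.0) + 0.03 * t.eps_hb_at(800.0))
    assert mua.flat[0] == pytest.approx(expected, rel=1e-6)


def test_absorption_superposition():
    """mua of a mixed voxel equals the sum over single-chromophore voxels."""
    t = DEFAULT_CHROMOPHORES
    mixed = _uniform_functional(80.0, 2.0, 30.0, 60.0, 0.5)
    total = compute_mua(mixed, t, 757.0).flat[0]
    parts = [
        compute_mua(_uniform_functional(80.0, 2.0, 0, 0, 0), t, 757.0),
        compute_mua(_uniform_functional(0.0, 0.0, 30.0, 0, 0), t, 757.0),
        compute_mua(_uniform_functional(0.0, 0.0, 0, 60.0, 0), t, 757.0),
        compute_mua(_uniform_functional(0.0, 0.0, 0, 0, 0.5), t, 757.0),
    ]
    assert total == pytest.approx(sum(p.flat[0] for p in parts), rel=1e-5)


def test_wavelength_out_of_range():
    f = _uniform_functional(50, 1, 30, 60, 0)
    with pytest.raises(InvalidArgumentError):
        compute_mua(f, DEFAULT_CHROMOPHORES, 650.0)


def test_isosbestic_point_near_800nm():
    """Around 800 nm the embedded oxy/deoxy extinctions nearly coincide,
    so blood absorption is insensitive to s there (reported tolerance,
    not a hard physical identity of the digitized table)."""
    t = DEFAULT_CHROMOPHORES
    rel = abs(t.eps_hbo2_at(800.0) - t.eps_hb_at(800.0)) / t.eps_hbo2_at(800.0)
    assert rel < 0.15


# --- scattering ------------------------------------------------------------

def test_mus_at_reference_wavelength():
    assert compute_mus(2.0, 1.3, 0.9, LAMBDA_REF) == pytest.approx(2.0 / 0.1)


def test_mus_b_zero_wavelength_independent():
    assert compute_mus(1.0, 0.0, 0.5, 700.0) == compute_mus(1.0, 0.0, 0.5, 1100.0)


def test_fat_mus_closed_form():
    expected = 0.83 / (1 - 0.98) * (800.0 / 500.0) ** (-0.617)
    assert compute_mus(0.83, 0.617, 0.98, 800.0) == pytest.approx(expected)


def test_mus_monotone_decreasing_for_positive_b():
    wl = np.linspace(700, 1100, 20)
    vals = [compute_mus(2.0, 1.0, 0.9, w) for w in wl]
    assert np.all(np.diff(vals) < 0)


def test_invalid_g_rejected():
    with pytest.raises(InvalidArgumentError):
        compute_mus(1.0, 1.0, 1.0, 800.0)


def test_fixed_tissues_deterministic():
    rng = np.random.default_rng(0)
    for _ in range(5):
        assert sample_scattering_params(OPTICAL_TABLE["fat"], rng) \
            == (0.83, 0.617)
        assert sample_scattering_params(OPTICAL_TABLE["glandular"], rng) \
            == (1.06, 0.52)


def test_joint_sampling_endpoints_and_correlation():
    """X=0/1 map to the interval endpoints; over many draws the rank
    correlation between mus'_ref and b is exactly 1 (one shared X)."""
    spec = OPTICAL_TABLE["skin"]

    class EndpointRng:
        def __init__(self, v):
            self.v = v

        def uniform(self):
            return self.v

    assert sample_scattering_params(spec, EndpointRng(0.0)) == (3.72, 1.39)
    assert sample_scattering_params(spec, EndpointRng(1.0)) == (4.78, 2.453)

    rng = np.random.default_rng(8)
    draws = [sample_scattering_params(spec, rng) for _ in range(2000)]
    mus_ref, b = zip(*draws)
    rho = stats.spearmanr(mus_ref, b).statistic
    assert rho == pytest.approx(1.0)
    assert min(mus_ref) >= 3.72 and max(mus_ref) <= 4.78


def test_water_scattering_fit_recovers_power_law():
    mus_ref, b = fit_water_scattering()
    assert b == pytest.approx(4.32, rel=1e-3)
    assert mus_ref == pytest.approx(2.9e-6, rel=1e-3)


# --- assembly --------------------------------------------------------------

def test_assembled_maps_piecewise_and_pa_inheritance(lesioned_volume,
                                                     lesioned_functional):
    om = oa.assemble_optical_maps(lesioned_volume, lesioned_functional,
                                  [757, 800, 850], np.random.default_rng(2))
    lab = lesioned_volume.labels
    vtc = lab == L.VTC
    assert np.all(om.g[vtc] == np.float32(0.955))
    assert np.all(om.n[vtc] == np.float32(1.39))
    # PA voxels inherit their recorded underlying tissue, never VTC optics
    pa = lab == L.PA
    under = lesioned_volume.meta["pa_underlying"]
    pa_over_gland = pa & (under == L.GLANDULAR)
    if pa_over_gland.any():
        assert np.all(om.g[pa_over_gland] == np.float32(0.96))
        assert np.all(om.n[pa_over_gland] == np.float32(1.36))
    pa_over_fat = pa & np.isin(under, (L.FAT, L.LIGAMENT, L.TDLU, L.DUCT))
    if pa_over_fat.any():
        assert np.all(om.g[pa_over_fat] == np.float32(0.98))
    assert not np.any(om.g[pa] == np.float32(0.955))
    # mus decreases with wavelength (b > 0 for every tissue)
    breast = lesioned_volume.breast_mask()
    assert np.all(om.mus[0][breast] > om.mus[2][breast])
    assert np.all(om.mua[0][breast] >= 0)


def test_vtc_scattering_draws_within_printed_range():
    rng = np.random.default_rng(0)
    draws = np.array([sample_scattering_params(OPTICAL_TABLE["VTC"], rng)
                      for _ in range(10_000)])
    assert draws[:, 0].min() >= 2.0 and draws[:, 0].max() <= 2.07
    assert 2.0 <= draws[:, 0].mean() <= 2.07
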