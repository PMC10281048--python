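"""Functional property draws and the diffusion-reaction solves."""

import numpy as np
import pytest

import oaphantom as oa
from oaphantom import labels as L
from oaphantom.errors import NoIndicatorError
from oaphantom.functional import (
    DEFAULT_MU,
    ReactionDiffusionProblem,
    sample_tissue_functionals,
    solve_reaction_diffusion,
)


def test_fixed_targets_are_exact(rng):
    d = sample_tissue_functionals(rng)
    assert d["skin"]["s"] == 98.9
    assert d["nipple"]["s"] == 71.28
    assert d["artery"]["fb"] == 100.0
    assert d["vein"]["fb"] == 100.0
    assert d["necrotic_core"]["fb"] == 0.0
    assert d["skin"]["fb"] == 0.39
    assert d["nipple"]["fb"] == 1.35


def test_tie_rules(rng):
    d = sample_tissue_functionals(rng)
    assert d["glandular"]["fb"] == d["fat"]["fb"]
    assert d["glandular"]["fw"] == d["fat"]["fw"]
    assert d["glandular"]["ff"] == 0.0
    assert d["necrotic_core"]["s"] == d["VTC"]["s"]
    assert d["necrotic_core"]["fw"] == d["VTC"]["fw"]
    assert d["PA"]["fw"] == d["VTC"]["fw"]
    # complements are exact
    assert d["fat"]["fb"] + d["fat"]["fw"] + d["fat"]["ff"] == pytest.approx(100)
    assert sum(d["nipple"][f] for f in ("fb", "fw", "ff", "fm")) \
        == pytest.approx(100)


def test_draw_supports_over_many_phantoms():
    """Sampled quantities respect their printed supports over 10^4 draws."""
    rng = np.random.default_rng(99)
    lo_cthb = np.inf
    for _ in range(10_000):
        d = sample_tissue_functionals(rng)
        lo_cthb = min(lo_cthb, d["ctHb_blood"])
        assert 1860.0 <= d["ctHb_blood"] <= 2325.0
        assert 0.91 <= d["fat"]["fb"] <= 1.43
        assert 95.0 <= d["artery"]["s"] <= 99.0
        assert 75.0 <= d["vein"]["s"] <= 84.0
        assert 0.44 <= d["skin"]["fm"] <= 0.84
    assert lo_cthb >= 1860.0


def _toy_volume(labels_arr, h=1.0):
    return oa.LabelVolume(h, (0, 0, 0), labels_arr)


def test_constant_solution_for_single_indicator():
    lab = np.full((6, 6, 6), L.FAT, dtype=np.uint8)
    vol = _toy_volume(lab)
    p = ReactionDiffusionProblem(targets={L.FAT: 42.0})
    u = solve_reaction_diffusion(p, vol)
    assert np.allclose(u, 42.0, atol=1e-6)


def test_equal_targets_give_constant():
    lab = np.full((6, 6, 6), L.FAT, dtype=np.uint8)
    lab[3:] = L.GLANDULAR
    vol = _toy_volume(lab)
    p = ReactionDiffusionProblem(targets={L.FAT: 7.5, L.GLANDULAR: 7.5})
    u = solve_reaction_diffusion(p, vol)
    assert np.allclose(u, 7.5, atol=1e-6)


def test_no_indicator_raises():
    lab = np.full((4, 4, 4), L.FAT, dtype=np.uint8)
    with pytest.raises(NoIndicatorError):
        solve_reaction_diffusion(
            ReactionDiffusionProblem(targets={L.VTC: 1.0}), _toy_volume(lab))


def _dense_reference(lab, domain, targets, mu, h):
    """Independent dense assembly of the same discrete operator, solved
    with numpy; used as the oracle for the sparse path."""
    idx = -np.ones(lab.shape, dtype=int)
    coords = np.argwhere(domain)
    for k, c in enumerate(coords):
        idx[tuple(c)] = k
    n = len(coords)
    A = np.zeros((n, n))
    b = np.zeros(n)
    k_diff = mu / h ** 2
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
               (0, 0, -1)]
    for k, c in enumerate(coords):
        code = lab[tuple(c)]
        if int(code) in targets:
            A[k, k] += 1.0
            b[k] += targets[int(code)]
        for off in offsets:
            nb = c + off
            if (nb < 0).any() or (nb >= np.array(lab.shape)).any():
                continue
            j = idx[tuple(nb)]
            if j < 0:
                continue
            A[k, k] += k_diff
            A[k, j] -= k_diff
    return idx, np.linalg.solve(A, b)


def test_solution_matches_dense_solve():
    """Two-slab configuration: sparse CG equals an independent dense solve
    and interpolates monotonically between the two targets."""
    rng = np.random.default_rng(4)
    lab = np.full((12, 5, 5), L.FAT, dtype=np.uint8)
    lab[:2] = L.ARTERY
    lab[-2:] = L.VEIN
    vol = _toy_volume(lab)
    targets = {int(L.ARTERY): 95.0, int(L.VEIN): 75.0}
    p = ReactionDiffusionProblem(mu=DEFAULT_MU, targets=targets, tol=1e-10)
    u = solve_reaction_diffusion(p, vol)
    domain = np.ones(lab.shape, dtype=bool)
    idx, ref = _dense_reference(lab, domain, targets, DEFAULT_MU, 1.0)
    assert np.allclose(u[domain], ref[idx[domain]], atol=1e-6)
    # monotone decay along the slab between the two targets
    profile = u[:, 2, 2]
    assert np.all(np.diff(profile) <= 1e-9)
    assert profile.min() >= 75.0 - 1e-9 and profile.max() <= 95.0 + 1e-9


def test_maximum_principle_on_phantom(lesioned_volume, lesioned_functional):
    d = lesioned_functional.draws
    s = lesioned_functional.s
    breast = lesioned_volume.breast_mask()
    lo = min(d["vein"]["s"], d["VTC"]["s"], d["nipple"]["s"])
    hi = max(d["artery"]["s"], d["skin"]["s"])
    assert s[breast].min() >= lo - 1e-4
    assert s[breast].max() <= hi + 1e-4


def test_tumor_hypoxia_minimum_near_lesion(lesioned_volume, lesioned_functional):
    """With a clearly hypoxic lesion draw (s = 65%, inside its support),
    the s minimum over the breast occurs in or adjacent to the lesion."""
    import copy

    from scipy import ndimage

    d = copy.deepcopy(lesioned_functional.draws)
    d["VTC"]["s"] = 65.0
    d["necrotic_core"]["s"] = 65.0
    s = oa.functional.assign_oxygen_saturation(lesioned_volume, d)
    lab = lesioned_volume.labels
    breast = lesioned_volume.breast_mask()
    s_masked = np.where(breast, s.astype(float), np.inf)
    argmin = np.unravel_index(np.argmin(s_masked), s.shape)
    lesion = np.isin(lab, np.array(L.LESION_CODES, dtype=np.uint8))
    near_lesion = ndimage.binary_dilation(lesion, iterations=3)
    assert near_lesion[argmin]
    # lesion tissue is hypoxic relative to healthy glandular tissue
    assert s[lab == L.VTC].mean() < s[lab == L.GLANDULAR].mean()


def test_smoothing_increases_with_mu(lesioned_volume, lesioned_functional):
    """Doubling mu strictly reduces the variance of s over PDE voxels."""
    d = lesioned_functional.draws
    lab = lesioned_volume.labels
    pde_voxels = np.isin(lab, np.array(
        (L.FAT, L.LIGAMENT, L.TDLU, L.DUCT, L.GLANDULAR, L.PA),
        dtype=np.uint8))
    s2 = oa.functional.assign_oxygen_saturation(lesioned_volume, d,
                                                mu=2 * DEFAULT_MU)
    var1 = float(np.var(lesioned_functional.s[pde_voxels]))
    var2 = float(np.var(s2[pde_voxels]))
    assert var2 < var1


def test_pa_blood_fraction_elevated(lesioned_volume, lesioned_functional):
    """Angiogenesis: with a vascularized lesion draw (VTC fb above the fat
    level, inside its support), the indicator-free PA shell interpolates
    strictly between the two — locally elevated fb around the lesion."""
    import copy

    d = copy.deepcopy(lesioned_functional.draws)
    d["VTC"]["fb"] = 2.5
    lab = lesioned_volume.labels
    fb = oa.functional.assign_blood_volume_fraction(lesioned_volume, d)
    fb_pa = fb[lab == L.PA]
    assert fb_pa.mean() > d["fat"]["fb"]
    assert fb_pa.max() <= d["VTC"]["fb"] + 1e-4


def test_fraction_budget_everywhere(lesioned_functional):
    assert float(lesioned_functional.budget().max()) <= 100.0 + 1e-3


def test_functional_determinism(lesioned_volume):
    a = oa.assemble_functional_maps(lesioned_volume, np.random.default_rng(5))
    b = oa.assemble_functional_maps(lesioned_volume, np.random.default_rng(5))
    assert np.array_equal(a.s, b.s) and np.array_equal(a.fb, b.fb)
    assert a.ctHb_blood == b.ctHb_blood
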