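"""Stochastic assignment of functional tissue properties.

Per phantom, each tissue draws one set of functional values: oxygen
saturation s (%), and volume fractions of blood fb, water fw, fat ff, and
melanosome fm (%), plus a per-phantom total hemoglobin concentration of
blood ctHb,blood (uM) drawn from U(1860, 2325), the range corresponding
to a normal female hematocrit. The fraction budget fb+fw+ff+fm never
exceeds 100% in any voxel; complements enforce exact budgets where the
property table prescribes them.

Oxygen diffuses from vessels and skin through the surrounding tissue, so
s is not piecewise constant: it solves the steady diffusion-reaction
equation

    -mu * Laplacian(u) + sum_i chi_i (u - target_i) = 0

with zero-flux boundaries on the breast surface, where chi_i is the 0/1
indicator of tissue i and target_i its sampled value. The same equation
smooths the blood volume fraction so the peripheral-angiogenesis shell
(which carries no indicator) interpolates between the elevated lesion
target and the surrounding tissue, emulating capillaries too fine to
resolve on the grid. mu (mm^2) sets the transition length ~sqrt(mu); the
default of 4 mm^2 gives ~2 mm transitions.

Discretization is a 7-point finite-difference Laplacian restricted to the
breast interior (reflecting/Neumann boundaries arise by dropping exterior
links), solved with conjugate gradients; the system is symmetric positive
definite whenever every connected component contains an indicator voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg

from . import labels as L
from .anatomy import LabelVolume
from .errors import InfeasibleDrawError, NoIndicatorError
from .sampling import FixedSpec, TruncatedGaussianSpec, UniformSpec

__all__ = [
    "FunctionalMaps",
    "ReactionDiffusionProblem",
    "FUNCTIONAL_TABLE",
    "CTHB_BLOOD_SPEC",
    "DEFAULT_MU",
    "sample_tissue_functionals",
    "solve_reaction_diffusion",
    "assign_oxygen_saturation",
    "assign_blood_volume_fraction",
    "assign_piecewise_fractions",
    "assemble_functional_maps",
]

DEFAULT_MU = 4.0  # mm^2 -> ~2 mm transition length
PDE = None  # sentinel: this entry is produced by the PDE solve, not a draw

#: Per-tissue distribution table for s, fb, fw, ff, fm (all percent).
#: Entries may be distribution specs, the PDE sentinel, or callables
#: receiving the dict of already-drawn tissues (complement/tie rules).
FUNCTIONAL_TABLE: dict[str, dict] = {
    "fat": {  # shared by fat / ligament / TDLU / duct
        "s": PDE,
        "fb": TruncatedGaussianSpec(1.15, 0.22, 0.91, 1.43),
        "fw": TruncatedGaussianSpec(29.17, 13.11, 14, 40),
        "ff": lambda d: 100.0 - (d["fat"]["fb"] + d["fat"]["fw"]),
        "fm": FixedSpec(0.0),
    },
    "glandular": {
        "s": PDE,
        "fb": lambda d: d["fat"]["fb"],
        "fw": lambda d: d["fat"]["fw"],
        "ff": FixedSpec(0.0),
        "fm": FixedSpec(0.0),
    },
    "skin": {
        "s": FixedSpec(98.9),
        "fb": FixedSpec(0.39),
        "fw": TruncatedGaussianSpec(18.68, 1.34, 12, 25),
        "ff": TruncatedGaussianSpec(30.72, 3.79, 12, 48),
        "fm": TruncatedGaussianSpec(0.64, 0.04, 0.44, 0.84),
    },
    "nipple": {
        "s": FixedSpec(71.28),
        "fb": FixedSpec(1.35),
        "fw": TruncatedGaussianSpec(45.4, 11.7, 25.1, 76.6),
        "ff": lambda d: 100.0 - (d["nipple"]["fb"] + d["nipple"]["fw"]
                                 + d["nipple"]["fm"]),
        "fm": TruncatedGaussianSpec(0.82, 0.09, 0.4, 1.24),
    },
    "artery": {
        "s": UniformSpec(95, 99),
        "fb": FixedSpec(100.0),
        "fw": FixedSpec(0.0),
        "ff": FixedSpec(0.0),
        "fm": FixedSpec(0.0),
    },
    "vein": {
        "s": UniformSpec(75, 84),
        "fb": lambda d: d["artery"]["fb"],
        "fw": FixedSpec(0.0),
        "ff": FixedSpec(0.0),
        "fm": FixedSpec(0.0),
    },
    "VTC": {
        "s": TruncatedGaussianSpec(69.91, 4.99, 62.5, 76.49),
        "fb": TruncatedGaussianSpec(1.64, 0.6, 0.89, 2.93),
        "fw": TruncatedGaussianSpec(47.67, 20.15, 24.14, 82.25),
        "ff": lambda d: 100.0 - (d["VTC"]["fb"] + d["VTC"]["fw"]),
        "fm": FixedSpec(0.0),
    },
    "necrotic_core": {
        "s": lambda d: d["VTC"]["s"],
        "fb": FixedSpec(0.0),
        "fw": lambda d: d["VTC"]["fw"],
        "ff": lambda d: d["VTC"]["ff"],
        "fm": FixedSpec(0.0),
    },
    "PA": {
        "s": PDE,
        "fb": PDE,
        "fw": lambda d: d["VTC"]["fw"],
        "ff": lambda d: d["VTC"]["ff"],
        "fm": FixedSpec(0.0),
    },
}

CTHB_BLOOD_SPEC = UniformSpec(1860.0, 2325.0)

# draw order fixed for reproducibility; complements resolved afterwards
_DRAW_ORDER = ("fat", "glandular", "skin", "nipple", "artery", "vein",
               "VTC", "necrotic_core", "PA")
_FIELDS = ("s", "fb", "fw", "ff", "fm")


def sample_tissue_functionals(
    rng: np.random.Generator,
    table: dict | None = None,
    max_retries: int = 32,
) -> dict:
    """Draw one per-phantom set of functional targets.

    Returns a dict mapping tissue name -> {s, fb, fw, ff, fm} (entries
    that come from the PDE solve are None) plus key ``ctHb_blood`` (uM).
    Tissues whose sampled fractions leave a negative complement are
    redrawn up to ``max_retries`` times before
    :class:`InfeasibleDrawError` is raised.
    """
    if table is None:
        table = FUNCTIONAL_TABLE
    for _ in range(max_retries):
        draws: dict = {}
        for tissue in _DRAW_ORDER:
            row = table[tissue]
            draws[tissue] = {}
            for f in _FIELDS:
                spec = row[f]
                if spec is PDE or callable(spec) and not hasattr(spec, "sample"):
                    draws[tissue][f] = spec  # resolve later
                else:
                    draws[tissue][f] = float(spec.sample(rng))
        # resolve ties/complements in order
        ok = True
        for tissue in _DRAW_ORDER:
            for f in _FIELDS:
                v = draws[tissue][f]
                if callable(v):
                    draws[tissue][f] = float(v(draws))
                elif v is PDE:
                    draws[tissue][f] = None
            vals = [draws[tissue][f] for f in _FIELDS[1:]]  # fractions only
            if any(v is not None and v < 0 for v in vals):
                ok = False
                break
            total = sum(v for v in vals if v is not None)
            if total > 100.0 + 1e-9:
                ok = False
                break
        if ok:
            draws["ctHb_blood"] = float(CTHB_BLOOD_SPEC.sample(rng))
            return draws
    raise InfeasibleDrawError(
        "sampled fractions left a negative complement after retries")


@dataclass
class ReactionDiffusionProblem:
    """Targets and indicators for one diffusion-reaction solve.

    ``targets`` maps tissue code -> target value; every listed code is an
    indicator (chi = 1 there, 0 elsewhere).
    """

    mu: float = DEFAULT_MU
    targets: dict[int, float] = field(default_factory=dict)
    tol: float = 1e-8
    maxiter: int = 10_000


def solve_reaction_diffusion(
    problem: ReactionDiffusionProblem,
    volume: LabelVolume,
    domain: np.ndarray | None = None,
) -> np.ndarray:
    """Solve -mu Lap(u) + chi (u - target) = 0 on the breast interior.

    ``domain`` defaults to all non-background voxels. Returns a float64
    array over the full grid, zero outside the domain. The solution obeys
    the discrete maximum principle: min(targets) <= u <= max(targets).
    """
    lab = volume.labels
    h = volume.voxel_size
    if domain is None:
        domain = lab != L.WATER
    domain = np.asarray(domain, dtype=bool)
    n = int(domain.sum())
    if n == 0:
        raise NoIndicatorError("empty solve domain")

    chi = np.zeros(lab.shape)
    rhs_full = np.zeros(lab.shape)
    for code, target in problem.targets.items():
        m = (lab == code) & domain
        chi[m] = 1.0
        rhs_full[m] = target
    if not chi.any():
        raise NoIndicatorError("no indicator tissue present in the domain")

    # every connected component needs at least one indicator voxel
    comp, n_comp = ndimage.label(domain)
    if n_comp > 1:
        has_ind = np.unique(comp[(chi > 0) & domain])
        missing = set(range(1, n_comp + 1)) - set(int(v) for v in has_ind)
        if missing:
            raise NoIndicatorError(
                f"{len(missing)} connected component(s) lack an indicator tissue")

    idx = -np.ones(lab.shape, dtype=np.int64)
    coords = np.argwhere(domain)
    idx[domain] = np.arange(n)

    k = problem.mu / (h * h)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for axis in range(3):
        shift_fwd = np.roll(idx, -1, axis=axis)
        # mark wrap-around as invalid
        sl = [slice(None)] * 3
        sl[axis] = -1
        shift_fwd[tuple(sl)] = -1
        here = idx[domain]
        there = shift_fwd[domain]
        ok = there >= 0
        i, j = here[ok], there[ok]
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([np.full(len(i), -k), np.full(len(i), -k)])
        np.add.at(diag, i, k)
        np.add.at(diag, j, k)
    diag += chi[domain]
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    b = rhs_full[domain] * chi[domain]

    x0 = np.full(n, b[chi[domain] > 0].mean() if (chi[domain] > 0).any() else 0.0)
    u, info = cg(A, b, x0=x0, rtol=problem.tol, maxiter=problem.maxiter)
    if info != 0:
        # fall back to a direct solve for robustness on small systems
        from scipy.sparse.linalg import spsolve

        u = spsolve(A.tocsc(), b)

    out = np.zeros(lab.shape)
    out[domain] = u
    return out


def assign_oxygen_saturation(
    volume: LabelVolume,
    draws: dict,
    mu: float = DEFAULT_MU,
    tol: float = 1e-8,
) -> np.ndarray:
    """Oxygen saturation map (%): indicators on skin, artery, vein, and
    lesion (VTC + necrotic core); fat/ligament/TDLU/duct/glandular/PA take
    the PDE solution; nipple carries its fixed target; indicator voxels
    carry their targets exactly."""
    targets = {
        L.SKIN: draws["skin"]["s"],
        L.ARTERY: draws["artery"]["s"],
        L.VEIN: draws["vein"]["s"],
        L.VTC: draws["VTC"]["s"],
        L.NECROTIC_CORE: draws["necrotic_core"]["s"],
    }
    problem = ReactionDiffusionProblem(mu=mu, targets=targets, tol=tol)
    s = solve_reaction_diffusion(problem, volume)
    lab = volume.labels
    for code, t in targets.items():
        s[lab == code] = t
    s[lab == L.NIPPLE] = draws["nipple"]["s"]
    s[lab == L.WATER] = 0.0
    return s.astype(np.float32)


def assign_blood_volume_fraction(
    volume: LabelVolume,
    draws: dict,
    mu: float = DEFAULT_MU,
    tol: float = 1e-8,
) -> np.ndarray:
    """Blood volume fraction map (%): indicators on VTC, necrotic core,
    fat-group, glandular, artery, and vein; the PA shell is indicator-free
    so fb interpolates smoothly between the lesion and its surroundings
    (modelling peri-tumoral angiogenesis); skin and nipple take their
    fixed table values outside the PDE."""
    fat_fb = draws["fat"]["fb"]
    targets = {
        L.VTC: draws["VTC"]["fb"],
        L.NECROTIC_CORE: draws["necrotic_core"]["fb"],
        L.FAT: fat_fb,
        L.LIGAMENT: fat_fb,
        L.TDLU: fat_fb,
        L.DUCT: fat_fb,
        L.GLANDULAR: draws["glandular"]["fb"],
        L.ARTERY: draws["artery"]["fb"],
        L.VEIN: draws["vein"]["fb"],
    }
    problem = ReactionDiffusionProblem(mu=mu, targets=targets, tol=tol)
    # exclude skin/nipple from the solve domain: their fb is assigned
    # piecewise-constant and they are not part of the diffusion model
    lab = volume.labels
    domain = (lab != L.WATER) & (lab != L.SKIN) & (lab != L.NIPPLE)
    fb = solve_reaction_diffusion(problem, volume, domain=domain)
    for code, t in targets.items():
        fb[lab == code] = t
    fb[lab == L.SKIN] = draws["skin"]["fb"]
    fb[lab == L.NIPPLE] = draws["nipple"]["fb"]
    fb[lab == L.WATER] = 0.0
    return fb.astype(np.float32)


def assign_piecewise_fractions(
    volume: LabelVolume,
    draws: dict,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-constant fw, ff, fm maps (%).

    Background water voxels carry fw = 100 (the breast is immersed in the
    water bowl); melanosome is present only in skin and nipple.
    """
    lab = volume.labels
    tissue_of_code = {
        L.FAT: "fat", L.LIGAMENT: "fat", L.TDLU: "fat", L.DUCT: "fat",
        L.GLANDULAR: "glandular", L.SKIN: "skin", L.NIPPLE: "nipple",
        L.ARTERY: "artery", L.VEIN: "vein", L.VTC: "VTC",
        L.NECROTIC_CORE: "necrotic_core", L.PA: "PA",
    }
    fw = np.zeros(lab.shape, dtype=np.float32)
    ff = np.zeros(lab.shape, dtype=np.float32)
    fm = np.zeros(lab.shape, dtype=np.float32)
    for code, tissue in tissue_of_code.items():
        m = lab == code
        if not m.any():
            continue
        fw[m] = draws[tissue]["fw"]
        ff[m] = draws[tissue]["ff"]
        fm[m] = draws[tissue]["fm"]
    fw[lab == L.WATER] = 100.0
    return fw, ff, fm


@dataclass
class FunctionalMaps:
    """Per-voxel functional property maps (percent) and the per-phantom
    blood hemoglobin concentration (uM)."""

    s: np.ndarray
    fb: np.ndarray
    fw: np.ndarray
    ff: np.ndarray
    fm: np.ndarray
    ctHb_blood: float

    def budget(self) -> np.ndarray:
        """fb + fw + ff + fm per voxel (percent)."""
        return self.fb + self.fw + self.ff + self.fm


def assemble_functional_maps(
    volume: LabelVolume,
    rng: np.random.Generator,
    mu_s: float = DEFAULT_MU,
    mu_fb: float = DEFAULT_MU,
    tol: float = 1e-8,
    table: dict | None = None,
) -> FunctionalMaps:
    """Draw tissue targets and build all functional maps for a phantom."""
    draws = sample_tissue_functionals(rng, table=table)
    s = assign_oxygen_saturation(volume, draws, mu=mu_s, tol=tol)
    fb = assign_blood_volume_fraction(volume, draws, mu=mu_fb, tol=tol)
    fw, ff, fm = assign_piecewise_fractions(volume, draws)
    maps = FunctionalMaps(s=s, fb=fb, fw=fw, ff=ff, fm=fm,
                          ctHb_blood=draws["ctHb_blood"])
    maps.draws = draws  # kept for provenance and testing
    return maps
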