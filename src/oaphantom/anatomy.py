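"""Anatomical label volumes: data model, shape sampling, fixture anatomy,
and interior blood-vessel tree growth.

The anatomical phantom is a 3D uniform Cartesian lattice of unsigned 8-bit
tissue codes. Axis 0 (x) runs from the chest wall toward the nipple; axes
1 and 2 (y, z) span the chest-wall plane, with z pointing toward the
patient's head and, for a left breast, y toward the sternum. The polar
angle theta of a vessel entry point is measured in the chest-wall plane
from +z toward +y.

Breast size/shape parameters follow the BI-RADS density types A-D
(almost entirely fatty through extremely dense) and are drawn from
truncated Gaussian distributions consistent with a prone position inside
a hemispherical scanner of 85 mm radius.

The fixture generator produces a simplified parametric anatomy (half
ellipsoid + skin shell + glandular compartment + ligament septa + duct /
TDLU seeds). It is a stand-in for externally produced anatomy engines:
volumes produced by such tools can be ingested through
:func:`oaphantom.io.read_label_volume` instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import labels as L
from .errors import InvalidArgumentError
from .sampling import TruncatedGaussianSpec

__all__ = [
    "LabelVolume",
    "ShapeParams",
    "VesselEntry",
    "VesselTreeConfig",
    "SHAPE_PARAM_TABLE",
    "DEFAULT_ENTRIES",
    "sample_shape_params",
    "generate_fixture_anatomy",
    "grow_vessel_trees",
    "vessel_entry_point",
]

BREAST_TYPES = ("A", "B", "C", "D")


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class LabelVolume:
    """A labeled anatomical volume on a uniform grid.

    Attributes
    ----------
    voxel_size : float
        Isotropic voxel edge length in mm.
    origin : tuple of float
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    labels : ndarray of uint8, shape (nx, ny, nz)
        Tissue code per voxel.
    label_table : dict
        Mapping code -> tissue name.
    meta : dict
        Free-form bookkeeping (generation counts, PA underlying-tissue map,
        vessel tree graphs, ...). Not required for correctness.
    """

    voxel_size: float
    origin: tuple[float, float, float]
    labels: np.ndarray
    label_table: dict[int, str] = field(default_factory=lambda: dict(L.LABEL_TABLE))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise InvalidArgumentError("voxel_size must be > 0")
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3 or min(self.labels.shape) < 1:
            raise InvalidArgumentError("labels must be a non-empty 3D array")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape

    def copy(self) -> "LabelVolume":
        return LabelVolume(
            self.voxel_size,
            tuple(self.origin),
            self.labels.copy(),
            dict(self.label_table),
            {k: (v.copy() if isinstance(v, np.ndarray) else v)
             for k, v in self.meta.items()},
        )

    def counts(self) -> dict[int, int]:
        """Voxel count per tissue code actually present."""
        codes, n = np.unique(self.labels, return_counts=True)
        return {int(c): int(k) for c, k in zip(codes, n)}

    def breast_mask(self) -> np.ndarray:
        """All non-background voxels."""
        return self.labels != L.WATER

    def validate(self) -> None:
        """Check that every voxel code is present in the label table."""
        present = set(self.counts())
        unknown = present - set(self.label_table)
        if unknown:
            from .errors import UnknownLabelError

            raise UnknownLabelError(min(unknown))


@dataclass(frozen=True)
class ShapeParams:
    """Breast volume extents (mm) and dimensionless shape coefficients.

    a1t/a1b: superior/inferior extents (z), a2l/a2r: lateral extents (y),
    a3: chest-wall-to-nipple depth (x). eps1 controls the roundness of the
    chest-wall cross-section; B0/B1/H0/H1 are low-order azimuthal
    modulations of the silhouette.
    """

    a1t: float
    a1b: float
    a2l: float
    a2r: float
    a3: float
    eps1: float = 1.0
    B0: float = 0.0
    B1: float = 0.0
    H0: float = 0.0
    H1: float = 0.0

    def __post_init__(self):
        for name in ("a1t", "a1b", "a2l", "a2r", "a3"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"extent {name} must be positive")

    @classmethod
    def hemisphere(cls, radius: float) -> "ShapeParams":
        """A hemispherical breast of the given radius (cup-stabilized shape)."""
        return cls(radius, radius, radius, radius, radius)


# Distribution table for shape/size parameters per breast type. Ratio rows
# apply to all types; a1t and a3/a1t differ by density type (A/B share one
# column, D follows C for a1t).
_A1T_AB = TruncatedGaussianSpec(59.70, 3.58, 50.77, 71.5)
_A1T_CD = TruncatedGaussianSpec(50.05, 3.58, 42.9, 57.2)

SHAPE_PARAM_TABLE = {
    "a1t": {"A": _A1T_AB, "B": _A1T_AB, "C": _A1T_CD, "D": _A1T_CD},
    "a1b_ratio": TruncatedGaussianSpec.normal(1.0, 0.02),
    "a2r_ratio": TruncatedGaussianSpec.normal(1.0, 0.05),
    "a2l_ratio": TruncatedGaussianSpec.normal(1.0, 0.05),
    "a3_ratio": {
        "A": TruncatedGaussianSpec(0.85, 0.14, 0.8, 1.2),
        "B": TruncatedGaussianSpec(0.85, 0.14, 0.8, 1.2),
        "C": TruncatedGaussianSpec(0.85, 0.12, 0.7, 1.1),
        "D": TruncatedGaussianSpec(0.85, 0.1, 0.7, 1.1),
    },
    "eps1": TruncatedGaussianSpec.normal(1.0, 0.1),
    "B0": TruncatedGaussianSpec(0.0, 0.1, -0.18, 0.18),
    "B1": TruncatedGaussianSpec(0.0, 0.1, -0.18, 0.18),
    "H0": TruncatedGaussianSpec(0.0, 0.15, -0.11, 0.11),
    "H1": TruncatedGaussianSpec(0.0, 0.25, -0.3, 0.3),
}


def sample_shape_params(breast_type: str, rng: np.random.Generator) -> ShapeParams:
    """Draw breast size and shape parameters for the given BI-RADS type.

    Ratio parameters (a1b/a1t, a2r/a1t, a2l/a2r, a3/a1t) are converted to
    absolute extents.
    """
    if breast_type not in BREAST_TYPES:
        raise InvalidArgumentError(
            f"unknown breast type {breast_type!r}; expected one of {BREAST_TYPES}"
        )
    t = SHAPE_PARAM_TABLE
    a1t = float(t["a1t"][breast_type].sample(rng))
    a1b = a1t * float(t["a1b_ratio"].sample(rng))
    a2r = a1t * float(t["a2r_ratio"].sample(rng))
    a2l = a2r * float(t["a2l_ratio"].sample(rng))
    a3 = a1t * float(t["a3_ratio"][breast_type].sample(rng))
    return ShapeParams(
        a1t=a1t, a1b=a1b, a2l=a2l, a2r=a2r, a3=a3,
        eps1=float(t["eps1"].sample(rng)),
        B0=float(t["B0"].sample(rng)),
        B1=float(t["B1"].sample(rng)),
        H0=float(t["H0"].sample(rng)),
        H1=float(t["H1"].sample(rng)),
    )


# ---------------------------------------------------------------------------
# fixture anatomy
# ---------------------------------------------------------------------------

#: Glandular volume fraction of the breast interior by density type.
GLANDULAR_FRACTION = {"A": 0.06, "B": 0.16, "C": 0.35, "D": 0.55}


def _quadrant_semiaxes(shape: ShapeParams, y: np.ndarray, z: np.ndarray):
    ay = np.where(y >= 0, shape.a2r, shape.a2l)
    az = np.where(z >= 0, shape.a1t, shape.a1b)
    return ay, az


def _cross_section_rho(shape: ShapeParams, y: np.ndarray, z: np.ndarray):
    """Normalized squared cross-section radius rho(y, z) with azimuthal
    modulation; membership is rho + (x/a3)^2 <= 1."""
    ay, az = _quadrant_semiaxes(shape, y, z)
    p = 2.0 / max(shape.eps1, 0.2)
    if abs(p - 2.0) < 1e-12:
        rho = (y / ay) ** 2 + (z / az) ** 2
    else:
        with np.errstate(invalid="ignore"):
            rho = (np.abs(y / ay) ** p + np.abs(z / az) ** p) ** (2.0 / p)
    phi = np.arctan2(y, z)
    mod = 1.0 + shape.B0 * np.cos(phi) + shape.B1 * np.sin(phi) \
        + shape.H0 * np.cos(2 * phi) + shape.H1 * np.sin(2 * phi)
    mod = np.clip(mod, 0.5, 1.5)
    return rho / (mod ** 2)


def _inside_breast(shape: ShapeParams, x, y, z):
    """Implicit half-superellipsoid membership with azimuthal modulation."""
    return _cross_section_rho(shape, y, z) + (x / shape.a3) ** 2 <= 1.0


def generate_fixture_anatomy(
    shape: ShapeParams,
    breast_type: str,
    voxel_size: float,
    rng: np.random.Generator,
    skin_thickness: float = 1.5,
    n_tdlu: int | None = None,
    n_septa: int = 8,
) -> LabelVolume:
    """Generate a synthetic labeled breast volume.

    Produces a half-ellipsoidal prone breast (chest wall at the x=0 face)
    with a closed skin shell, a nipple cap at the apex, a fat/glandular
    partition whose glandular fraction rises from type A to D, thin
    ligament septa, and scattered TDLU/duct seed voxels that serve as
    lesion candidate sites. The background is water.
    """
    if breast_type not in BREAST_TYPES:
        raise InvalidArgumentError(f"unknown breast type {breast_type!r}")
    if voxel_size <= 0:
        raise InvalidArgumentError("voxel_size must be > 0")

    h = float(voxel_size)
    pad = 2
    nx = int(math.ceil(shape.a3 / h)) + pad
    ny = int(math.ceil((shape.a2l + shape.a2r) / h)) + 2 * pad
    nz = int(math.ceil((shape.a1b + shape.a1t) / h)) + 2 * pad
    if nx * ny * nz > 600_000_000:
        raise InvalidArgumentError("requested grid exceeds memory bounds")

    # voxel-center coordinates; chest wall plane at x = 0 (voxel 0 center at h/2)
    x = (np.arange(nx) + 0.5) * h
    y = (np.arange(ny) + 0.5) * h - (pad * h + shape.a2l)
    z = (np.arange(nz) + 0.5) * h - (pad * h + shape.a1b)
    Y2, Z2 = y[:, None], z[None, :]          # 2D cross-section fields
    rho2 = _cross_section_rho(shape, Y2, Z2)
    inside = rho2[None, :, :] + (x[:, None, None] / shape.a3) ** 2 <= 1.0

    lab = np.zeros((nx, ny, nz), dtype=np.uint8)

    # Skin: all interior voxels within skin_thickness of the exterior,
    # including across the chest-wall face so the shell is closed.
    padded = np.pad(inside, 1, constant_values=False)
    dist_in = ndimage.distance_transform_edt(padded, sampling=h)[1:-1, 1:-1, 1:-1]
    skin = inside & (dist_in <= skin_thickness)
    interior = inside & ~skin
    lab[skin] = L.SKIN
    lab[interior] = L.FAT

    # Nipple cap: relabel skin and shallow interior near the apex.
    apex = np.array([shape.a3, 0.0, 0.0])
    r2_yz = Y2 ** 2 + Z2 ** 2
    r_apex2 = (x[:, None, None] - apex[0]) ** 2 + r2_yz[None, :, :]
    nipple = inside & (r_apex2 <= 4.0 ** 2) & (dist_in <= 2.0 * skin_thickness)
    lab[nipple] = L.NIPPLE

    # Glandular compartment: smoothed random field (generated on a ~2 mm
    # lattice and upsampled) biased toward the central axis, thresholded
    # at the quantile realizing the density fraction for the breast type.
    interior = lab == L.FAT
    n_int = int(interior.sum())
    if n_int:
        ds = max(1, int(round(2.0 / h)))
        coarse_dims = tuple(max(2, -(-d // ds)) for d in (nx, ny, nz))
        noise_c = rng.standard_normal(coarse_dims).astype(np.float32)
        noise_c = ndimage.gaussian_filter(noise_c, sigma=max(8.0 / (h * ds), 1.0))
        noise = ndimage.zoom(noise_c, [d / c for d, c in zip((nx, ny, nz),
                                                             coarse_dims)],
                             order=1, grid_mode=True, mode="nearest")
        sd = noise[interior].std()
        if sd > 0:
            noise /= sd
        r_axis = np.sqrt(r2_yz) / max(shape.a2l, shape.a2r)
        score = noise + 1.5 * (1.0 - r_axis)[None, :, :]
        frac = GLANDULAR_FRACTION[breast_type]
        thr = np.quantile(score[interior], 1.0 - frac)
        lab[interior & (score > thr)] = L.GLANDULAR

    # Ligament septa: thin radial sheets through the fat.
    phi2 = np.arctan2(Y2, Z2)
    r2 = np.sqrt(r2_yz)
    septa2 = np.zeros((ny, nz), dtype=bool)
    sept_angles = rng.uniform(-np.pi, np.pi, size=n_septa)
    half_w = max(h * 0.75, 0.4)
    for a in sept_angles:
        d = np.abs(np.angle(np.exp(1j * (phi2 - a))))
        septa2 |= (d * np.maximum(r2, 1.0) <= half_w) & (r2 > 5.0)
    lab[(lab == L.FAT) & septa2[None, :, :]] = L.LIGAMENT

    # TDLU / duct seeds inside the glandular compartment: candidate lesion
    # sites. Ducts are short voxel lines pointing toward the nipple.
    gland_idx = np.argwhere(lab == L.GLANDULAR)
    if n_tdlu is None:
        n_tdlu = max(10, min(150, n_int // 5_000))
    if len(gland_idx):
        pick = rng.choice(len(gland_idx), size=min(n_tdlu, len(gland_idx)),
                          replace=False)
        apex_idx = np.array([(apex[0] - 0.5 * h) / h,
                             (0.0 - y[0]) / h, (0.0 - z[0]) / h])
        for k in pick:
            c = gland_idx[k]
            sl = tuple(slice(max(ci - 1, 0), ci + 2) for ci in c)
            region = lab[sl]
            region[region == L.GLANDULAR] = L.TDLU
            # short duct segment toward the nipple
            d = apex_idx - c
            norm = np.linalg.norm(d)
            if norm > 0:
                d = d / norm
                for step in range(1, int(min(norm, 6.0 / h))):
                    p = np.round(c + d * step).astype(int)
                    if (p < 0).any() or (p >= lab.shape).any():
                        break
                    if lab[tuple(p)] in (L.GLANDULAR, L.FAT):
                        lab[tuple(p)] = L.DUCT

    vol = LabelVolume(
        voxel_size=h,
        origin=(float(x[0]), float(y[0]), float(z[0])),
        labels=lab,
        meta={
            "breast_type": breast_type,
            "shape": shape,
            "skin_thickness": skin_thickness,
        },
    )
    vol.meta["gen_counts"] = vol.counts()
    return vol


# ---------------------------------------------------------------------------
# vessel trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselEntry:
    """Entry point of one vessel tree on the chest-wall silhouette."""

    name: str
    theta: float          # polar angle (rad) in the chest-wall plane
    code: int             # labels.ARTERY or labels.VEIN
    d_edge: float         # distance from the breast edge (mm)


def _default_entries() -> tuple[VesselEntry, ...]:
    A, V = L.ARTERY, L.VEIN
    e = []
    # five anatomical vessel sets; internal mammary and intercostal carry
    # two arteries and two veins each
    for th in (11 * math.pi / 15, -8 * math.pi / 9):
        e.append(VesselEntry("internal_mammary", th, A, 2.0))
    for th in (41 * math.pi / 45, -32 * math.pi / 45):
        e.append(VesselEntry("internal_mammary", th, V, 2.0))
    e.append(VesselEntry("thoraco_acromial", 2 * math.pi / 5, A, 2.0))
    e.append(VesselEntry("thoraco_acromial", 17 * math.pi / 30, V, 2.0))
    e.append(VesselEntry("lateral_thoracic", -2 * math.pi / 45, A, 2.0))
    e.append(VesselEntry("lateral_thoracic", math.pi / 5, V, 2.0))
    e.append(VesselEntry("subscapular_thoraco_dorsal", -math.pi / 2, A, 2.0))
    e.append(VesselEntry("subscapular_thoraco_dorsal", -13 * math.pi / 45, V, 2.0))
    for th in (16 * math.pi / 45, -math.pi / 12):
        e.append(VesselEntry("intercostal", th, A, 24.0))
    for th in (math.pi / 6, -3 * math.pi / 10):
        e.append(VesselEntry("intercostal", th, V, 24.0))
    return tuple(e)


DEFAULT_ENTRIES = _default_entries()


@dataclass(frozen=True)
class VesselTreeConfig:
    """Growth parameters of the simplified branching tree model.

    maxBranch / initRad / minRadFrac / numTry / maxTry / absMaxTry follow
    the vessel-parameter vocabulary of the anatomy engine's configuration;
    seg_len_factor, branch_segments and cone_angle are geometric knobs of
    the simplified grower, calibrated so the ensemble breast-volume
    percentage occupied by vessels matches clinically estimated statistics.
    """

    entries: tuple[VesselEntry, ...] = DEFAULT_ENTRIES
    max_branch: int = 500
    init_rad: float = 0.6
    min_rad_frac: float = 0.85
    num_try: int = 50
    max_try: int = 100
    abs_max_try: int = 1000
    seg_len_factor: float = 4.0     # segment length = factor * current radius
    branch_segments: int = 3        # segments per branch
    cone_angle: float = 0.6         # rad, direction jitter per segment
    min_radius: float = 0.15        # mm, stop growing below this radius
    end_taper: float = 1.0          # end radius / start radius within a branch
    #: interior-tree vascular volume as a fraction of breast volume; the
    #: grower stops a tree once its share of this budget is rasterized
    #: (vascular volume scales with perfused tissue volume, which keeps
    #: the blood-vessel volume percentage stable across breast sizes)
    vol_budget_frac: float = 0.0034

    def __post_init__(self):
        if self.init_rad <= 0:
            raise InvalidArgumentError("init_rad must be > 0")
        if not (0 < self.min_rad_frac <= 1):
            raise InvalidArgumentError("min_rad_frac must be in (0, 1]")
        for name in ("max_branch", "num_try", "max_try", "abs_max_try"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")


def vessel_entry_point(volume: LabelVolume, theta: float, d_edge: float):
    """Voxel index of a tree root: the point at polar angle ``theta`` on the
    breast silhouette in the chest-wall plane, ``d_edge`` mm inside the
    breast edge, a few voxels in front of the chest wall.

    Returns None when the ray at ``theta`` never leaves the breast (entry
    outside the volume) or the inset point is not interior tissue.
    """
    lab = volume.labels
    h = volume.voxel_size
    nx, ny, nz = lab.shape
    # chest-wall slice a few voxels inside so the root is interior tissue
    x_idx = min(max(int(round(3.0 / h)), 1), nx - 1)
    sl = lab[x_idx]
    inside = sl != L.WATER
    if not inside.any():
        return None
    idx = np.argwhere(inside)
    cy, cz = idx.mean(axis=0)
    u = np.array([math.sin(theta), math.cos(theta)])  # (y, z) direction
    # march outward to the boundary
    r_max = max(ny, nz)
    r_edge = None
    for r in np.arange(0, r_max):
        p = np.round([cy + u[0] * r, cz + u[1] * r]).astype(int)
        if (p < 0).any() or p[0] >= ny or p[1] >= nz or not inside[p[0], p[1]]:
            r_edge = r
            break
    if r_edge is None or r_edge * h <= d_edge:
        return None
    r_in = r_edge - d_edge / h
    p = np.round([cy + u[0] * r_in, cz + u[1] * r_in]).astype(int)
    if not inside[p[0], p[1]]:
        return None
    return (x_idx, int(p[0]), int(p[1]))


def _rasterize_segment(lab, p0, p1, radius_vox, allowed, code):
    """Paint a sphere-swept segment (capsule) of the given voxel radius."""
    lo = np.floor(np.minimum(p0, p1) - radius_vox - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + radius_vox + 2).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, lab.shape)
    if (hi <= lo).any():
        return 0
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    gx, gy, gz = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    pts = np.stack([gx, gy, gz], axis=-1).astype(float)
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0:
        t = np.zeros(pts.shape[:-1])
    else:
        t = np.clip(((pts - p0) @ d) / denom, 0.0, 1.0)
    closest = p0 + t[..., None] * d
    dist = np.linalg.norm(pts - closest, axis=-1)
    region = lab[sl]
    hit = (dist <= radius_vox) & np.isin(region, allowed)
    region[hit] = code
    return int(hit.sum())


def grow_vessel_trees(
    volume: LabelVolume,
    config: VesselTreeConfig | None = None,
    rng: np.random.Generator | None = None,
) -> LabelVolume:
    """Grow a stochastic branching vessel tree from each configured entry.

    Branches are random walks of capsule segments; the root radius is
    ``init_rad`` and each child's starting radius is at least
    ``min_rad_frac`` times its parent's end radius. Segments that would
    leave the interior (or exceed the retry budgets) are rejected. Vessel
    voxels only ever overwrite fat, glandular, or ligament tissue. The
    grown tree graphs (lists of (start, end, r_start, r_end, depth)
    segments in voxel coordinates) are stored in ``meta['vessel_trees']``.
    """
    if config is None:
        config = VesselTreeConfig()
    if rng is None:
        rng = np.random.default_rng()
    out = volume.copy()
    lab = out.labels
    h = out.voxel_size
    allowed = np.array(L.VESSEL_OVERWRITABLE, dtype=np.uint8)
    interior_ok = np.isin(lab, np.array(
        (L.FAT, L.GLANDULAR, L.LIGAMENT, L.TDLU, L.DUCT), dtype=np.uint8))
    trees = []

    roots = []
    for entry in config.entries:
        root = vessel_entry_point(out, entry.theta, entry.d_edge)
        if root is None:
            import logging
            logging.getLogger(__name__).warning(
                "vessel entry %s (theta=%.3f) outside breast; skipped", entry.name,
                entry.theta)
        roots.append(root)
    n_valid = sum(1 for r in roots if r is not None)
    n_breast = int((lab != L.WATER).sum())
    budget_per_tree = (config.vol_budget_frac * n_breast / max(n_valid, 1)
                       if config.vol_budget_frac > 0 else float("inf"))

    for entry, root in zip(config.entries, roots):
        if root is None:
            continue
        root = np.array(root, dtype=float)
        # seed voxel so even maxBranch = 0 leaves a root mark
        _rasterize_segment(lab, root, root, config.init_rad / h, allowed, entry.code)
        segments = []
        if config.max_branch > 0:
            # initial direction: inward (away from the silhouette), i.e.
            # toward +x with a pull toward the central axis
            c_dir = np.array([1.0, -math.sin(entry.theta), -math.cos(entry.theta)])
            c_dir /= np.linalg.norm(c_dir)
            stack = [(root, c_dir, config.init_rad, 0)]
            n_branch = 0
            tries_total = 0
            voxels_painted = 0
            while stack and n_branch < config.max_branch \
                    and voxels_painted < budget_per_tree \
                    and tries_total < config.abs_max_try:
                p, d, r, depth = stack.pop()
                if r < config.min_radius:
                    continue
                n_branch += 1
                r_end = r * config.end_taper
                ok_any = False
                for si in range(config.branch_segments):
                    seg_len = max(config.seg_len_factor * r, 2 * h) / h
                    placed = False
                    for attempt in range(config.num_try):
                        tries_total += 1
                        if tries_total >= config.abs_max_try:
                            break
                        jitter = rng.normal(scale=config.cone_angle, size=3)
                        nd = d + jitter
                        nd /= np.linalg.norm(nd)
                        q = p + nd * seg_len
                        qi = np.round(q).astype(int)
                        if (qi < 0).any() or (qi >= lab.shape).any():
                            continue
                        if not interior_ok[tuple(qi)] and \
                                lab[tuple(qi)] not in (entry.code,):
                            continue
                        ri = r + (r_end - r) * (si + 1) / config.branch_segments
                        voxels_painted += _rasterize_segment(
                            lab, p, q, ri / h, allowed, entry.code)
                        segments.append((tuple(p), tuple(q), float(r), float(ri),
                                         depth))
                        p, d, r = q, nd, ri
                        placed = True
                        ok_any = True
                        break
                    if not placed:
                        break
                if ok_any:
                    # spawn two children at the branch tip
                    for _ in range(2):
                        frac = rng.uniform(config.min_rad_frac, 1.0)
                        stack.append((p.copy(), d.copy(), r * frac, depth + 1))
        trees.append({"name": entry.name, "code": entry.code,
                      "root": tuple(int(v) for v in root.astype(int)),
                      "segments": segments})

    out.meta["vessel_trees"] = trees
    return out
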