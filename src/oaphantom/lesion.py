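"""Numerical lesion phantoms: spiculated viable-tumor-cell (VTC) masks,
necrotic core / peripheral angiogenesis (PA) morphology, and insertion
into anatomical volumes.

Malignant breast lesions arise in ducts and lobules and, when aggressive,
develop an avascular necrotic center and a rim of newly sprouted
microvasculature (angiogenesis) around the viable tumor shell. The core
is obtained by eroding the VTC mask with a spherical structuring element
of 0.75 mm radius (the thickness of the remaining viable ring) and the PA
shell by dilating it with a 5 mm ball; structuring elements are exact
Euclidean balls realized through distance transforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import labels as L
from .anatomy import LabelVolume
from .errors import (
    InvalidArgumentError,
    PlacementConflictError,
    PlacementFailureError,
)

__all__ = [
    "LesionPhantom",
    "OUTSIDE", "PA_CODE", "VTC_CODE", "CORE_CODE",
    "generate_vtc_mask",
    "add_necrosis_and_pa",
    "select_insertion_sites",
    "insert_lesion",
]

# compartment codes inside a LesionPhantom mask
OUTSIDE = 0
PA_CODE = 1
VTC_CODE = 2
CORE_CODE = 3


@dataclass
class LesionPhantom:
    """Ternary lesion mask: 0 outside, 1 PA, 2 VTC, 3 necrotic core."""

    mask: np.ndarray
    voxel_size: float
    nominal_diameter: float
    has_core_and_pa: bool

    def __post_init__(self):
        if self.nominal_diameter <= 0:
            raise InvalidArgumentError("nominal_diameter must be > 0")

    def counts(self) -> dict[int, int]:
        codes, n = np.unique(self.mask, return_counts=True)
        return {int(c): int(k) for c, k in zip(codes, n)}


def _feret_diameter(mask: np.ndarray, voxel_size: float) -> float:
    """Maximum caliper (Feret) extent of a binary mask, in mm."""
    pts = np.argwhere(mask)
    if len(pts) == 0:
        return 0.0
    if len(pts) > 40:
        try:
            from scipy.spatial import ConvexHull

            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:  # degenerate (coplanar) point sets
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max())) * voxel_size


def generate_vtc_mask(
    diameter: float,
    irregularity: float,
    voxel_size: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate a connected, irregular, spiculated VTC blob.

    The boundary is a sphere modulated by a smoothed random radial field
    plus thin radial spicules; the field amplitude scales with
    ``irregularity`` (0 gives an exact voxelized sphere). The mask is
    rescaled once so its maximum Feret extent matches the requested
    diameter.
    """
    if irregularity < 0:
        raise InvalidArgumentError("irregularity must be >= 0")
    h = float(voxel_size)
    if diameter < 3 * h:
        raise InvalidArgumentError(
            f"diameter {diameter} mm must span at least 3 voxels at {h} mm")
    R = diameter / 2.0
    margin = 1.0 + 0.8 * irregularity
    n = 2 * int(np.ceil(R * margin / h)) + 5
    c = (n - 1) / 2.0
    g = (np.indices((n, n, n)) - c) * h
    r = np.sqrt((g ** 2).sum(axis=0))

    if irregularity == 0:
        return r <= R

    noise = rng.standard_normal((n, n, n))
    noise = ndimage.gaussian_filter(noise, sigma=max(R / (2.5 * h), 1.0))
    sd = noise.std()
    if sd > 0:
        noise = noise / sd

    n_spic = 6 + int(round(8 * irregularity))
    dirs = rng.normal(size=(n_spic, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    spic_len = R * (1.0 + 0.6 * irregularity)
    spic_rad = max(1.5 * h, 0.12 * R)

    def build(scale: float) -> np.ndarray:
        r_thr = scale * R * (1.0 + 0.35 * irregularity * noise)
        m = r <= np.maximum(r_thr, h)
        for d in dirs:
            proj = g[0] * d[0] + g[1] * d[1] + g[2] * d[2]
            perp2 = np.maximum(r ** 2 - proj ** 2, 0.0)
            m |= (proj >= 0) & (proj <= scale * spic_len) & \
                 (perp2 <= spic_rad ** 2)
        # keep the component containing the center, fill holes
        lab_arr, _ = ndimage.label(m)
        center_lab = lab_arr[int(c), int(c), int(c)]
        if center_lab == 0:
            return m
        m = lab_arr == center_lab
        return ndimage.binary_fill_holes(m)

    # iterate the overall scale so the max Feret extent matches the
    # requested diameter (the noise field and clipping make the mapping
    # mildly nonlinear); the noise draws are fixed, so this stays
    # deterministic
    scale = 1.0
    m = build(scale)
    for _ in range(4):
        feret = _feret_diameter(m, h)
        if feret <= 0 or abs(feret - diameter) / diameter < 0.03:
            break
        scale *= diameter / feret
        m = build(scale)
    return m


def add_necrosis_and_pa(
    vtc_mask: np.ndarray,
    erosion_radius: float = 0.75,
    dilation_radius: float = 5.0,
    voxel_size: float = 0.125,
) -> LesionPhantom:
    """Form the necrotic core and PA shell around a VTC mask.

    core = VTC eroded by a ball of ``erosion_radius``; the viable ring is
    VTC minus core; PA = (VTC dilated by ``dilation_radius``) minus VTC.
    A VTC smaller than the erosion element yields an empty core (the
    lesion is then entirely viable tumor). The returned mask is padded so
    the PA shell is never clipped by the array bounds.
    """
    vtc = np.asarray(vtc_mask, dtype=bool)
    if not vtc.any():
        raise InvalidArgumentError("vtc_mask is empty")
    h = float(voxel_size)
    pad = int(np.ceil(dilation_radius / h)) + 2
    vtc = np.pad(vtc, pad, constant_values=False)

    dist_in = ndimage.distance_transform_edt(vtc, sampling=h)
    dist_out = ndimage.distance_transform_edt(~vtc, sampling=h)
    core = dist_in > erosion_radius
    pa = (~vtc) & (dist_out <= dilation_radius)

    mask = np.zeros(vtc.shape, dtype=np.uint8)
    mask[pa] = PA_CODE
    mask[vtc] = VTC_CODE
    mask[core] = CORE_CODE
    diameter = _feret_diameter(vtc, h)
    return LesionPhantom(
        mask=mask,
        voxel_size=h,
        nominal_diameter=diameter if diameter > 0 else h,
        has_core_and_pa=bool(core.any()),
    )


def select_insertion_sites(
    volume: LabelVolume,
    n_lesions: int,
    lesion_extents: list[float],
    rng: np.random.Generator,
) -> list[tuple[int, int, int]]:
    """Sample lesion center sites near duct/TDLU voxels.

    Each candidate site is accepted only when a bounding ball of half the
    lesion's extent avoids skin, nipple, muscle, background, and the
    bounding balls of previously placed lesions. Raises
    :class:`PlacementFailureError` when the pool is exhausted.
    """
    if n_lesions == 0:
        return []
    if len(lesion_extents) < n_lesions:
        raise InvalidArgumentError("need one extent per lesion")
    lab = volume.labels
    h = volume.voxel_size
    pool = np.argwhere(np.isin(lab, np.array((L.TDLU, L.DUCT), dtype=np.uint8)))
    if len(pool) == 0:
        raise PlacementFailureError(0, n_lesions)
    # distance of every voxel to the nearest forbidden (protected) voxel
    forbidden = np.isin(lab, np.array(L.PROTECTED_CODES, dtype=np.uint8))
    clearance = ndimage.distance_transform_edt(~forbidden, sampling=h)

    order = rng.permutation(len(pool))
    sites: list[tuple[int, int, int]] = []
    radii: list[float] = []
    # place the largest lesions first: they are the hardest to fit
    extents = sorted(lesion_extents[:n_lesions], reverse=True)
    for extent in extents:
        r = extent / 2.0
        placed = False
        for k in order:
            c = tuple(int(v) for v in pool[k])
            if clearance[c] <= r:
                continue
            ok = True
            for s_prev, r_prev in zip(sites, radii):
                d = np.linalg.norm((np.array(c) - np.array(s_prev)) * h)
                if d <= r + r_prev:
                    ok = False
                    break
            if ok:
                sites.append(c)
                radii.append(r)
                placed = True
                break
        if not placed:
            raise PlacementFailureError(len(sites), n_lesions)
    return sites


def insert_lesion(
    volume: LabelVolume,
    lesion: LesionPhantom,
    site: tuple[int, int, int],
) -> LabelVolume:
    """Insert a lesion centered at ``site`` (voxel coordinates).

    VTC/core/PA codes overwrite fat, glandular, ligament, TDLU, and duct
    voxels. PA voxels remember the underlying tissue code in the parallel
    map ``meta['pa_underlying']`` (optical/acoustic assignment inherits
    the underlying tissue there). Any overlap of the lesion with skin,
    nipple, muscle, or background raises
    :class:`PlacementConflictError`.
    """
    if abs(lesion.voxel_size - volume.voxel_size) > 1e-9:
        raise InvalidArgumentError("lesion and volume voxel sizes differ")
    out = volume.copy()
    lab = out.labels
    m = lesion.mask
    c = np.array(site, dtype=int)
    half = (np.array(m.shape) - 1) // 2
    lo = c - half
    hi = lo + np.array(m.shape)
    if (lo < 0).any() or (hi > np.array(lab.shape)).any():
        # crop, but only if no lesion voxel would be clipped away
        mlo = np.maximum(-lo, 0)
        mhi = np.array(m.shape) - np.maximum(hi - np.array(lab.shape), 0)
        crop = tuple(slice(a, b) for a, b in zip(mlo, mhi))
        if int((m[crop] > OUTSIDE).sum()) != int((m > OUTSIDE).sum()):
            raise PlacementConflictError("lesion extends outside the volume bounds")
        m = m[crop]
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, np.array(lab.shape))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    region = lab[sl]
    lesion_here = m > OUTSIDE
    protected = np.isin(region, np.array(L.PROTECTED_CODES, dtype=np.uint8))
    if (lesion_here & protected).any():
        raise PlacementConflictError(
            "lesion overlaps protected tissue (skin/nipple/muscle/background)")
    overlap_lesion = np.isin(region, np.array(L.LESION_CODES, dtype=np.uint8))
    if (lesion_here & overlap_lesion).any():
        raise PlacementConflictError("lesion overlaps a previously inserted lesion")

    pa_under = out.meta.get("pa_underlying")
    if pa_under is None:
        pa_under = np.zeros(lab.shape, dtype=np.uint8)
    pa_here = m == PA_CODE
    pa_under[sl][pa_here] = region[pa_here]
    out.meta["pa_underlying"] = pa_under

    region[pa_here] = L.PA
    region[m == VTC_CODE] = L.VTC
    region[m == CORE_CODE] = L.NECROTIC_CORE
    manifest = out.meta.setdefault("lesions", [])
    manifest.append({
        "site": tuple(int(v) for v in site),
        "nominal_diameter_mm": lesion.nominal_diameter,
        "has_core_and_pa": lesion.has_core_and_pa,
        "counts": lesion.counts(),
    })
    return out
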