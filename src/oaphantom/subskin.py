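"""Stochastic blood vasculature at a shallow fixed depth under the skin.

Superficial vessels dominate clinical optoacoustic breast images but are
absent from mammography-oriented anatomy engines. They are synthesized
here with cheap image-processing primitives: a uniform random matrix is
band-pass filtered (difference of Gaussians at scales sigma1 < sigma2),
binarized by Otsu's threshold and skeletonized, producing a random planar
curve network whose branch spacing is controlled by the two blur scales.
Replicating the 2D skeleton along the depth axis gives a sheet volume;
intersecting it with the thin shell lying ``depth`` below the inner skin
surface yields curves draped over the breast dome. Re-skeletonizing,
blurring with sigma3 and thresholding again inflates the centerlines to
tubes whose diameter is set by sigma3 (the defaults give ~0.75 mm vessels
at 0.375 mm depth). Connected segments are finally split alternately into
arteries and veins by the azimuthal position of their centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from . import labels as L
from .anatomy import LabelVolume
from .errors import InvalidArgumentError

__all__ = ["SubskinParams", "generate_subskin_vessels", "embed_subskin_vessels"]


@dataclass(frozen=True)
class SubskinParams:
    """Blur scales (mm), vessel depth below the inner skin surface (mm)."""

    sigma1: float = 3.875
    sigma2: float = 6.125
    sigma3: float = 0.219
    depth: float = 0.375
    target_diameter: float = 0.75   # informational
    xor_mode: str = "intersection"  # or "strict"

    def __post_init__(self):
        if not (0 < self.sigma1 < self.sigma2):
            raise InvalidArgumentError("need 0 < sigma1 < sigma2")
        if self.sigma3 <= 0:
            raise InvalidArgumentError("sigma3 must be > 0")
        if self.depth < 0:
            raise InvalidArgumentError("depth must be >= 0")
        if self.xor_mode not in ("intersection", "strict"):
            raise InvalidArgumentError("xor_mode must be 'intersection' or 'strict'")


def subskin_shell(breast_mask_no_skin: np.ndarray, depth: float,
                  voxel_size: float) -> np.ndarray:
    """The sub-skin shell: mask XOR (mask eroded to the requested depth).

    Depth is realized as iterated single-voxel erosions, so e.g. a depth
    of 0.375 mm at 0.125 mm voxels corresponds to three erosion passes.
    """
    iters = int(round(depth / voxel_size))
    if iters <= 0:
        return np.zeros_like(breast_mask_no_skin)
    eroded = ndimage.binary_erosion(
        breast_mask_no_skin, iterations=iters, border_value=0)
    return breast_mask_no_skin ^ eroded


def generate_subskin_vessels(
    breast_mask_no_skin: np.ndarray,
    params: SubskinParams,
    voxel_size: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate sub-skin artery and vein masks.

    Parameters
    ----------
    breast_mask_no_skin : bool ndarray (nx, ny, nz)
        Breast interior excluding the skin layer.
    params : SubskinParams
    voxel_size : float
        Isotropic voxel size in mm.
    rng : numpy Generator

    Returns
    -------
    (artery_mask, vein_mask) : disjoint boolean masks whose union is the
    final thresholded vessel set restricted to the breast interior.
    """
    mask = np.asarray(breast_mask_no_skin, dtype=bool)
    nx, ny, nz = mask.shape
    empty = (np.zeros_like(mask), np.zeros_like(mask))
    if not mask.any():
        return empty
    h = float(voxel_size)

    # (1)-(5): random planar curve network in the chest-wall plane
    u = rng.random((ny, nz))
    g1 = ndimage.gaussian_filter(u, params.sigma1 / h, mode="reflect")
    g2 = ndimage.gaussian_filter(u, params.sigma2 / h, mode="reflect")
    diff = g1 - g2
    bw = diff > threshold_otsu(diff)
    sk2 = skeletonize(bw)

    # (6): replicate along the depth axis into a sheet volume
    sheet = np.broadcast_to(sk2[None, :, :], (nx, ny, nz))

    # (7): thin shell at the requested depth below the inner skin surface
    shell = subskin_shell(mask, params.depth, h)

    # (8): combine sheet and shell (see module docstring; the geometric
    # intent is the set of skeleton curves lying on the shell)
    if params.xor_mode == "strict":
        comb = sheet ^ shell
    else:
        comb = sheet & shell
    if not comb.any():
        return empty

    # (9)-(11): centerlines, thickness blur, binarization
    sk3 = skeletonize(comb)
    blurred = ndimage.gaussian_filter(sk3.astype(np.float32), params.sigma3 / h,
                                      mode="reflect")
    if blurred.max() <= 0:
        return empty
    vessels = blurred > threshold_otsu(blurred)
    vessels &= mask
    if not vessels.any():
        return empty

    # (12): label connected segments alternately artery / vein, ordered by
    # the azimuthal angle of their centroids about the breast axis
    lab_arr, n_seg = ndimage.label(vessels, structure=np.ones((3, 3, 3), dtype=bool))
    centroids = ndimage.center_of_mass(vessels, lab_arr, range(1, n_seg + 1))
    cy = np.array([c[1] for c in centroids])
    cz = np.array([c[2] for c in centroids])
    phi = np.arctan2(cy - (ny - 1) / 2.0, cz - (nz - 1) / 2.0)
    order = np.argsort(phi, kind="stable")
    artery = np.zeros_like(mask)
    vein = np.zeros_like(mask)
    for rank, seg_idx in enumerate(order):
        seg = lab_arr == (seg_idx + 1)
        if rank % 2 == 0:
            artery |= seg
        else:
            vein |= seg
    return artery, vein


def embed_subskin_vessels(
    volume: LabelVolume,
    artery_mask: np.ndarray,
    vein_mask: np.ndarray,
) -> LabelVolume:
    """Relabel mask voxels as artery/vein, never touching skin, nipple,
    muscle, or background. The number of protected overlaps skipped is
    recorded in ``meta['subskin_protected_overlaps']``."""
    if artery_mask.shape != volume.dims or vein_mask.shape != volume.dims:
        raise InvalidArgumentError("mask dims do not match volume dims")
    out = volume.copy()
    lab = out.labels
    protected = np.isin(lab, np.array(L.PROTECTED_CODES, dtype=np.uint8))
    skipped = 0
    for mask, code in ((artery_mask, L.ARTERY), (vein_mask, L.VEIN)):
        m = np.asarray(mask, dtype=bool)
        hit = m & ~protected
        n_skip = int((m & protected).sum())
        if n_skip:
            import logging
            logging.getLogger(__name__).info(
                "%d %s voxels overlapped protected tissue and were skipped",
                n_skip, L.LABEL_TABLE[code])
        skipped += n_skip
        lab[hit] = code
    out.meta["subskin_protected_overlaps"] = skipped
    return out
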