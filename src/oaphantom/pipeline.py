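"""End-to-end phantom generation.

Pipeline order: anatomy -> interior vessel trees -> sub-skin vasculature
-> lesions -> functional -> optical -> acoustic. A single master seed
spawns one independent substream per stage (in a fixed order), so
changing e.g. the lesion count never perturbs the anatomy stream and any
bundle can be regenerated bit-identically from its config snapshot.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import labels as L
from .acoustic import AcousticMaps, assemble_acoustic_maps
from .anatomy import (
    LabelVolume,
    ShapeParams,
    VesselTreeConfig,
    SHAPE_PARAM_TABLE,
    generate_fixture_anatomy,
    grow_vessel_trees,
    sample_shape_params,
)
from .config import validate_config
from .errors import PhantomError
from .functional import FunctionalMaps, assemble_functional_maps
from .lesion import add_necrosis_and_pa, generate_vtc_mask, insert_lesion, \
    select_insertion_sites
from .optical import OpticalMaps, assemble_optical_maps
from .subskin import SubskinParams, embed_subskin_vessels, generate_subskin_vessels

log = logging.getLogger(__name__)

__all__ = ["PhantomBundle", "generate_phantom"]

_STAGES = ("anatomy", "trees", "subskin", "lesion", "functional", "optical",
           "acoustic")


@dataclass
class PhantomBundle:
    """Everything one phantom realization produces."""

    volume: LabelVolume
    functional: FunctionalMaps
    optical: OpticalMaps
    acoustic: AcousticMaps
    config: dict
    seed: int
    manifest: dict = field(default_factory=dict)


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


def generate_phantom(config: dict | None = None) -> PhantomBundle:
    """Run the full generation flow for one phantom.

    Any stage failure is re-raised with the stage name and seed in the
    message. When ``out_dir`` is set, label volume, property maps, and a
    machine-readable manifest are written there.
    """
    cfg = validate_config(config)
    seed = int(cfg["seed"])
    rngs = _stage_rngs(seed)
    manifest: dict = {"seed": seed, "stages": {}}
    stage = "anatomy"
    try:
        t0 = time.perf_counter()
        if cfg["shape"]:
            shape = ShapeParams(**cfg["shape"])
        elif cfg["hemispherical"]:
            radius = float(SHAPE_PARAM_TABLE["a1t"][cfg["breast_type"]]
                           .sample(rngs["anatomy"]))
            shape = ShapeParams.hemisphere(radius)
        else:
            shape = sample_shape_params(cfg["breast_type"], rngs["anatomy"])
        vol = generate_fixture_anatomy(
            shape, cfg["breast_type"], cfg["voxel_size_mm"], rngs["anatomy"],
            skin_thickness=cfg["skin_thickness_mm"])
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0,
                                     "dims": list(vol.dims)}

        stage = "trees"
        t0 = time.perf_counter()
        if cfg["vessel_trees"].get("enabled", True):
            overrides = {k: v for k, v in cfg["vessel_trees"].items()
                         if k != "enabled"}
            vol = grow_vessel_trees(vol, VesselTreeConfig(**overrides)
                                    if overrides else None, rngs["trees"])
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}

        stage = "subskin"
        t0 = time.perf_counter()
        if cfg["subskin"].get("enabled", True):
            sub = cfg["subskin"]
            params = SubskinParams(
                sigma1=sub["sigma1_mm"], sigma2=sub["sigma2_mm"],
                sigma3=sub["sigma3_mm"], depth=sub["depth_mm"],
                xor_mode=sub["xor_mode"])
            mask_no_skin = ~np.isin(
                vol.labels,
                np.array((L.WATER, L.SKIN, L.NIPPLE), dtype=np.uint8))
            art, vein = generate_subskin_vessels(
                mask_no_skin, params, vol.voxel_size, rngs["subskin"])
            vol = embed_subskin_vessels(vol, art, vein)
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}

        stage = "lesion"
        t0 = time.perf_counter()
        les = cfg["lesions"]
        if les["count"] > 0:
            rng = rngs["lesion"]
            phantoms = []
            extents = []
            for d in les["diameters_mm"][: les["count"]]:
                vtc = generate_vtc_mask(d, les["irregularity"],
                                        cfg["voxel_size_mm"], rng)
                if les["with_core_and_pa"]:
                    lp = add_necrosis_and_pa(
                        vtc, les["erosion_radius_mm"], les["dilation_radius_mm"],
                        cfg["voxel_size_mm"])
                else:
                    from .lesion import LesionPhantom, VTC_CODE, _feret_diameter
                    mask = np.zeros(vtc.shape, dtype=np.uint8)
                    mask[vtc] = VTC_CODE
                    lp = LesionPhantom(mask, cfg["voxel_size_mm"],
                                       _feret_diameter(vtc, cfg["voxel_size_mm"]),
                                       False)
                phantoms.append(lp)
                ext = lp.nominal_diameter
                if les["with_core_and_pa"]:
                    ext += 2 * les["dilation_radius_mm"]
                extents.append(ext)
            sites = select_insertion_sites(vol, les["count"], extents, rng)
            for lp, site in zip(phantoms, sites):
                vol = insert_lesion(vol, lp, site)
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}
        manifest["lesions"] = vol.meta.get("lesions", [])

        stage = "functional"
        t0 = time.perf_counter()
        fn = cfg["functional"]
        functional = assemble_functional_maps(
            vol, rngs["functional"], mu_s=fn["mu_s"], mu_fb=fn["mu_fb"],
            tol=fn["pde_tolerance"])
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0,
                                     "ctHb_blood_uM": functional.ctHb_blood}

        stage = "optical"
        t0 = time.perf_counter()
        optical = assemble_optical_maps(
            vol, functional, cfg["wavelengths_nm"], rngs["optical"])
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}

        stage = "acoustic"
        t0 = time.perf_counter()
        acoustic = assemble_acoustic_maps(vol, cfg["breast_type"],
                                          rngs["acoustic"])
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0,
                                     "y": acoustic.y}
    except PhantomError as exc:
        raise type(exc)(
            f"stage {stage!r} failed for seed {seed}: {exc}") from exc

    manifest["config"] = cfg
    bundle = PhantomBundle(volume=vol, functional=functional, optical=optical,
                           acoustic=acoustic, config=cfg, seed=seed,
                           manifest=manifest)
    if cfg["out_dir"]:
        _export(bundle, Path(cfg["out_dir"]))
    return bundle


def _export(bundle: PhantomBundle, out_dir: Path) -> None:
    from .io import write_float_map, write_label_volume, write_label_volume_nifti

    out_dir.mkdir(parents=True, exist_ok=True)
    h = bundle.volume.voxel_size
    write_label_volume(bundle.volume, out_dir / "labels.raw")
    for name in ("s", "fb", "fw", "ff", "fm"):
        write_float_map(getattr(bundle.functional, name), h,
                        out_dir / f"functional_{name}.raw", units="%", name=name)
    for i, wl in enumerate(bundle.optical.wavelengths):
        write_float_map(bundle.optical.mua[i], h,
                        out_dir / f"mua_{wl:.0f}nm.raw", units="1/mm", name="mua")
        write_float_map(bundle.optical.mus[i], h,
                        out_dir / f"mus_{wl:.0f}nm.raw", units="1/mm", name="mus")
    write_float_map(bundle.optical.g, h, out_dir / "g.raw", name="g")
    write_float_map(bundle.optical.n, h, out_dir / "n.raw", name="n")
    write_float_map(bundle.acoustic.c, h, out_dir / "c.raw", units="mm/us",
                    name="c")
    write_float_map(bundle.acoustic.rho, h, out_dir / "rho.raw", units="g/mm3",
                    name="rho")
    write_float_map(bundle.acoustic.alpha0, h, out_dir / "alpha0.raw",
                    units="dB/MHz^y mm", name="alpha0")
    if bundle.config.get("export_nifti"):
        write_label_volume_nifti(bundle.volume, out_dir / "labels.nii.gz")
    if bundle.config.get("export_hdf5"):
        _export_hdf5(bundle, out_dir / "bundle.h5")
    manifest = dict(bundle.manifest)
    manifest["acoustic_y"] = bundle.acoustic.y
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      default=str))


def _export_hdf5(bundle: PhantomBundle, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["voxel_size_mm"] = bundle.volume.voxel_size
        f.attrs["seed"] = bundle.seed
        f.attrs["acoustic_y"] = bundle.acoustic.y
        f.create_dataset("labels", data=bundle.volume.labels,
                         compression="gzip")
        for name in ("s", "fb", "fw", "ff", "fm"):
            f.create_dataset(f"functional/{name}",
                             data=getattr(bundle.functional, name),
                             compression="gzip")
        f.create_dataset("optical/wavelengths_nm",
                         data=np.array(bundle.optical.wavelengths))
        f.create_dataset("optical/mua", data=bundle.optical.mua,
                         compression="gzip")
        f.create_dataset("optical/mus", data=bundle.optical.mus,
                         compression="gzip")
        f.create_dataset("optical/g", data=bundle.optical.g, compression="gzip")
        f.create_dataset("optical/n", data=bundle.optical.n, compression="gzip")
        for name in ("c", "rho", "alpha0"):
            f.create_dataset(f"acoustic/{name}",
                             data=getattr(bundle.acoustic, name),
                             compression="gzip")
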