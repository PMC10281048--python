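"""Configuration validation and defaults for the generation pipeline."""

from __future__ import annotations

import copy

from .errors import InvalidArgumentError

__all__ = ["DEFAULT_CONFIG", "validate_config"]

DEFAULT_CONFIG: dict = {
    "breast_type": "C",
    "voxel_size_mm": 0.125,
    "seed": 0,
    "wavelengths_nm": [757.0, 800.0, 850.0],
    "shape": None,              # optional dict of ShapeParams overrides
    "hemispherical": False,     # cup-stabilized hemispherical shape
    "skin_thickness_mm": 1.5,
    "vessel_trees": {"enabled": True},   # plus VesselTreeConfig overrides
    "subskin": {
        "enabled": True,
        "sigma1_mm": 3.875,
        "sigma2_mm": 6.125,
        "sigma3_mm": 0.219,
        "depth_mm": 0.375,
        "xor_mode": "intersection",
    },
    "lesions": {
        "count": 0,
        "diameters_mm": [],
        "irregularity": 0.5,
        "with_core_and_pa": False,
        "erosion_radius_mm": 0.75,
        "dilation_radius_mm": 5.0,
    },
    "functional": {"mu_s": 4.0, "mu_fb": 4.0, "pde_tolerance": 1e-8},
    "out_dir": None,
    "export_nifti": False,
    "export_hdf5": False,
}

_NIR_RANGE = (700.0, 1100.0)


def validate_config(config: dict | None) -> dict:
    """Fill defaults and check units/ranges; raises one aggregated
    InvalidArgumentError naming every offending key."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    errors: list[str] = []
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            errors.append(f"unknown config keys: {sorted(unknown)}")
        for k, v in config.items():
            if k in cfg and isinstance(cfg[k], dict) and isinstance(v, dict):
                sub_unknown = set(v) - set(cfg[k])
                if sub_unknown:
                    errors.append(f"unknown keys in {k!r}: {sorted(sub_unknown)}")
                cfg[k].update({kk: vv for kk, vv in v.items() if kk in cfg[k]})
            elif k in cfg:
                cfg[k] = v

    if cfg["breast_type"] not in ("A", "B", "C", "D"):
        errors.append(f"breast_type must be one of A-D, got {cfg['breast_type']!r}")
    if not isinstance(cfg["voxel_size_mm"], (int, float)) or cfg["voxel_size_mm"] <= 0:
        errors.append(f"voxel_size_mm must be > 0, got {cfg['voxel_size_mm']!r}")
    for wl in cfg["wavelengths_nm"]:
        if not (_NIR_RANGE[0] <= wl <= _NIR_RANGE[1]):
            errors.append(
                f"wavelength {wl} nm outside the NIR support "
                f"{_NIR_RANGE[0]:.0f}-{_NIR_RANGE[1]:.0f} nm")
    les = cfg["lesions"]
    if les["count"] < 0:
        errors.append("lesions.count must be >= 0")
    if les["count"] > 0 and len(les["diameters_mm"]) < les["count"]:
        errors.append("lesions.diameters_mm must list one diameter per lesion")
    if any(d <= 0 for d in les["diameters_mm"]):
        errors.append("lesion diameters must be positive")
    sub = cfg["subskin"]
    if not (0 < sub["sigma1_mm"] < sub["sigma2_mm"]):
        errors.append("subskin: need 0 < sigma1_mm < sigma2_mm")
    if sub["sigma3_mm"] <= 0:
        errors.append("subskin.sigma3_mm must be > 0")
    fn = cfg["functional"]
    if fn["mu_s"] <= 0 or fn["mu_fb"] <= 0:
        errors.append("functional.mu_s and mu_fb must be > 0")

    if errors:
        raise InvalidArgumentError("invalid configuration:\n  " +
                                   "\n  ".join(errors))
    return cfg
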