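"""Tissue codes used in anatomical label volumes.

Codes are unsigned 8-bit. Code 0 is the water background (the breast is
imaged immersed in a water bowl). Muscle is defined for compatibility with
externally produced volumes but the built-in fixture generator never emits
it (the chest-muscle region is cropped before property assignment).
"""

from __future__ import annotations

WATER = 0
FAT = 1
SKIN = 2
GLANDULAR = 3
NIPPLE = 4
MUSCLE = 5
LIGAMENT = 6
TDLU = 7
DUCT = 8
ARTERY = 9
VEIN = 10
VTC = 11
NECROTIC_CORE = 12
PA = 13

LABEL_TABLE: dict[int, str] = {
    WATER: "water",
    FAT: "fat",
    SKIN: "skin",
    GLANDULAR: "glandular",
    NIPPLE: "nipple",
    MUSCLE: "muscle",
    LIGAMENT: "ligament",
    TDLU: "TDLU",
    DUCT: "duct",
    ARTERY: "artery",
    VEIN: "vein",
    VTC: "VTC",
    NECROTIC_CORE: "necrotic_core",
    PA: "PA",
}

NAME_TO_CODE: dict[str, int] = {v: k for k, v in LABEL_TABLE.items()}

#: Vessel labels.
VESSEL_CODES = (ARTERY, VEIN)

#: Codes a grown or embedded vessel may overwrite.
VESSEL_OVERWRITABLE = (FAT, GLANDULAR, LIGAMENT)

#: Codes a lesion may overwrite on insertion.
LESION_OVERWRITABLE = (FAT, GLANDULAR, LIGAMENT, TDLU, DUCT)

#: Codes that must never be overwritten by vessels or lesions.
PROTECTED_CODES = (WATER, SKIN, NIPPLE, MUSCLE)

#: Lesion compartment codes.
LESION_CODES = (VTC, NECROTIC_CORE, PA)
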