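"""Reading and writing label volumes and property maps.

Label volumes travel as headerless unsigned-8-bit raw payloads in
x-fastest order with a JSON sidecar (dims, voxel size, origin, label
table), which matches the raw-volume dialect emitted by anatomy engines
in this lineage; NIfTI export via nibabel is supported for interoperable
tooling. Float property maps use the same raw+sidecar layout with 32-bit
floats, and a whole phantom bundle can be stored as a single HDF5 file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import labels as L
from .anatomy import LabelVolume
from .errors import CorruptInputError, UnknownLabelError

__all__ = [
    "write_label_volume",
    "read_label_volume",
    "write_label_volume_nifti",
    "read_label_volume_nifti",
    "write_float_map",
    "read_float_map",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_label_volume(volume: LabelVolume, path) -> None:
    """Write a raw uint8 payload (x fastest) plus a JSON sidecar."""
    path = Path(path)
    data = volume.labels.flatten(order="F")  # axis 0 (x) fastest
    path.write_bytes(data.tobytes())
    sidecar = {
        "dims": list(volume.dims),
        "voxel_size_mm": volume.voxel_size,
        "origin_mm": list(volume.origin),
        "dtype": "uint8",
        "order": "x-fastest",
        "label_table": {str(k): v for k, v in volume.label_table.items()},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_label_volume(path, metadata: dict | None = None) -> LabelVolume:
    """Read a raw uint8 label volume.

    ``metadata`` overrides the sidecar; it must provide ``dims`` and
    ``voxel_size_mm`` when no sidecar exists.
    """
    path = Path(path)
    if metadata is None:
        side = _sidecar_path(path)
        if not side.exists():
            raise CorruptInputError(f"no sidecar found for {path}")
        metadata = json.loads(side.read_text())
    dims = tuple(int(d) for d in metadata["dims"])
    voxel = float(metadata["voxel_size_mm"])
    origin = tuple(metadata.get("origin_mm", (0.0, 0.0, 0.0)))
    table = {int(k): v for k, v in metadata.get(
        "label_table", {str(k): v for k, v in L.LABEL_TABLE.items()}).items()}
    payload = np.fromfile(path, dtype=np.uint8)
    n_expected = int(np.prod(dims))
    if payload.size != n_expected:
        raise CorruptInputError(
            f"{path}: payload holds {payload.size} voxels, sidecar dims "
            f"{dims} require {n_expected}"
        )
    labels = payload.reshape(dims, order="F")
    present = np.unique(labels)
    for code in present:
        if int(code) not in table:
            raise UnknownLabelError(int(code))
    return LabelVolume(voxel, origin, labels, table)


def write_label_volume_nifti(volume: LabelVolume, path) -> None:
    import nibabel as nib

    affine = np.diag([volume.voxel_size] * 3 + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.labels.astype(np.uint8), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_label_volume_nifti(path) -> LabelVolume:
    import nibabel as nib

    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.uint8)
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise CorruptInputError("anisotropic voxels are not supported")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    vol = LabelVolume(float(zooms[0]), origin, labels)
    vol.validate()
    return vol


def write_float_map(array: np.ndarray, voxel_size: float, path,
                    units: str = "", name: str = "") -> None:
    path = Path(path)
    arr = np.asarray(array, dtype=np.float32)
    path.write_bytes(arr.flatten(order="F").tobytes())
    sidecar = {
        "dims": list(arr.shape),
        "voxel_size_mm": voxel_size,
        "dtype": "float32",
        "order": "x-fastest",
        "units": units,
        "name": name,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_float_map(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    dims = tuple(int(d) for d in meta["dims"])
    payload = np.fromfile(path, dtype=np.float32)
    if payload.size != int(np.prod(dims)):
        raise CorruptInputError(f"{path}: payload size mismatch")
    return payload.reshape(dims, order="F"), meta
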