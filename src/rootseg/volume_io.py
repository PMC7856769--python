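"""Volumetric image containers and file I/O.

Conventions used throughout the package
---------------------------------------
* Arrays are indexed ``(x, y, z)``; after anatomical alignment ``z`` is the
  occluso-apical axis (+z occlusal).
* Voxels are isotropic; sizes are in micrometres (μm).  The physical
  coordinate of voxel ``(i, j, k)`` is ``(i, j, k) * voxel_size`` at the voxel
  centre, 0-based (see :func:`voxel_centers_um`, the single source of truth).
* NIfTI (``.nii``/``.nii.gz``) is the canonical on-disk format because it
  carries spacing metadata; multi-page TIFF stacks are supported for import
  with an explicit voxel size.  Label maps store their legend in a JSON
  sidecar ``<file>.labels.json``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .errors import VolumeIOError

#: Roles a label may carry in a :class:`LabelMap` legend.
ROLES = frozenset(
    {
        "air",
        "bone",
        "molar",
        "spring",
        "crown",
        "root_mesial",
        "root_distal",
        "root_palatal",
    }
)

#: Roles whose union constitutes the first molar (crown + named roots).
MOLAR_ROLES = frozenset({"molar", "crown", "root_mesial", "root_distal", "root_palatal"})

ROOT_ROLES = ("root_mesial", "root_distal", "root_palatal")


def voxel_centers_um(indices: np.ndarray, voxel_size: float) -> np.ndarray:
    """Physical coordinates (μm) of voxel centres for 0-based ``indices``.

    This helper is the package-wide definition of the grid-to-physical
    mapping: coordinate = index × voxel_size.
    """
    return np.asarray(indices, dtype=float) * float(voxel_size)


@dataclass
class Volume3D:
    """A 3-D scalar intensity grid with isotropic voxel size in μm."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise VolumeIOError(f"volume must be 3-D, got shape {self.data.shape}")
        if not (math.isfinite(self.voxel_size) and self.voxel_size > 0):
            raise VolumeIOError(f"voxel_size must be positive and finite, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise VolumeIOError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclass
class LabelMap:
    """Integer segmentation on the same grid as a companion :class:`Volume3D`.

    Label 0 is reserved for unassigned/air.  ``legend`` maps every nonzero
    label id to one role from :data:`ROLES` (several labels may share a role,
    e.g. two teeth both carrying role ``molar``).
    """

    labels: np.ndarray
    legend: dict[int, str]
    voxel_size: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise VolumeIOError(f"label map must be 3-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise VolumeIOError("label map must have an integer dtype")
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        if 0 in self.legend and self.legend[0] != "air":
            raise VolumeIOError("label 0 is reserved for unassigned/air")
        bad_roles = set(self.legend.values()) - ROLES
        if bad_roles:
            raise VolumeIOError(f"unknown roles in legend: {sorted(bad_roles)}")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            raise VolumeIOError(f"labels missing from legend: {sorted(missing)}")
        if not (math.isfinite(self.voxel_size) and self.voxel_size > 0):
            raise VolumeIOError(f"voxel_size must be positive and finite, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    def labels_for_role(self, *roles: str) -> list[int]:
        return sorted(k for k, v in self.legend.items() if v in roles)

    def mask_for_role(self, *roles: str) -> np.ndarray:
        """Boolean mask of all voxels whose label carries one of ``roles``."""
        ids = self.labels_for_role(*roles)
        if not ids:
            return np.zeros(self.labels.shape, dtype=bool)
        return np.isin(self.labels, ids)

    def molar_mask(self) -> np.ndarray:
        """Mask of the first molar: crown, generic molar and named roots."""
        return self.mask_for_role(*MOLAR_ROLES)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_TIFF_SUFFIXES = (".tif", ".tiff")


def _has_suffix(path: Path, suffixes: tuple[str, ...]) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in suffixes)


def _nifti_voxel_size_um(img) -> float | None:
    zoom = float(img.header.get_zooms()[0])
    if zoom <= 0:
        return None
    units = img.header.get_xyzt_units()[0]
    if units == "micron":
        return zoom
    if units == "mm":
        return zoom * 1000.0
    if units == "meter":
        return zoom * 1e6
    # unknown units: a 1.0 zoom is nibabel's placeholder, treat as absent
    return None if zoom == 1.0 else zoom


def read_volume(path, voxel_size_um: float | None = None) -> Volume3D:
    """Read a NIfTI file or multi-page TIFF stack into a :class:`Volume3D`.

    Voxel size is taken from file metadata when present; otherwise
    ``voxel_size_um`` must be supplied.  If both are present and differ by
    more than 1 %, the conflict is an error.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    if _has_suffix(path, _NIFTI_SUFFIXES):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        meta_vs = _nifti_voxel_size_um(img)
    elif _has_suffix(path, _TIFF_SUFFIXES):
        import tifffile

        stack = tifffile.imread(str(path))
        if stack.ndim != 3:
            raise VolumeIOError(f"TIFF stack in {path} is not 3-D (shape {stack.shape})")
        # stacks are written page-major (z, y, x); restore (x, y, z)
        data = np.ascontiguousarray(stack.transpose(2, 1, 0))
        meta_vs = None
    else:
        raise VolumeIOError(f"unrecognised volume format: {path}")
    if data.ndim != 3:
        raise VolumeIOError(f"{path} does not contain a 3-D volume (shape {data.shape})")

    if meta_vs is None and voxel_size_um is None:
        raise VolumeIOError(f"voxel size unknown for {path}: file carries no spacing metadata")
    if meta_vs is not None and voxel_size_um is not None:
        if abs(meta_vs - voxel_size_um) > 0.01 * meta_vs:
            raise VolumeIOError(
                f"voxel size conflict for {path}: metadata {meta_vs} μm vs argument {voxel_size_um} μm"
            )
    voxel = meta_vs if meta_vs is not None else float(voxel_size_um)
    return Volume3D(data=data, voxel_size=voxel)


def _sidecar_path(path: Path) -> Path:
    return path.parent / (path.name + ".labels.json")


def write_volume(obj: Volume3D | LabelMap, path) -> None:
    """Write a volume or label map; lossless round-trip for integer data.

    Integer intensities are stored as uint16 (μCT native range), floats as
    float32.  Label maps additionally get a JSON legend sidecar.
    """
    path = Path(path)
    if not path.parent.exists():
        raise VolumeIOError(f"parent directory does not exist: {path.parent}")
    is_labels = isinstance(obj, LabelMap)
    data = obj.labels if is_labels else obj.data
    if is_labels:
        out = np.asarray(data, dtype=np.int32)
    elif np.issubdtype(data.dtype, np.integer):
        if data.min() < 0 or data.max() > np.iinfo(np.uint16).max:
            out = np.asarray(data, dtype=np.int32)
        else:
            out = np.asarray(data, dtype=np.uint16)
    else:
        out = np.asarray(data, dtype=np.float32)

    if _has_suffix(path, _NIFTI_SUFFIXES):
        import nibabel as nib

        affine = np.diag([obj.voxel_size, obj.voxel_size, obj.voxel_size, 1.0])
        img = nib.Nifti1Image(out, affine)
        img.header.set_zooms((obj.voxel_size,) * 3)
        img.header.set_xyzt_units(xyz="micron")
        nib.save(img, str(path))
    elif _has_suffix(path, _TIFF_SUFFIXES):
        import tifffile

        tifffile.imwrite(str(path), np.ascontiguousarray(out.transpose(2, 1, 0)), photometric="minisblack")
    else:
        raise VolumeIOError(f"unrecognised output format: {path}")

    if is_labels:
        sidecar = {"voxel_size_um": obj.voxel_size, "legend": {str(k): v for k, v in obj.legend.items()}}
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_labels(path, voxel_size_um: float | None = None) -> LabelMap:
    """Read a label map written by :func:`write_volume` (legend from sidecar)."""
    path = Path(path)
    vol = read_volume(path, voxel_size_um=voxel_size_um)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise VolumeIOError(f"label legend sidecar missing: {sidecar}")
    meta = json.loads(sidecar.read_text())
    legend = {int(k): v for k, v in meta["legend"].items()}
    return LabelMap(labels=np.asarray(vol.data, dtype=np.int32), legend=legend, voxel_size=vol.voxel_size)


def write_measurements(result, path) -> None:
    """Serialize a measurement object to CSV with a JSON mirror.

    ``result`` must provide ``to_records()`` (list of flat dicts, one row per
    root/quantity) and ``to_dict()`` (nested JSON form).  The JSON mirror is
    written next to the CSV with a ``.json`` suffix.
    """
    import pandas as pd

    path = Path(path)
    if not path.parent.exists():
        raise VolumeIOError(f"parent directory does not exist: {path.parent}")
    records = result.to_records()
    pd.DataFrame.from_records(records).to_csv(path, index=False, float_format="%.10g")
    json_path = path.with_suffix(".json")
    json_path.write_text(json.dumps(result.to_dict(), indent=2, sort_keys=True))
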