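"""Volume containers and file I/O.

The in-memory unit is :class:`VolumeImage`: a 3-D scalar grid with per-axis
voxel spacing (mm) and a world origin at the *center* of voxel ``(0, 0, 0)``
(0-based indices).  The world coordinate of voxel index ``k`` along an axis is
``origin + k * spacing`` — every physical distance in the package is derived
from this convention, and anisotropic spacing is supported throughout.

Supported on-disk formats:

* MetaImage (``.mhd`` / ``.mha``) via SimpleITK — spacing/origin in the native
  header, the unit tag in a custom header field;
* NIfTI (``.nii`` / ``.nii.gz``) via nibabel — spacing on the affine diagonal,
  the unit tag in ``descrip``;
* multi-page TIFF via tifffile, with a required plain-text sidecar
  (``<stem>.spacing.txt``, ``key = value`` lines) because TIFF has no standard
  3-D spacing field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import tifffile

from .errors import MetadataError, ParameterError

__all__ = [
    "VolumeImage",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "block_average_resample",
]

_UNIT_TAGS = ("intensity", "g/cc", "label")


@dataclass
class VolumeImage:
    """3-D scalar grid with physical metadata.

    Parameters
    ----------
    voxels
        3-D array; axis order matches ``spacing``.
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        World position (mm) of the center of voxel (0, 0, 0).
    unit_tag
        One of ``"intensity"`` (raw scanner units), ``"g/cc"`` (mapped
        density) or ``"label"`` (integer segmentation).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit_tag: str = "intensity"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ParameterError("voxels must be a non-empty 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.unit_tag not in _UNIT_TAGS:
            raise ParameterError(f"unit_tag must be one of {_UNIT_TAGS}, got {self.unit_tag!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """World positions (mm) of 0-based voxel indices, shape (n, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def same_grid(self, other: "VolumeImage") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class LabelVolume(VolumeImage):
    """Integer segmentation on the same grid semantics; 0 is background."""

    unit_tag: str = "label"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if not np.issubdtype(self.voxels.dtype, np.integer):
            rounded = np.rint(self.voxels)
            if not np.array_equal(rounded, self.voxels):
                raise ParameterError("labels must be integers")
            self.voxels = rounded.astype(np.int32)
        if self.voxels.min() < 0:
            raise ParameterError("labels must be non-negative")
        super().__post_init__()

    def mask(self, *labels: int) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given labels."""
        return np.isin(self.voxels, labels)


# ---------------------------------------------------------------------------
# file formats


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".mhd", ".mha")):
        return "metaimage"
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff"
    raise ParameterError(f"cannot infer volume format from {path.name!r}")


def _sidecar_path(path: Path) -> Path:
    stem = path.name
    for suf in (".tif", ".tiff"):
        if stem.lower().endswith(suf):
            stem = stem[: -len(suf)]
            break
    return path.with_name(stem + ".spacing.txt")


def read_volume(path: str | Path, format: str | None = None) -> VolumeImage:
    """Read a volume with its physical metadata.

    ``format`` is one of ``"metaimage"``, ``"nifti"``, ``"tiff"``; when None it
    is inferred from the file extension.  TIFF stacks require the
    ``<stem>.spacing.txt`` sidecar; a missing sidecar or a sidecar without a
    ``spacing`` entry raises :class:`MetadataError`.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = (format or _detect_format(path)).lower()

    if fmt == "metaimage":
        img = sitk.ReadImage(str(path))
        voxels = sitk.GetArrayFromImage(img)  # (z, y, x)
        spacing = tuple(reversed(img.GetSpacing()))
        origin = tuple(reversed(img.GetOrigin()))
        unit = img.GetMetaData("unit_tag") if img.HasMetaDataKey("unit_tag") else "intensity"
        return VolumeImage(voxels, spacing, origin, unit)

    if fmt == "nifti":
        img = nib.load(str(path))
        voxels = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        if any(z <= 0 for z in zooms):
            raise MetadataError(f"non-positive spacing in NIfTI header: {zooms}")
        origin = tuple(float(v) for v in img.affine[:3, 3])
        descrip = img.header["descrip"].item().decode(errors="ignore")
        unit = descrip if descrip in _UNIT_TAGS else "intensity"
        return VolumeImage(voxels, tuple(float(z) for z in zooms), origin, unit)

    if fmt == "tiff":
        voxels = tifffile.imread(str(path))
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise MetadataError(
                f"TIFF stack {path.name} has no spacing sidecar {sidecar.name}; "
                "field 'spacing' is required"
            )
        meta: dict[str, str] = {}
        for line in sidecar.read_text().splitlines():
            if "=" in line:
                key, _, val = line.partition("=")
                meta[key.strip()] = val.strip()
        if "spacing" not in meta:
            raise MetadataError(f"sidecar {sidecar.name} lacks required field 'spacing'")
        spacing = tuple(float(v) for v in meta["spacing"].split(","))
        origin = tuple(float(v) for v in meta.get("origin", "0,0,0").split(","))
        unit = meta.get("unit_tag", "intensity")
        return VolumeImage(voxels, spacing, origin, unit)

    raise ParameterError(f"unknown format {fmt!r}")


def write_volume(vol: VolumeImage, path: str | Path, format: str | None = None) -> None:
    """Write a volume so that :func:`read_volume` round-trips it."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    fmt = (format or _detect_format(path)).lower()

    if fmt == "metaimage":
        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels))
        img.SetSpacing(tuple(reversed(vol.spacing)))
        img.SetOrigin(tuple(reversed(vol.origin)))
        img.SetMetaData("unit_tag", vol.unit_tag)
        sitk.WriteImage(img, str(path))
        return

    if fmt == "nifti":
        affine = np.diag(list(vol.spacing) + [1.0])
        affine[:3, 3] = vol.origin
        img = nib.Nifti1Image(np.asarray(vol.voxels), affine)
        img.header["descrip"] = vol.unit_tag.encode()
        nib.save(img, str(path))
        return

    if fmt == "tiff":
        tifffile.imwrite(str(path), np.asarray(vol.voxels))
        _sidecar_path(path).write_text(
            "spacing = {}\norigin = {}\nunit_tag = {}\n".format(
                ",".join(repr(s) for s in vol.spacing),
                ",".join(repr(o) for o in vol.origin),
                vol.unit_tag,
            )
        )
        return

    raise ParameterError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# resampling


def block_average_resample(vol: VolumeImage, factor: int | tuple[int, int, int]) -> VolumeImage:
    """Downsample by averaging non-overlapping blocks.

    Each output voxel is the arithmetic mean of its source block; trailing
    partial blocks are averaged over the voxels actually available.  Output
    spacing is input spacing times the factor, and the origin moves to the
    center of the first block.  This is the partial-volume model: structures
    smaller than the output voxel are blended with their surroundings.
    """
    factors = (factor,) * 3 if np.isscalar(factor) else tuple(factor)
    if len(factors) != 3 or any(int(f) != f or f < 1 for f in factors):
        raise ParameterError(f"factor must be integers >= 1 per axis, got {factor}")
    factors = tuple(int(f) for f in factors)

    data = vol.voxels.astype(np.float64)
    for ax, f in enumerate(factors):
        if f == 1:
            continue
        starts = np.arange(0, data.shape[ax], f)
        sums = np.add.reduceat(data, starts, axis=ax)
        counts = np.diff(np.append(starts, data.shape[ax]))
        shape = [1, 1, 1]
        shape[ax] = -1
        data = sums / counts.reshape(shape)

    spacing = tuple(s * f for s, f in zip(vol.spacing, factors))
    origin = tuple(o + (f - 1) / 2 * s for o, s, f in zip(vol.origin, vol.spacing, factors))
    return VolumeImage(data, spacing, origin, vol.unit_tag)
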