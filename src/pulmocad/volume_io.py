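"""CT volume I/O, resampling, intensity standardization and patch extraction.

Conventions
-----------
Voxel grids are indexed ``(z, y, x)``, 0-based; ``spacing`` and ``origin``
follow the same axis order in millimetres.  Annotation CSVs use the public
LUNA16/TIANCHI dialect: world-millimetre coordinates in ``(x, y, z)`` order
with columns ``seriesuid,coordX,coordY,coordZ,diameter_mm``.  Patch shapes
are stated ``(x, y, z)`` — the convention the patch size 40x40x26 is quoted
in — and converted internally.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "CTVolume",
    "AnnotationRecord",
    "Patch",
    "read_metaimage",
    "write_metaimage",
    "resample_isotropic",
    "standardize_intensity",
    "extract_patch",
    "read_annotations",
]

#: Hounsfield value of air, the default padding for out-of-grid voxels.
AIR_HU = -1000.0


class FormatError(ValueError):
    """Raised for malformed files (headers, CSVs)."""


@dataclass
class CTVolume:
    """A 3D scalar volume with geometric metadata.

    Parameters
    ----------
    voxels
        3D array indexed ``(z, y, x)``; converted to float64 on construction.
    spacing
        Millimetres per voxel along ``(z, y, x)``; strictly positive.
    origin
        World-coordinate offset of voxel ``(0, 0, 0)`` in mm, ``(z, y, x)``.
    series_id
        Opaque identifier used to join annotations to volumes.
    """

    voxels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    series_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxel grid must be rank 3, got rank {self.voxels.ndim}")
        if min(self.voxels.shape) < 1:
            raise ValueError(f"all dims must be >= 1, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components (z, y, x)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def voxel_to_world(self, index: Sequence[float]) -> np.ndarray:
        """World mm coordinate (z, y, x) of a (possibly fractional) index."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def world_to_voxel(self, world: Sequence[float]) -> np.ndarray:
        """Continuous (z, y, x) index of a world mm coordinate."""
        return (np.asarray(world, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class AnnotationRecord:
    """One nodule annotation: world-mm center (x, y, z) and diameter."""

    series_id: str
    center: tuple  # (x, y, z) world mm, LUNA16 dialect
    diameter_mm: float

    def __post_init__(self) -> None:
        self.center = tuple(float(c) for c in self.center)
        self.diameter_mm = float(self.diameter_mm)
        if not all(np.isfinite(self.center)):
            raise ValueError(f"center must be finite, got {self.center}")
        if not self.diameter_mm > 0:
            raise ValueError(f"diameter_mm must be > 0, got {self.diameter_mm}")


#: Default patch shape in (x, y, z) order: the 40x40x26 block that fully
#: contains nodules up to 30 mm at ~1 mm resolution.
DEFAULT_PATCH_SHAPE_XYZ = (40, 40, 26)


@dataclass
class Patch:
    """A fixed-size block cut from a volume, optionally with a label mask."""

    voxels: np.ndarray  # (z, y, x)
    source_series: str = ""
    source_center: tuple = (0, 0, 0)  # (z, y, x) voxel index in the source
    label: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.label is not None:
            self.label = np.asarray(self.label)
            if self.label.shape != self.voxels.shape:
                raise ValueError(
                    f"label shape {self.label.shape} != voxels shape {self.voxels.shape}"
                )


# ---------------------------------------------------------------------------
# MetaImage I/O
# ---------------------------------------------------------------------------

def read_metaimage(path: str | os.PathLike) -> CTVolume:
    """Read a MetaImage (.mhd + .raw) volume.

    SimpleITK reports spacing/origin in (x, y, z); they are reversed here to
    the package's (z, y, x) convention.  Voxel values are converted to
    float64 regardless of the stored element type.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"MetaImage header not found: {path}")
    _check_element_data_file(path)
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # pragma: no cover - SimpleITK error text varies
        raise FormatError(f"cannot read MetaImage {path}: {exc}") from exc
    voxels = sitk.GetArrayFromImage(img).astype(np.float64)  # already (z, y, x)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    series_id = os.path.splitext(os.path.basename(path))[0]
    return CTVolume(voxels=voxels, spacing=spacing, origin=origin, series_id=series_id)


def _check_element_data_file(header_path: str) -> None:
    """Fail early, naming the missing .raw file, before SimpleITK does."""
    try:
        with open(header_path, "r") as fh:
            for line in fh:
                if line.strip().startswith("ElementDataFile"):
                    raw_name = line.split("=", 1)[1].strip()
                    if raw_name in ("LOCAL", "LIST"):
                        return
                    raw_path = os.path.join(os.path.dirname(header_path), raw_name)
                    if not os.path.exists(raw_path):
                        raise IOError(f"ElementDataFile not found: {raw_path}")
                    return
    except UnicodeDecodeError as exc:
        raise FormatError(f"not a MetaImage header: {header_path}") from exc


def write_metaimage(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a CTVolume as an uncompressed .mhd/.raw pair."""
    path = os.fspath(path)
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"directory does not exist: {parent}")
    img = sitk.GetImageFromArray(volume.voxels)
    img.SetSpacing(tuple(reversed(volume.spacing)))
    img.SetOrigin(tuple(reversed(volume.origin)))
    try:
        sitk.WriteImage(img, path, useCompression=False)
    except RuntimeError as exc:
        raise IOError(f"cannot write MetaImage {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Resampling and standardization
# ---------------------------------------------------------------------------

def resample_isotropic(
    volume: CTVolume, target_mm: float = 1.0, *, is_mask: bool = False
) -> CTVolume:
    """Resample to isotropic voxels of ``target_mm`` per side.

    Trilinear interpolation for intensity volumes, nearest-neighbour when
    ``is_mask`` is set.  Output dims are ``round(dim * spacing / target)``
    with a floor of 1, so the world extent is preserved to within one voxel.
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be > 0, got {target_mm}")
    from scipy import ndimage  # deferred: keeps module import light

    in_shape = np.array(volume.shape)
    in_spacing = np.array(volume.spacing)
    out_shape = np.maximum(np.round(in_shape * in_spacing / target_mm).astype(int), 1)
    factors = out_shape / in_shape
    out = ndimage.zoom(
        volume.voxels, factors, order=0 if is_mask else 1, mode="nearest"
    )
    assert out.shape == tuple(out_shape)
    return CTVolume(
        voxels=out.astype(np.float64),
        spacing=(target_mm,) * 3,
        origin=volume.origin,
        series_id=volume.series_id,
    )


def standardize_intensity(volume: CTVolume, mean: float, std: float) -> CTVolume:
    """Affine gray-value standardization ``(v - mean) / std``.

    ``mean``/``std`` are typically the training-set statistics (dataset-global
    mode); passing the volume's own statistics gives per-volume mode.
    """
    if std <= 0:
        raise ValueError(f"std must be > 0, got {std}")
    return CTVolume(
        voxels=(volume.voxels - float(mean)) / float(std),
        spacing=volume.spacing,
        origin=volume.origin,
        series_id=volume.series_id,
    )


def dataset_intensity_stats(volumes: Sequence[CTVolume]) -> tuple:
    """Pooled mean/std over a list of volumes (the dataset-global mode)."""
    n = sum(v.voxels.size for v in volumes)
    mean = sum(float(v.voxels.sum()) for v in volumes) / n
    ss = sum(float(((v.voxels - mean) ** 2).sum()) for v in volumes)
    return mean, float(np.sqrt(ss / n))


# ---------------------------------------------------------------------------
# Patch extraction
# ---------------------------------------------------------------------------

def extract_patch(
    volume: CTVolume,
    center: Sequence[int],
    shape: Sequence[int] = DEFAULT_PATCH_SHAPE_XYZ,
    pad_value: float = AIR_HU,
    label_volume: Optional[np.ndarray] = None,
) -> Patch:
    """Cut a fixed-size block centred on a voxel index.

    Parameters
    ----------
    center
        Voxel index ``(z, y, x)``; must lie inside the grid.
    shape
        Patch dims stated ``(x, y, z)`` per the field convention; the default
        is 40x40x26.  The centre voxel lands at ``floor(shape/2)``.
    pad_value
        Fill for out-of-grid voxels; defaults to air (-1000).
    label_volume
        Optional binary grid of the volume's shape; the matching block is
        stored as the patch label (padded with 0).
    """
    center = tuple(int(c) for c in center)
    vshape = volume.shape
    if any(c < 0 or c >= s for c, s in zip(center, vshape)):
        raise ValueError(f"center {center} outside grid of shape {vshape}")
    shape_zyx = tuple(int(s) for s in reversed(tuple(shape)))

    def _cut(arr: np.ndarray, fill: float) -> np.ndarray:
        out = np.full(shape_zyx, fill, dtype=arr.dtype if arr.dtype.kind == "f" else np.float64)
        src, dst = [], []
        for ax in range(3):
            half = shape_zyx[ax] // 2
            lo = center[ax] - half
            hi = lo + shape_zyx[ax]
            src.append(slice(max(lo, 0), min(hi, vshape[ax])))
            dst.append(slice(max(-lo, 0), shape_zyx[ax] - max(hi - vshape[ax], 0)))
        out[tuple(dst)] = arr[tuple(src)]
        return out

    label = None
    if label_volume is not None:
        label = _cut(np.asarray(label_volume, dtype=np.float64), 0.0) > 0.5
    return Patch(
        voxels=_cut(volume.voxels, float(pad_value)),
        source_series=volume.series_id,
        source_center=center,
        label=label,
    )


# ---------------------------------------------------------------------------
# Annotation CSV
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["seriesuid", "coordX", "coordY", "coordZ", "diameter_mm"]


def read_annotations(path: str | os.PathLike) -> list:
    """Read a LUNA16-dialect annotation CSV into AnnotationRecord objects.

    Malformed rows raise a FormatError naming the offending line number
    (1-based, counting the header as line 1).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"annotation file not found: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        line_no = int(i) + 2  # header is line 1
        try:
            records.append(
                AnnotationRecord(
                    series_id=str(row["seriesuid"]),
                    center=(float(row["coordX"]), float(row["coordY"]), float(row["coordZ"])),
                    diameter_mm=float(row["diameter_mm"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed row at line {line_no}: {exc}") from exc
    return records


def write_annotations(records: Sequence[AnnotationRecord], path: str | os.PathLike) -> None:
    """Write annotation records in the same CSV dialect read_annotations expects."""
    df = pd.DataFrame(
        [
            {
                "seriesuid": r.series_id,
                "coordX": r.center[0],
                "coordY": r.center[1],
                "coordZ": r.center[2],
                "diameter_mm": r.diameter_mm,
            }
            for r in records
        ],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(os.fspath(path), index=False)
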