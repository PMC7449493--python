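"""Four-step lung parenchyma segmentation.

Step 1 roughly segments the thoracic cavity: adaptive (Otsu) thresholding,
maximum-connectivity background removal, per-slice seed/hole filling.
Step 2 removes the airway: the main trachea by optimal-threshold region
growing with a leak-explosion stop rule, the bronchi by grayscale
closing-by-reconstruction.  Step 3 tests for left/right lung fusion
(component-area ratio against T = 4) and, when fused, separates the lungs
along the minimum of the vertical integral projection.  Step 4 repairs the
lung boundary with the rolling-ball method (disc closing, radius 12.5 mm),
restoring juxtapleural concavities.

Masks are boolean arrays in the package's (z, y, x) convention.  Component
connectivity is 26 in 3D and 8 in 2D throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from pulmocad.volume_io import CTVolume

__all__ = [
    "SegmentationConfig",
    "StageMasks",
    "SegmentationResult",
    "TracheaNotFoundError",
    "DegenerateVolumeError",
    "binarize_adaptive",
    "remove_background",
    "fill_body",
    "extract_main_trachea",
    "reconstruct_bronchi",
    "detect_fusion",
    "separate_lungs",
    "repair_boundary",
    "segment_lungs",
    "dice",
]

_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


class TracheaNotFoundError(RuntimeError):
    """No circular airway seed found in the top axial slices."""


class DegenerateVolumeError(ValueError):
    """The volume lacks the two intensity populations the pipeline assumes."""


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks (1.0 when both are empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)


@dataclass
class SegmentationConfig:
    """Tunables of the segmentation pipeline.

    fusion_threshold is the T of the fusion test (ratio of the two largest
    component areas); ball_radius_mm the rolling-ball radius.  The
    optimal-threshold growing raises the intensity threshold by
    growth_increment (HU) per iteration and stops when the grown volume
    jumps by more than growth_explosion_factor between iterations, or at
    growth_max_threshold.
    """

    fusion_threshold: float = 4.0
    fusion_mode: str = "ratio"  # or "absolute"
    ball_radius_mm: float = 12.5
    rolling_ball_3d: bool = False
    growth_explosion_factor: float = 1.5
    growth_increment: float = 20.0
    growth_max_threshold: float = -500.0
    closing_radius_mm: float = 3.0
    bronchi_diff_threshold: float = 100.0
    min_component_voxels: int = 64
    seed_top_slices: int = 3
    seed_min_area: int = 5
    seed_min_circularity: float = 0.5


@dataclass
class StageMasks:
    """Every intermediate mask of the pipeline, each of the volume's shape."""

    raw_threshold: np.ndarray
    background_removed: np.ndarray
    body_filled: np.ndarray
    trachea: np.ndarray
    bronchi: np.ndarray
    fused_check_input: np.ndarray
    separated: np.ndarray
    repaired: np.ndarray


@dataclass
class SegmentationResult:
    lung_mask: np.ndarray
    left_mask: np.ndarray
    right_mask: np.ndarray
    fused_detected: bool
    separation_line: dict  # z slice -> x column (empty when not fused)
    stages: StageMasks


# ---------------------------------------------------------------------------
# Step 1
# ---------------------------------------------------------------------------

def binarize_adaptive(volume: CTVolume) -> np.ndarray:
    """Threshold the volume with Otsu's between-class-variance criterion.

    The dark class (air + lung parenchyma) is the foreground: the returned
    mask marks voxels strictly below the computed threshold.
    """
    vox = volume.voxels
    if float(vox.max()) == float(vox.min()):
        raise DegenerateVolumeError("constant-intensity volume has no threshold")
    thr = threshold_otsu(vox, nbins=256)
    return vox < thr


def remove_background(mask: np.ndarray) -> np.ndarray:
    """Delete dark components connected to the lateral image border.

    The ambient air (and scanner tray) always reaches the x/y faces of an
    axial CT volume; anatomy cropped in z (trachea at the top slice) does
    not disqualify a component, so only lateral-face contact is tested.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    labels, n = ndimage.label(mask, structure=_STRUCT_3D)
    border = np.zeros(n + 1, dtype=bool)
    for face in (labels[:, 0, :], labels[:, -1, :], labels[:, :, 0], labels[:, :, -1]):
        border[np.unique(face)] = True
    border[0] = False
    keep = ~border[labels]
    return mask & keep


def fill_body(mask: np.ndarray, volume: Optional[CTVolume] = None) -> np.ndarray:
    """Fill per-slice holes (vessels, nodules) inside the retained components."""
    mask = np.asarray(mask, dtype=bool)
    out = np.empty_like(mask)
    for z in range(mask.shape[0]):
        out[z] = ndimage.binary_fill_holes(mask[z])
    return out


# ---------------------------------------------------------------------------
# Step 2
# ---------------------------------------------------------------------------

def _find_trachea_seed(rough_mask: np.ndarray, config: SegmentationConfig):
    """Most circular region of the rough mask in the top axial slices."""
    best = None
    for z in range(min(config.seed_top_slices, rough_mask.shape[0])):
        labels = measure.label(rough_mask[z], connectivity=2)
        for region in measure.regionprops(labels):
            if region.area < config.seed_min_area or region.perimeter <= 0:
                continue
            circ = 4.0 * np.pi * region.area / region.perimeter**2
            if circ < config.seed_min_circularity:
                continue
            if best is None or circ > best[0]:
                cy, cx = region.centroid
                best = (circ, (z, int(round(cy)), int(round(cx))))
    if best is None:
        raise TracheaNotFoundError("no circular airway seed in the top slices")
    return best[1]


def extract_main_trachea(
    volume: CTVolume,
    rough_mask: np.ndarray,
    config: Optional[SegmentationConfig] = None,
) -> np.ndarray:
    """Grow the main trachea from a top-slice seed by optimal thresholding.

    The intensity threshold is raised in steps of growth_increment; at each
    level the connected component (26-connectivity) of sub-threshold voxels
    containing the seed is the grown region.  Growth stops at the largest
    threshold for which the region volume does not jump by more than
    growth_explosion_factor between iterations — the classic leak test that
    keeps the growth from flooding the lung.
    """
    config = config or SegmentationConfig()
    seed = _find_trachea_seed(np.asarray(rough_mask, dtype=bool), config)
    vox = volume.voxels
    seed_val = float(vox[seed])
    best_region = None
    prev_volume = 0
    theta = seed_val + config.growth_increment
    while theta <= config.growth_max_threshold:
        dark = vox < theta
        if not dark[seed]:
            theta += config.growth_increment
            continue
        labels, _ = ndimage.label(dark, structure=_STRUCT_3D)
        region = labels == labels[seed]
        vol = int(region.sum())
        if prev_volume > 0 and vol > config.growth_explosion_factor * prev_volume:
            break  # leak: keep the last safe region
        best_region = region
        prev_volume = vol
        theta += config.growth_increment
    if best_region is None:
        raise TracheaNotFoundError("threshold growing produced no region")
    return best_region


def reconstruct_bronchi(
    volume: CTVolume,
    parenchyma_mask: np.ndarray,
    config: Optional[SegmentationConfig] = None,
    return_internals: bool = False,
):
    """Recover thin dark airway tubes by grayscale closing-by-reconstruction.

    The marker is the grayscale closing of the masked intensity image with a
    ball of closing_radius_mm; reconstruction by erosion under the original
    image then shrinks the marker back except where a dark structure is too
    thin for the ball to enter.  The positive difference reconstruction -
    original, thresholded, is the bronchi mask.
    """
    config = config or SegmentationConfig()
    mask = np.asarray(parenchyma_mask, dtype=bool)
    if not mask.any():
        empty = np.zeros_like(mask)
        if return_internals:
            z = np.zeros(mask.shape)
            return empty, z, z, z
        return empty
    # work on the mask's bounding box, padded by the ball radius
    r = max(int(round(config.closing_radius_mm / volume.spacing[1])), 1)
    zz, yy, xx = np.where(mask)
    lo = [max(int(v.min()) - r - 1, 0) for v in (zz, yy, xx)]
    hi = [min(int(v.max()) + r + 2, s) for v, s in zip((zz, yy, xx), mask.shape)]
    box = tuple(slice(a, b) for a, b in zip(lo, hi))

    sub_mask = mask[box]
    fill_value = float(np.percentile(volume.voxels[mask], 95))
    img = np.where(sub_mask, volume.voxels[box], fill_value)
    marker = ndimage.grey_closing(img, footprint=morphology.ball(r))
    recon = morphology.reconstruction(marker, img, method="erosion")
    diff = recon - img
    out = np.zeros_like(mask)
    out[box] = (diff > config.bronchi_diff_threshold) & sub_mask
    if return_internals:
        return out, recon, marker, img
    return out


# ---------------------------------------------------------------------------
# Step 3
# ---------------------------------------------------------------------------

def detect_fusion(lung_mask: np.ndarray, config: Optional[SegmentationConfig] = None) -> bool:
    """Fusion test on the two largest component areas A1 >= A2.

    Ratio mode (default): fused when A1 / max(A2, 1) > T.  A single
    component (A2 = 0) therefore always reads as fused.  Absolute mode
    compares A1 - A2 > T instead.
    """
    config = config or SegmentationConfig()
    mask = np.asarray(lung_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: nothing to test for fusion")
    labels, n = ndimage.label(mask, structure=_STRUCT_3D)
    areas = np.sort(np.bincount(labels.ravel())[1:])[::-1]
    a1 = float(areas[0])
    a2 = float(areas[1]) if n > 1 else 0.0
    if config.fusion_mode == "absolute":
        return (a1 - a2) > config.fusion_threshold
    return a1 / max(a2, 1.0) > config.fusion_threshold


def separate_lungs(
    lung_mask: np.ndarray, config: Optional[SegmentationConfig] = None
) -> tuple:
    """Break a fused lung mask along the vertical-integral-projection minimum.

    Per axial slice the column-wise foreground count, restricted to the
    central third of the x-range, attains its minimum at the adhesion; the
    minimizing column per slice defines the dividing line, interpolated
    linearly across slices where it is undefined.  Foreground voxels on the
    line are cleared.  A mask that is not fused is returned unchanged with
    an empty line.
    """
    config = config or SegmentationConfig()
    mask = np.asarray(lung_mask, dtype=bool)
    if not detect_fusion(mask, config):
        return mask.copy(), {}
    nz, ny, nx = mask.shape
    x0, x1 = nx // 3, 2 * nx // 3
    cols = np.full(nz, np.nan)
    for z in range(nz):
        central = mask[z, :, x0:x1]
        if not central.any():
            continue
        sums = central.sum(axis=0)
        minimizers = np.flatnonzero(sums == sums.min())
        cols[z] = x0 + int(minimizers[len(minimizers) // 2])
    defined = np.flatnonzero(~np.isnan(cols))
    if defined.size == 0:
        return mask.copy(), {}
    all_z = np.arange(defined[0], defined[-1] + 1)
    line_vals = np.round(np.interp(all_z, defined, cols[defined])).astype(int)
    out = mask.copy()
    line = {}
    for i, z in enumerate(all_z):
        # clear the span covering the neighbouring slices' line columns as
        # well, so the cut surface stays connected under 26-connectivity
        nbrs = line_vals[max(i - 1, 0) : i + 2]
        out[z, :, nbrs.min() : nbrs.max() + 1] = False
        line[int(z)] = int(line_vals[i])
    return out, line


# ---------------------------------------------------------------------------
# Step 4
# ---------------------------------------------------------------------------

def repair_boundary(
    lung_mask: np.ndarray,
    spacing: tuple = (1.0, 1.0, 1.0),
    config: Optional[SegmentationConfig] = None,
) -> np.ndarray:
    """Rolling-ball boundary repair: per-component disc closing.

    Each 3D component is closed slice-by-slice with a disc of
    ball_radius_mm / in-plane-spacing voxels (a 3D ball behind the
    rolling_ball_3d flag).  Closing is extensive, so the output is a
    superset of the input; components are treated separately so the closing
    cannot bridge the left and right lungs.
    """
    config = config or SegmentationConfig()
    if config.ball_radius_mm <= 0:
        raise ValueError(f"ball radius must be > 0, got {config.ball_radius_mm}")
    mask = np.asarray(lung_mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    # radius in voxels, rounded half-up so 12.5 mm at 1 mm spacing uses the
    # odd-sized disc that covers the stated radius
    r = max(int(np.floor(config.ball_radius_mm / spacing[-1] + 0.5)), 1)
    labels, n = ndimage.label(mask, structure=_STRUCT_3D)
    out = mask.copy()
    for lab in range(1, n + 1):
        comp = labels == lab
        if config.rolling_ball_3d:
            rz = max(int(np.floor(config.ball_radius_mm / spacing[0] + 0.5)), 1)
            closed = _padded_closing(comp, morphology.ball(max(r, rz)))
        else:
            closed = np.zeros_like(comp)
            disk = morphology.disk(r)
            for z in range(comp.shape[0]):
                if comp[z].any():
                    closed[z] = _padded_closing(comp[z], disk)
        out |= closed
    return out


def _padded_closing(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Binary closing with enough border padding to avoid edge artifacts."""
    pad = max(footprint.shape) // 2 + 1
    padded = np.pad(mask, pad)
    closed = ndimage.binary_closing(padded, structure=footprint)
    slicer = tuple(slice(pad, pad + s) for s in mask.shape)
    return closed[slicer]


# ---------------------------------------------------------------------------
# the composed pipeline
# ---------------------------------------------------------------------------

def segment_lungs(
    volume: CTVolume, config: Optional[SegmentationConfig] = None
) -> SegmentationResult:
    """Run the full four-step pipeline and keep every stage mask."""
    config = config or SegmentationConfig()
    raw = binarize_adaptive(volume)
    bg_removed = remove_background(raw)
    if not bg_removed.any():
        raise DegenerateVolumeError("no interior dark structures after background removal")
    rough = fill_body(bg_removed, volume)

    try:
        trachea = extract_main_trachea(volume, rough, config)
    except TracheaNotFoundError:
        trachea = np.zeros_like(rough)
    after_trachea = rough & ~trachea

    bronchi = reconstruct_bronchi(volume, after_trachea, config)
    after_bronchi = after_trachea & ~bronchi

    cleaned = _remove_specks(after_bronchi, config.min_component_voxels)
    if not cleaned.any():
        raise DegenerateVolumeError("no lung-sized components survived cleaning")

    fused = detect_fusion(cleaned, config)
    if fused:
        separated, line = separate_lungs(cleaned, config)
    else:
        separated, line = cleaned.copy(), {}

    repaired = repair_boundary(separated, volume.spacing, config)
    left, right = _split_left_right(repaired)

    stages = StageMasks(
        raw_threshold=raw,
        background_removed=bg_removed,
        body_filled=rough,
        trachea=trachea,
        bronchi=bronchi,
        fused_check_input=cleaned,
        separated=separated,
        repaired=repaired,
    )
    return SegmentationResult(
        lung_mask=repaired,
        left_mask=left,
        right_mask=right,
        fused_detected=bool(fused),
        separation_line=line,
        stages=stages,
    )


def _remove_specks(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    """Drop components below min_voxels, always keeping the two largest."""
    labels, n = ndimage.label(mask, structure=_STRUCT_3D)
    if n == 0:
        return mask.copy()
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    principal = set(np.argsort(counts)[::-1][:2])
    keep = np.zeros(n + 1, dtype=bool)
    for lab in range(1, n + 1):
        keep[lab] = lab in principal or counts[lab] >= min_voxels
    return keep[labels]


def _split_left_right(mask: np.ndarray) -> tuple:
    """Partition the final mask into left/right by component centroid x.

    'Left' is the image-left (smaller x) side.  With a single component the
    split falls back to halving at the component's x-centroid so the
    partition invariant (disjoint union = mask) still holds.
    """
    labels, n = ndimage.label(mask, structure=_STRUCT_3D)
    if n == 0:
        empty = np.zeros_like(mask)
        return empty, empty.copy()
    centroids = ndimage.center_of_mass(mask, labels, index=range(1, n + 1))
    order = np.argsort([c[2] for c in centroids])  # by x
    if n == 1:
        cx = int(round(centroids[0][2]))
        left = mask.copy()
        left[:, :, cx:] = False
        return left, mask & ~left
    half = [order[i] + 1 for i in range(n // 2)] if n > 2 else [order[0] + 1]
    left = np.isin(labels, half)
    return left & mask, mask & ~left
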