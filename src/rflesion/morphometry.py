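"""Image-analysis pipeline turning lesion photographs into measurements.

The pipeline mirrors how the ablation study evaluated its photographs:
calibrate pixels to millimetres, segment the frame into individual lesion
sub-images, convert to grayscale, threshold at 40% of the white level
(the lesion border runs through the graded reversible-injury rim, where
tissue is neither clearly white nor black), binarize and fill enclosed
holes, then compute the centroid, ellipse-equivalent major/minor axes and
area of the lesion region, rotate the region about its centroid so the
major axis is vertical, and classify the morphology as ellipse, oval or
circle.  Bisected views yield the maximum lesion depth below the tissue
surface; replicate measurements are averaged into per-condition
summaries including a pixelwise mean "average lesion morphology" mask.

Conventions: row 0 is the top of the image and depth increases downward;
a pixel belongs to the region whose test its centre passes; all reported
lengths are in mm.  Grayscale uses Rec.601 luminance then division by
the frame maximum; axis lengths come from normalized second central
moments (the ellipse-equivalent definition); rotation is
nearest-neighbour with re-binarization so masks stay binary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

log = logging.getLogger(__name__)

DEFAULT_CONCENTRATION = 0.40
DEFAULT_MIN_AREA_MM2 = 1.0
DEFAULT_TISSUE_THRESHOLD = 0.15

REC601_WEIGHTS = np.array([0.299, 0.587, 0.114])


class CalibrationError(ValueError):
    """The pixel-to-mm scale could not be resolved."""


class RegionError(ValueError):
    """A mask does not contain exactly one connected lesion component."""


@dataclass(frozen=True)
class CalibratedImage:
    pixels: np.ndarray
    mm_per_pixel: float
    view: str = "top"  # "top" | "bisected"


@dataclass(frozen=True)
class LesionRegion:
    """One measured lesion: binary mask plus calibrated shape descriptors."""

    mask: np.ndarray
    mm_per_pixel: float
    centroid_mm: tuple[float, float]  # (row, col)
    major_axis_mm: float
    minor_axis_mm: float
    orientation_deg: float  # major-axis angle from vertical (rows), CCW
    area_mm2: float
    shape_class: str = "unclassified"


@dataclass(frozen=True)
class DepthMeasurement:
    surface_row_mm: float
    max_depth_mm: float


@dataclass(frozen=True)
class ReplicateSummary:
    n: int
    mean_area_mm2: float
    sd_area_mm2: float
    mean_depth_mm: float
    sd_depth_mm: float
    mean_mask: np.ndarray  # pixelwise mean of centroid-registered masks, in [0, 1]


def calibrate(
    image: np.ndarray,
    mm_per_pixel: float | None = None,
    points: tuple[tuple[float, float], tuple[float, float]] | None = None,
    separation_mm: float | None = None,
    view: str = "top",
) -> CalibratedImage:
    """Attach a mm-per-pixel scale to a raster image.

    Either pass ``mm_per_pixel`` explicitly, or two annotated points (row,
    col) together with their known physical separation in mm.
    """
    if mm_per_pixel is None:
        if points is None or separation_mm is None:
            raise CalibrationError("need mm_per_pixel or two points with separation_mm")
        (r1, c1), (r2, c2) = points
        dist_px = float(np.hypot(r2 - r1, c2 - c1))
        if dist_px == 0:
            raise CalibrationError("calibration points coincide")
        if separation_mm <= 0:
            raise CalibrationError("separation_mm must be positive")
        mm_per_pixel = separation_mm / dist_px
    if not mm_per_pixel > 0:
        raise CalibrationError(f"mm_per_pixel must be positive, got {mm_per_pixel}")
    return CalibratedImage(np.asarray(image), float(mm_per_pixel), view)


def to_grayscale(image: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Single-channel intensity in [0, 1]: Rec.601 luminance, then division
    by the image maximum (skipped when ``normalize`` is False)."""
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    else:
        img = img.astype(float)
    if img.ndim == 3:
        gray = img[..., :3] @ REC601_WEIGHTS
    elif img.ndim == 2:
        gray = img
    else:
        raise ValueError(f"expected 2-D or 3-D image, got shape {img.shape}")
    if normalize:
        peak = gray.max()
        if peak > 0:
            gray = gray / peak
    return gray


def threshold_lesion(
    gray: np.ndarray, concentration: float = DEFAULT_CONCENTRATION
) -> np.ndarray:
    """Binarize: lesion (white) where normalized intensity >= concentration."""
    if not 0.0 < concentration < 1.0:
        raise ValueError(f"concentration must lie in (0, 1), got {concentration}")
    mask = np.asarray(gray) >= concentration
    if mask.all() or not mask.any():
        log.warning(
            "degenerate segmentation: threshold %.2f yields %s-foreground mask",
            concentration, "all" if mask.all() else "no",
        )
    return mask


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background components not connected to the image border."""
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest connected foreground component (8-connected)."""
    labels, nlab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if nlab == 0:
        return np.zeros_like(np.asarray(mask, dtype=bool))
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, nlab + 1))
    return labels == (1 + int(np.argmax(sizes)))


def segment_lesions(
    frame: CalibratedImage,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
    concentration: float = DEFAULT_CONCENTRATION,
    pad_mm: float = 1.0,
) -> list[CalibratedImage]:
    """Split a top-view frame into padded per-lesion sub-images.

    Candidate regions are 8-connected components of the thresholded
    grayscale frame with area >= min_area_mm2, ordered by centroid row
    then column.  An empty frame yields an empty list (logged).
    """
    if frame.view != "top":
        raise ValueError("segment_lesions expects a top view")
    gray = to_grayscale(frame.pixels)
    mask = threshold_lesion(gray, concentration)
    labels, nlab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    pad = int(np.ceil(pad_mm / frame.mm_per_pixel))
    candidates = []
    for prop in skmeasure.regionprops(labels):
        if prop.area * frame.mm_per_pixel**2 < min_area_mm2:
            continue
        candidates.append((prop.centroid, prop.bbox))
    candidates.sort(key=lambda t: (t[0][0], t[0][1]))
    subs = []
    for _, (r0, c0, r1, c1) in candidates:
        r0, c0 = max(0, r0 - pad), max(0, c0 - pad)
        r1 = min(frame.pixels.shape[0], r1 + pad)
        c1 = min(frame.pixels.shape[1], c1 + pad)
        subs.append(CalibratedImage(frame.pixels[r0:r1, c0:c1], frame.mm_per_pixel, "top"))
    if not subs:
        log.warning("no lesion candidates above %.2f mm^2", min_area_mm2)
    return subs


def measure_region(mask: np.ndarray, mm_per_pixel: float) -> LesionRegion:
    """Shape descriptors of a single-component binary lesion mask.

    Area is the foreground pixel count times mm_per_pixel^2; the centroid
    is the mean foreground pixel-centre position; axis lengths and
    orientation come from normalized second central moments.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, nlab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if nlab != 1:
        raise RegionError(f"expected exactly 1 connected component, found {nlab}")
    prop = skmeasure.regionprops(labels)[0]
    s = mm_per_pixel
    centroid = ((prop.centroid[0] + 0.5) * s, (prop.centroid[1] + 0.5) * s)
    return LesionRegion(
        mask=mask,
        mm_per_pixel=s,
        centroid_mm=centroid,
        major_axis_mm=prop.axis_major_length * s,
        minor_axis_mm=prop.axis_minor_length * s,
        orientation_deg=float(np.degrees(prop.orientation)),
        area_mm2=prop.area * s**2,
    )


def align_major_axis(region: LesionRegion) -> LesionRegion:
    """Rotate the mask about its centroid until the major axis is vertical.

    Nearest-neighbour resampling with re-binarization keeps the mask
    binary; area drift is bounded (~interpolation error) and the centroid
    moves by at most a pixel.
    """
    if abs(region.orientation_deg) < 0.5:
        return region
    rotated = ndimage.rotate(
        region.mask.astype(np.uint8),
        -region.orientation_deg,
        reshape=True,
        order=0,
        prefilter=False,
    ) > 0.5
    rotated = largest_component(rotated)  # NN resampling can shed isolated pixels
    out = measure_region(rotated, region.mm_per_pixel)
    return replace(out, shape_class=region.shape_class)


def measure_depth(
    frame: CalibratedImage,
    concentration: float = DEFAULT_CONCENTRATION,
    tissue_threshold: float = DEFAULT_TISSUE_THRESHOLD,
    column_window: tuple[int, int] | None = None,
) -> DepthMeasurement:
    """Maximum lesion depth below the tissue surface in a bisected view.

    The surface row is the median, over columns (optionally restricted to
    a lateral window), of the first row whose normalized intensity clears
    the tissue/saline contrast threshold.  Depth is the full pixel extent
    from the surface row to the lowest lesion-foreground row.
    """
    if frame.view != "bisected":
        raise ValueError("measure_depth expects a bisected view")
    gray = to_grayscale(frame.pixels)
    if column_window is not None:
        gray_w = gray[:, column_window[0]:column_window[1]]
    else:
        gray_w = gray
    tissue = gray_w >= tissue_threshold
    has_tissue = tissue.any(axis=0)
    if not has_tissue.any():
        raise ValueError("no tissue found above the contrast threshold")
    first_rows = np.argmax(tissue, axis=0)[has_tissue]
    surface_row = float(np.median(first_rows))
    lesion = fill_holes(threshold_lesion(gray, concentration))
    rows = np.nonzero(lesion.any(axis=1))[0]
    if rows.size == 0 or rows.max() < surface_row:
        log.warning("no lesion foreground below the tissue surface; depth 0")
        return DepthMeasurement(surface_row * frame.mm_per_pixel, 0.0)
    depth_px = rows.max() - surface_row + 1
    return DepthMeasurement(
        surface_row * frame.mm_per_pixel, float(depth_px * frame.mm_per_pixel)
    )


def classify_morphology(
    region: LesionRegion,
    circle_axis_ratio: float = 1.15,
    oval_asymmetry: float = 0.05,
) -> str:
    """Assign a shape class to an axis-aligned lesion region.

    circle: major/minor <= circle_axis_ratio; otherwise oval when the
    along-axis half-area asymmetry |A_top - A_bottom| / A >= oval_asymmetry
    (split at the midpoint of the region's vertical extent); otherwise
    ellipse.
    """
    if region.minor_axis_mm <= 0:
        return "unclassified"
    if region.major_axis_mm / region.minor_axis_mm <= circle_axis_ratio:
        return "circle"
    rows = np.nonzero(region.mask)[0]
    mid = (rows.min() + rows.max()) / 2.0
    top = np.sum(rows < mid)
    bottom = np.sum(rows > mid)
    asym = abs(int(top) - int(bottom)) / rows.size
    return "oval" if asym >= oval_asymmetry else "ellipse"


def summarize_replicates(
    regions: Sequence[LesionRegion],
    depths: Sequence[DepthMeasurement] = (),
) -> ReplicateSummary:
    """Mean/SD (ddof=1) of area and depth plus the mean morphology mask.

    The mean mask registers every aligned mask by translating its centroid
    to the centre of a common canvas and averages pixelwise.
    """
    if not regions:
        raise ValueError("no regions to summarize")
    areas = np.array([r.area_mm2 for r in regions])
    depth_vals = np.array([d.max_depth_mm for d in depths]) if depths else np.array([])

    def _sd(v: np.ndarray) -> float:
        return float(np.std(v, ddof=1)) if v.size > 1 else 0.0

    h = max(r.mask.shape[0] for r in regions)
    w = max(r.mask.shape[1] for r in regions)
    canvas = np.zeros((2 * h + 1, 2 * w + 1))
    cr, cc = h, w
    for r in regions:
        rows, cols = np.nonzero(r.mask)
        rr = rows - int(round(rows.mean())) + cr
        cc_ = cols - int(round(cols.mean())) + cc
        canvas[rr, cc_] += 1.0
    canvas /= len(regions)
    return ReplicateSummary(
        n=len(regions),
        mean_area_mm2=float(areas.mean()),
        sd_area_mm2=_sd(areas),
        mean_depth_mm=float(depth_vals.mean()) if depth_vals.size else float("nan"),
        sd_depth_mm=_sd(depth_vals) if depth_vals.size else float("nan"),
        mean_mask=canvas,
    )


def measure_top_frame(
    frame: CalibratedImage,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
    concentration: float = DEFAULT_CONCENTRATION,
) -> list[LesionRegion]:
    """Full top-view pipeline: segment, threshold, fill, measure, align,
    classify.  Returns one aligned, classified region per detected lesion."""
    out = []
    for sub in segment_lesions(frame, min_area_mm2, concentration):
        gray = to_grayscale(sub.pixels)
        mask = fill_holes(threshold_lesion(gray, concentration))
        mask = largest_component(mask)
        region = measure_region(mask, sub.mm_per_pixel)
        region = align_major_axis(region)
        region = replace(region, shape_class=classify_morphology(region))
        out.append(region)
    return out
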