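"""Synthetic lesion photographs with known ground truth.

Emulates the two kinds of photographs the morphometry pipeline consumes:

* **top views** — white-ish quasi-elliptical coagulated lesions on darker
  epicardial tissue, each surrounded by a graded "reversible injury" rim
  where the colour change is partial;
* **bisected views** — a cross-section after cutting the lesion along its
  diameter: saline above a horizontal tissue surface, with a bright
  half-elliptical lesion profile extending to a known maximum depth.

Three shape classes mirror the morphologies seen at different catheter
contact angles: a 2:1 *ellipse* for parallel contact (0 deg), an
egg-like *oval* for oblique contact (30/45/60 deg) and a *circle* for
perpendicular contact (90 deg).  The oval is an ellipse whose local
half-width is modulated linearly along the major axis by an ``ovality``
factor o:

    half_width(u) = b * (1 + o * u / (2a)) * sqrt(1 - (u/a)^2),  |u| <= a

The linear modulation is odd in u, so the enclosed area stays exactly
pi*a*b for every ovality — area targeting is independent of shape class —
while the half-area asymmetry about the centre is 2o/(3*pi).

Intensity model (8-bit): tissue 60, lesion core 230, saline 10, with a
linear ramp of configurable width centred on the true lesion boundary
and optional additive Gaussian read noise.  All randomness flows through
one seeded generator; identical seeds give bit-identical frames.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from . import study_data

log = logging.getLogger(__name__)

TISSUE_LEVEL = 60
CORE_LEVEL = 230
SALINE_LEVEL = 10

#: Contact-angle -> (shape class, major/minor aspect, ovality) mapping.
ANGLE_SHAPE_CLASS: dict[int, tuple[str, float, float]] = {
    0: ("ellipse", 2.0, 0.0),
    30: ("oval", 1.5, 0.4),
    45: ("oval", 1.5, 0.4),
    60: ("oval", 1.5, 0.4),
    90: ("circle", 1.0, 0.0),
}

DEFAULT_MM_PER_PIXEL = 0.05
DEFAULT_FRAME_SHAPE = (800, 1200)  # rows x cols
DEFAULT_BORDER_WIDTH_MM = 0.4
DEFAULT_NOISE_SD = 4.0


class FrameGeometryError(ValueError):
    """A lesion does not fit the frame or overlaps another lesion."""


@dataclass(frozen=True)
class LesionSpec:
    """Ground-truth description of one lesion."""

    shape_class: str  # "ellipse" | "oval" | "circle"
    semi_major_mm: float
    semi_minor_mm: float
    ovality: float = 0.0
    center_mm: tuple[float, float] = (0.0, 0.0)  # (row, col) in mm
    orientation_deg: float = 0.0  # major axis angle from vertical (rows)
    border_width_mm: float = 0.0
    depth_mm: float = 0.0

    def __post_init__(self) -> None:
        if not (self.semi_major_mm >= self.semi_minor_mm > 0):
            raise ValueError("need semi_major_mm >= semi_minor_mm > 0")
        if not 0.0 <= self.ovality <= 0.6:
            raise ValueError("ovality must lie in [0, 0.6]")
        if self.shape_class == "circle":
            if self.semi_major_mm / self.semi_minor_mm > 1.05 or self.ovality != 0:
                raise ValueError("circle requires near-equal axes and zero ovality")
        if self.shape_class not in ("ellipse", "oval", "circle"):
            raise ValueError(f"unknown shape class {self.shape_class!r}")

    @property
    def area_mm2(self) -> float:
        """Enclosed area; exactly pi*a*b for every ovality (odd modulation)."""
        return float(np.pi * self.semi_major_mm * self.semi_minor_mm)


@dataclass(frozen=True)
class SyntheticFrame:
    image: np.ndarray  # uint8, rows x cols
    mm_per_pixel: float
    specs: tuple[LesionSpec, ...]
    view: str  # "top" | "bisected"
    seed: int
    meta: dict = field(default_factory=dict, compare=False)


def _pixel_grid_mm(shape: tuple[int, int], mm_per_pixel: float):
    rows = (np.arange(shape[0]) + 0.5) * mm_per_pixel
    cols = (np.arange(shape[1]) + 0.5) * mm_per_pixel
    return rows[:, None], cols[None, :]


def rasterize_top_mask(
    spec: LesionSpec, shape: tuple[int, int], mm_per_pixel: float
) -> np.ndarray:
    """Boolean mask of the lesion core: pixel centres inside the implicit curve."""
    y, x = _pixel_grid_mm(shape, mm_per_pixel)
    cy, cx = spec.center_mm
    phi = np.deg2rad(spec.orientation_deg)
    # u along the major axis (vertical when orientation is 0), v across it
    u = (y - cy) * np.cos(phi) + (x - cx) * np.sin(phi)
    v = -(y - cy) * np.sin(phi) + (x - cx) * np.cos(phi)
    a, b = spec.semi_major_mm, spec.semi_minor_mm
    half_w = b * (1.0 + spec.ovality * u / (2.0 * a))
    with np.errstate(divide="ignore", invalid="ignore"):
        inside = (np.abs(u) <= a) & ((u / a) ** 2 + (v / half_w) ** 2 <= 1.0)
    return inside & (half_w > 0)


def _shade(core: np.ndarray, mm_per_pixel: float, border_width_mm: float,
           lo: float, hi: float) -> np.ndarray:
    """Intensity field: hi inside the core, lo outside, linear ramp of the
    given width centred on the core boundary (signed-distance based)."""
    img = np.where(core, float(hi), float(lo))
    if border_width_mm > 0 and core.any() and not core.all():
        d_out = (ndimage.distance_transform_edt(~core) - 0.5) * mm_per_pixel
        d_in = (ndimage.distance_transform_edt(core) - 0.5) * mm_per_pixel
        signed = np.where(core, -d_in, d_out)
        frac = np.clip(0.5 - signed / border_width_mm, 0.0, 1.0)
        img = lo + (hi - lo) * frac
    return img


def _finalize(img: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_top_view(
    specs: list[LesionSpec],
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    frame_shape: tuple[int, int] = DEFAULT_FRAME_SHAPE,
) -> SyntheticFrame:
    """Render a top-view frame of non-overlapping lesions.

    Raises FrameGeometryError naming the offending spec index if a lesion
    (including its rim) leaves the frame or collides with an earlier one.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if mm_per_pixel <= 0:
        raise ValueError("mm_per_pixel must be positive")
    occupied = np.zeros(frame_shape, dtype=bool)
    union = np.zeros(frame_shape, dtype=bool)
    pad_px = int(np.ceil(0.5 * max(s.border_width_mm for s in specs) / mm_per_pixel)) if specs else 0
    for i, spec in enumerate(specs):
        core = rasterize_top_mask(spec, frame_shape, mm_per_pixel)
        if not core.any():
            raise FrameGeometryError(f"spec {i}: empty rasterization (degenerate or out of frame)")
        foot = ndimage.binary_dilation(core, iterations=pad_px) if pad_px else core
        edge = np.zeros(frame_shape, dtype=bool)
        edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
        if (foot & edge).any():
            raise FrameGeometryError(f"spec {i}: lesion footprint leaves the frame")
        if (foot & occupied).any():
            raise FrameGeometryError(f"spec {i}: lesion overlaps an earlier lesion")
        occupied |= foot
        union |= core
    border = max((s.border_width_mm for s in specs), default=0.0)
    img = _shade(union, mm_per_pixel, border, TISSUE_LEVEL, CORE_LEVEL)
    rng = np.random.default_rng(seed)
    return SyntheticFrame(
        _finalize(img, noise_sd, rng), mm_per_pixel, tuple(specs), "top", seed
    )


def generate_bisected_view(
    spec: LesionSpec,
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    frame_shape: tuple[int, int] | None = None,
    surface_mm: float = 3.0,
) -> SyntheticFrame:
    """Render a cross-section: saline above a flat tissue surface, with a
    bright half-elliptical lesion profile of maximum depth ``spec.depth_mm``
    and half-width ``spec.semi_major_mm`` (the cut runs along the diameter).
    """
    if spec.depth_mm <= 0:
        raise FrameGeometryError("bisected view requires depth_mm > 0")
    if frame_shape is None:
        h = int(np.ceil((surface_mm + spec.depth_mm + spec.border_width_mm + 4.0) / mm_per_pixel))
        w = int(np.ceil((2 * (spec.semi_major_mm + spec.border_width_mm) + 8.0) / mm_per_pixel))
        frame_shape = (h, w)
    if surface_mm + spec.depth_mm >= frame_shape[0] * mm_per_pixel:
        raise FrameGeometryError("lesion depth exceeds the frame height")
    y, x = _pixel_grid_mm(frame_shape, mm_per_pixel)
    cx = frame_shape[1] * mm_per_pixel / 2.0
    depth_below = y - surface_mm  # mm below the tissue surface
    a, d = spec.semi_major_mm, spec.depth_mm
    core = (depth_below >= 0) & (((x - cx) / a) ** 2 + (depth_below / d) ** 2 <= 1.0)
    if not core.any():
        raise FrameGeometryError("degenerate cross-section: empty rasterization")
    img = _shade(core, mm_per_pixel, spec.border_width_mm, TISSUE_LEVEL, CORE_LEVEL)
    img = np.where(depth_below < 0, float(SALINE_LEVEL), img)
    rng = np.random.default_rng(seed)
    return SyntheticFrame(
        _finalize(img, noise_sd, rng), mm_per_pixel, (spec,), "bisected", seed,
        meta={"surface_mm": surface_mm},
    )


def _lognormal_factor(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw from a log-normal with the given mean and SD (exact moments)."""
    cv2 = (sd / mean) ** 2
    sigma = np.sqrt(np.log1p(cv2))
    mu = np.log(mean) - 0.5 * sigma**2
    return float(rng.lognormal(mu, sigma))


def make_condition_specs(
    angle_deg: int,
    force_gf: int,
    n: int,
    rng: np.random.Generator,
    border_width_mm: float = DEFAULT_BORDER_WIDTH_MM,
    area_table: study_data.ConditionTable | None = None,
    depth_table: study_data.ConditionTable | None = None,
) -> list[LesionSpec]:
    """Draw n replicate lesion specs for one study condition.

    Target areas and depths are log-normal with the condition's reported
    mean and SD; both half-axes scale by a common factor so the drawn area
    is hit exactly.  Shape class follows the contact angle (parallel ->
    ellipse, oblique -> oval, perpendicular -> circle).
    """
    if n < 1:
        raise ValueError("need n >= 1 replicates")
    area_table = area_table or study_data.load_lesion_area_table()
    depth_table = depth_table or study_data.load_lesion_depth_table()
    a_cell = area_table.cell(angle_deg, force_gf)
    d_cell = depth_table.cell(angle_deg, force_gf)
    shape_class, aspect, ovality = ANGLE_SHAPE_CLASS[angle_deg]
    specs = []
    for _ in range(n):
        area = _lognormal_factor(rng, a_cell.mean, a_cell.sd)
        depth = _lognormal_factor(rng, d_cell.mean, d_cell.sd)
        a = float(np.sqrt(area * aspect / np.pi))
        b = a / aspect
        orient = 0.0 if shape_class == "circle" else float(rng.uniform(-45.0, 45.0))
        specs.append(
            LesionSpec(
                shape_class=shape_class,
                semi_major_mm=a,
                semi_minor_mm=b,
                ovality=ovality,
                orientation_deg=orient,
                border_width_mm=border_width_mm,
                depth_mm=depth,
            )
        )
    return specs


def make_condition_panel(
    angle_deg: int,
    force_gf: int,
    n: int = study_data.REPLICATES,
    seed: int = 0,
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL,
    noise_sd: float = DEFAULT_NOISE_SD,
    border_width_mm: float = DEFAULT_BORDER_WIDTH_MM,
) -> tuple[list[SyntheticFrame], list[SyntheticFrame]]:
    """n top-view and n bisected frames for one (angle, force) condition.

    Each replicate gets its own auto-sized single-lesion frame; the frame
    metadata records the condition so measurement output can be grouped.
    """
    rng = np.random.default_rng(seed)
    specs = make_condition_specs(angle_deg, force_gf, n, rng, border_width_mm)
    tops, cuts = [], []
    for rep, spec in enumerate(specs):
        side = 2 * (spec.semi_major_mm + spec.border_width_mm) + 4.0
        npx = int(np.ceil(side / mm_per_pixel))
        centred = dataclasses.replace(
            spec, center_mm=(npx * mm_per_pixel / 2, npx * mm_per_pixel / 2)
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        meta = {"angle_deg": angle_deg, "force_gf": force_gf, "replicate": rep}
        top = generate_top_view(
            [centred], mm_per_pixel, noise_sd, seed=sub_seed, frame_shape=(npx, npx)
        )
        tops.append(dataclasses.replace(top, meta={**top.meta, **meta}))
        cut = generate_bisected_view(
            centred, mm_per_pixel, noise_sd, seed=sub_seed + 1
        )
        cuts.append(dataclasses.replace(cut, meta={**cut.meta, **meta}))
    return tops, cuts


# ---------------------------------------------------------------------------
# PNG + JSON sidecar I/O


def write_frame(frame: SyntheticFrame, path: str | Path) -> Path:
    """Write ``<path>.png`` plus a ``<path>.json`` sidecar with the scale,
    seed, view, metadata and ground-truth specs.  Returns the PNG path."""
    path = Path(path)
    png = path.with_suffix(".png")
    iio.imwrite(png, frame.image)
    sidecar = {
        "mm_per_pixel": frame.mm_per_pixel,
        "view": frame.view,
        "seed": frame.seed,
        "meta": frame.meta,
        "specs": [dataclasses.asdict(s) for s in frame.specs],
    }
    png.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return png


def read_frame(png_path: str | Path) -> SyntheticFrame:
    """Read a frame written by :func:`write_frame` back, sidecar included."""
    png_path = Path(png_path)
    sidecar = json.loads(png_path.with_suffix(".json").read_text())
    image = iio.imread(png_path)
    specs = tuple(
        LesionSpec(**{**s, "center_mm": tuple(s["center_mm"])})
        for s in sidecar["specs"]
    )
    return SyntheticFrame(
        image, float(sidecar["mm_per_pixel"]), specs, sidecar["view"],
        int(sidecar["seed"]), sidecar.get("meta", {}),
    )
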