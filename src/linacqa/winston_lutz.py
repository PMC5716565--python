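"""Winston-Lutz analysis: BB and radiation-field center detection on portal
images, and combination of cardinal-gantry-angle offsets into a 3D isocenter
estimate.

All detected positions are sub-pixel and reported in isocenter-plane mm with
x left(-)/right(+), y up(-)/down(+) about the raster center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from linacqa.core_io import Offset2D, PlanarImage, Point2D, ValidationError

__all__ = [
    "DetectionError",
    "WLImageResult",
    "CardinalOffsets",
    "IsocenterOffset3D",
    "detect_field_center",
    "detect_bb_center",
    "analyze_wl_image",
    "isocenter_from_cardinal",
    "wl_batch_summary",
]

CARDINAL_ANGLES = (0.0, 90.0, 180.0, 270.0)


class DetectionError(RuntimeError):
    """Raised when the BB or the field edges cannot be located."""


@dataclass(frozen=True)
class WLImageResult:
    """Per-image result: BB center, field center and their difference."""

    bb_center: Point2D
    field_center: Point2D
    gantry_deg: float = 0.0
    table_deg: float = 0.0

    @property
    def offset(self) -> Offset2D:
        """BB minus field center, isocenter-plane mm."""
        return self.bb_center - self.field_center


@dataclass(frozen=True)
class CardinalOffsets:
    """BB-minus-field offsets at the four cardinal gantry angles, table zero."""

    g0: Offset2D
    g90: Offset2D
    g180: Offset2D
    g270: Offset2D


@dataclass(frozen=True)
class IsocenterOffset3D:
    """3D BB location w.r.t. the radiation isocenter.

    rl: mm, R(-)/L(+); ap: mm, A(-)/P(+); is_: mm, I(-)/S(+).
    """

    rl: float
    ap: float
    is_: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.rl, self.ap, self.is_)):
            raise ValidationError("non-finite isocenter offset")


def _intensity_levels(pixels: np.ndarray) -> tuple[float, float]:
    """Robust (baseline, plateau) estimate via an Otsu split.

    Plateau is the median of the top decile inside the bright class and
    baseline the median of the bottom decile outside it, which keeps the BB
    dip and edge pixels out of the plateau estimate.
    """
    flat = pixels.ravel()
    if float(flat.max()) - float(flat.min()) <= 0:
        raise DetectionError("image has no contrast")
    thr = threshold_otsu(flat)
    bright = flat[flat >= thr]
    dark = flat[flat < thr]
    if bright.size == 0 or dark.size == 0:
        raise DetectionError("could not split field from background")
    plateau = float(np.median(bright[bright >= np.quantile(bright, 0.9)]))
    baseline = float(np.median(dark[dark <= np.quantile(dark, 0.1)]))
    if plateau <= baseline:
        raise DetectionError("plateau not above baseline")
    return baseline, plateau


def _first_crossing(profile: np.ndarray, level: float, reverse: bool = False) -> float | None:
    """Sub-pixel index of the first upward crossing of ``level``.

    Scans left-to-right (or right-to-left when ``reverse``) and linearly
    interpolates between the straddling samples. Returns None if the profile
    never rises through the level.
    """
    idx = np.arange(profile.size)
    p = profile[::-1] if reverse else profile
    below = p < level
    for i in range(p.size - 1):
        if below[i] and p[i + 1] >= level:
            frac = (level - p[i]) / (p[i + 1] - p[i])
            pos = i + frac
            return (profile.size - 1 - pos) if reverse else pos
    return None


def detect_field_center(
    image: PlanarImage,
) -> tuple[Point2D, dict[str, float]]:
    """Locate the radiation-field center from the 50% intensity edges.

    Edges are found at 50% of (plateau - baseline) above baseline, sub-pixel
    by linear interpolation along row/column profiles. Scanning inward from
    the image border makes the result insensitive to the dark BB inside the
    field; the 50% chord midpoint is the center coordinate for both
    rectangular and circular apertures, so their medians over rows/columns
    give the field center.

    Returns the center and the four median edge positions (mm) as a dict
    with keys ``left``, ``right``, ``top``, ``bottom``.
    """
    pixels = image.pixels
    baseline, plateau = _intensity_levels(pixels)
    level = baseline + 0.5 * (plateau - baseline)
    x_mm, y_mm = image.iso_coords()

    def _axis_midpoints(arr: np.ndarray, coords: np.ndarray):
        mids, lo_edges, hi_edges = [], [], []
        for line in arr:
            if line.max() < level:
                continue
            lo = _first_crossing(line, level)
            hi = _first_crossing(line, level, reverse=True)
            if lo is None or hi is None or hi <= lo:
                continue
            lo_mm = float(np.interp(lo, np.arange(coords.size), coords))
            hi_mm = float(np.interp(hi, np.arange(coords.size), coords))
            mids.append(0.5 * (lo_mm + hi_mm))
            lo_edges.append(lo_mm)
            hi_edges.append(hi_mm)
        return mids, lo_edges, hi_edges

    row_mids, lefts, rights = _axis_midpoints(pixels, x_mm)
    col_mids, tops, bottoms = _axis_midpoints(pixels.T, y_mm)
    if not row_mids or not col_mids:
        raise DetectionError("no 50% edge crossings found")
    center = Point2D(float(np.median(row_mids)), float(np.median(col_mids)))
    edges = {
        "left": float(np.median(lefts)),
        "right": float(np.median(rights)),
        "top": float(np.median(tops)),
        "bottom": float(np.median(bottoms)),
    }
    return center, edges


def detect_bb_center(image: PlanarImage) -> Point2D:
    """Locate the dark BB disc inside the field, sub-pixel.

    The field interior is segmented by Otsu and eroded away from the edges;
    the BB is thresholded at half the depth of its intensity dip and its
    center taken as the centroid weighted by ``max(threshold - I, 0)``.
    """
    pixels = image.pixels
    baseline, plateau = _intensity_levels(pixels)
    thr = threshold_otsu(pixels)
    # fill the BB's own hole so erosion only trims the outer field edge
    field_mask = ndimage.binary_fill_holes(pixels >= thr)

    # pull in from the field edge so edge penumbra cannot masquerade as a BB
    erode_px = max(2, int(round(1.5 / image.pitch_iso_mm)))
    interior = ndimage.binary_erosion(field_mask, iterations=erode_px)
    if not interior.any():
        raise DetectionError("field interior empty after erosion")

    inner_vals = pixels[interior]
    dip_min = float(inner_vals.min())
    local_plateau = float(np.median(inner_vals[inner_vals >= np.quantile(inner_vals, 0.8)]))
    depth = local_plateau - dip_min
    if depth < 0.1 * (plateau - baseline):
        raise DetectionError("no BB dip found inside the field")
    bb_level = dip_min + 0.5 * depth

    candidate = interior & (pixels <= bb_level)
    labels, n = ndimage.label(candidate)
    if n == 0:
        raise DetectionError("no BB candidate region")
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        order = np.argsort(sizes)[::-1]
        if sizes[order[0]] < 4 or (len(order) > 1 and sizes[order[1]] >= 0.25 * sizes[order[0]]):
            raise DetectionError(f"{n} BB candidate regions found")
        candidate = labels == (order[0] + 1)

    weights = np.clip(bb_level - pixels, 0.0, None) * candidate
    total = float(weights.sum())
    if total <= 0:
        raise DetectionError("degenerate BB weighting")
    rows, cols = np.nonzero(weights)
    w = weights[rows, cols]
    row_c = float(np.sum(rows * w) / total)
    col_c = float(np.sum(cols * w) / total)
    return image.px_to_iso(col_c, row_c)


def analyze_wl_image(image: PlanarImage) -> WLImageResult:
    """Detect both centers on one portal image."""
    field_center, _ = detect_field_center(image)
    bb_center = detect_bb_center(image)
    return WLImageResult(
        bb_center=bb_center,
        field_center=field_center,
        gantry_deg=image.gantry_deg,
        table_deg=image.table_deg,
    )


def isocenter_from_cardinal(offsets: CardinalOffsets) -> IsocenterOffset3D:
    """Combine the four cardinal-angle 2D offsets into a 3D BB location.

    rl = (G0.x - G180.x)/2, ap = (G90.x - G270.x)/2,
    is_ = (G0.y + G90.y + G180.y + G270.y)/4. Valid only for the complete
    gantry set at table zero.
    """
    g0, g90, g180, g270 = offsets.g0, offsets.g90, offsets.g180, offsets.g270
    return IsocenterOffset3D(
        rl=(g0.x - g180.x) / 2.0,
        ap=(g90.x - g270.x) / 2.0,
        is_=(g0.y + g90.y + g180.y + g270.y) / 4.0,
    )


def cardinal_from_results(results: list[WLImageResult]) -> CardinalOffsets:
    """Extract the table-zero cardinal set from a batch of per-image results."""
    by_angle: dict[float, Offset2D] = {}
    for r in results:
        if abs(r.table_deg) > 1e-9:
            continue
        angle = float(r.gantry_deg) % 360.0
        if angle not in CARDINAL_ANGLES:
            continue
        if angle in by_angle:
            raise ValidationError(f"duplicate gantry angle {angle}")
        by_angle[angle] = r.offset
    missing = [a for a in CARDINAL_ANGLES if a not in by_angle]
    if missing:
        raise ValidationError(f"missing cardinal gantry angles {missing}")
    return CardinalOffsets(
        g0=by_angle[0.0], g90=by_angle[90.0], g180=by_angle[180.0], g270=by_angle[270.0]
    )


def wl_batch_summary(
    results: list[WLImageResult], tolerance_mm: float = 1.0
) -> dict:
    """Summarize per-image offset magnitudes against a tolerance (default 1 mm).

    A magnitude equal to the tolerance passes (comparison is ``<=``).
    """
    if not results:
        raise ValidationError("empty result list")
    rows = []
    for r in results:
        mag = r.offset.norm
        rows.append(
            {
                "gantry_deg": r.gantry_deg,
                "table_deg": r.table_deg,
                "offset_x_mm": r.offset.x,
                "offset_y_mm": r.offset.y,
                "magnitude_mm": mag,
                "pass": mag <= tolerance_mm,
            }
        )
    mags = [row["magnitude_mm"] for row in rows]
    return {
        "per_image": rows,
        "max_mm": max(mags),
        "mean_mm": float(np.mean(mags)),
        "tolerance_mm": tolerance_mm,
        "pass": max(mags) <= tolerance_mm,
    }
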