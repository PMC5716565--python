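"""End-to-end dosimetric verification: film-to-dose conversion, 2D gamma
analysis, hidden-target offsets, and the isocenter dose report.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from linacqa.core_io import Offset2D, PlanarImage, ValidationError
from linacqa.winston_lutz import (
    CardinalOffsets,
    IsocenterOffset3D,
    analyze_wl_image,
    cardinal_from_results,
    isocenter_from_cardinal,
)

__all__ = [
    "DoseGrid",
    "GammaCriteria",
    "GammaMap",
    "DoseComparisonReport",
    "film_to_dose",
    "gamma_map",
    "hidden_target_offsets",
    "isocenter_dose_report",
    "read_dose_grid",
    "write_dose_grid",
]


@dataclass
class DoseGrid:
    """A planar dose distribution in cGy on a regular grid."""

    dose: np.ndarray
    pitch_mm: float
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.ndim != 2:
            raise ValidationError("dose must be a 2D raster")
        if np.any(self.dose < 0):
            raise ValidationError("doses must be >= 0")
        if self.pitch_mm <= 0:
            raise ValidationError("pitch must be > 0")


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma-index criteria: dose difference (%) and distance to agreement (mm)."""

    dose_difference_pct: float = 3.0
    distance_to_agreement_mm: float = 1.0
    normalization: str = "global_max"
    low_dose_cutoff_pct: float = 10.0

    def __post_init__(self) -> None:
        if self.dose_difference_pct <= 0 or self.distance_to_agreement_mm <= 0:
            raise ValidationError("both gamma criteria must be > 0")
        if self.normalization not in {"global_max", "local"}:
            raise ValidationError(f"unknown normalization {self.normalization!r}")


@dataclass
class GammaMap:
    gamma: np.ndarray
    pass_rate_pct: float
    roi_mask: np.ndarray
    criteria: GammaCriteria

    def __post_init__(self) -> None:
        if np.any(self.gamma[self.roi_mask] < 0):
            raise ValidationError("gamma values must be >= 0")
        if not (0.0 <= self.pass_rate_pct <= 100.0):
            raise ValidationError("pass rate must be within [0, 100]")


# ----------------------------------------------------------------------------
# film dosimetry


def film_to_dose(
    scan: np.ndarray,
    calibration: dict[str, tuple[np.ndarray, np.ndarray]],
    channels: tuple[str, ...] = ("red", "green"),
    pitch_mm: float = 1.0,
    flat_field: np.ndarray | None = None,
) -> tuple[DoseGrid, dict]:
    """Convert a scanned film image to dose via per-channel calibration curves.

    ``scan`` is either a 2D array (single channel named by the sole entry of
    ``channels``) or an (n, m, 3) RGB array with channel order red, green,
    blue. Each calibration entry maps pixel value to dose (cGy) and must be
    strictly monotone in pixel value; per-channel doses are interpolated and
    averaged over the requested channels. Pixels outside a calibration
    domain are clamped and counted in the returned flags. ``flat_field``
    optionally divides the scan before conversion (scanner nonuniformity
    hook).
    """
    scan = np.asarray(scan, dtype=float)
    if flat_field is not None:
        ff = np.asarray(flat_field, dtype=float)
        if ff.shape != scan.shape[:2]:
            raise ValidationError("flat-field map must match the scan shape")
        scan = scan / ff[..., None] if scan.ndim == 3 else scan / ff
    channel_index = {"red": 0, "green": 1, "blue": 2}
    planes: list[np.ndarray] = []
    clamped_total = 0
    for ch in channels:
        if ch not in calibration:
            raise ValidationError(f"no calibration curve for channel {ch!r}")
        px, dose = (np.asarray(a, dtype=float) for a in calibration[ch])
        if px.size != dose.size or px.size < 2:
            raise ValidationError("calibration curve needs >= 2 points")
        order = np.argsort(px)
        px, dose = px[order], dose[order]
        diffs = np.diff(dose)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValidationError(f"calibration for {ch!r} is not strictly monotone")
        if scan.ndim == 3:
            plane_px = scan[..., channel_index[ch]]
        else:
            if len(channels) != 1:
                raise ValidationError("2D scan supports exactly one channel")
            plane_px = scan
        clamped_total += int(np.sum((plane_px < px[0]) | (plane_px > px[-1])))
        planes.append(np.interp(plane_px, px, dose))
    mean_dose = np.clip(np.mean(planes, axis=0), 0.0, None)
    flags = {"clamped_pixels": clamped_total}
    return DoseGrid(dose=mean_dose, pitch_mm=pitch_mm), flags


# ----------------------------------------------------------------------------
# gamma analysis


def _search_offsets(
    dta_mm: float, pitch_mm: float, step_mm: float | None, radius_factor: float
) -> np.ndarray:
    step = step_mm if step_mm is not None else dta_mm / 10.0
    radius = radius_factor * dta_mm
    k = int(math.floor(radius / step))
    ax = np.arange(-k, k + 1) * step
    dx, dy = np.meshgrid(ax, ax)
    r2 = dx**2 + dy**2
    keep = r2 <= radius**2 + 1e-12
    offs = np.column_stack([dx[keep], dy[keep], r2[keep]])
    return offs[np.argsort(offs[:, 2])]  # origin first: early exit friendly


def gamma_map(
    ref: DoseGrid,
    eval_: DoseGrid,
    criteria: GammaCriteria = GammaCriteria(),
    roi_mask: np.ndarray | None = None,
    search_step_mm: float | None = None,
    search_radius_factor: float = 3.0,
) -> GammaMap:
    """Per-pixel 2D gamma index of ``eval_`` against ``ref``.

    For every reference pixel the minimum of
    ``sqrt((dD / DD)^2 + (dr / DTA)^2)`` is taken over a search disc of
    radius ``search_radius_factor * DTA``, sampling the evaluated grid by
    bilinear interpolation at ``search_step_mm`` (default DTA / 10). Dose
    differences are normalized to the global reference maximum or to the
    local reference dose per ``criteria.normalization``. The pass rate
    counts gamma <= 1 over the ROI restricted to reference doses above the
    low-dose cutoff.
    """
    if ref.dose.shape != eval_.dose.shape:
        raise ValidationError("grids must have identical shapes")
    if not math.isclose(ref.pitch_mm, eval_.pitch_mm, rel_tol=1e-9):
        raise ValidationError("grids must share one pixel pitch")
    nrow, ncol = ref.dose.shape
    pitch = ref.pitch_mm
    dd, dta = criteria.dose_difference_pct, criteria.distance_to_agreement_mm
    ref_max = float(ref.dose.max())
    if ref_max <= 0:
        raise ValidationError("reference grid has no dose")
    if criteria.normalization == "global_max":
        dd_norm = np.full_like(ref.dose, dd / 100.0 * ref_max)
    else:
        dd_norm = dd / 100.0 * np.maximum(ref.dose, 1e-12)

    rows, cols = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
    gamma_sq = np.full((nrow, ncol), np.inf)
    for dx_mm, dy_mm, r2 in _search_offsets(dta, pitch, search_step_mm, search_radius_factor):
        dist_term = r2 / dta**2
        if np.all(gamma_sq <= dist_term):
            break  # no remaining pixel can improve
        sample_rows = rows + dy_mm / pitch
        sample_cols = cols + dx_mm / pitch
        ev = map_coordinates(eval_.dose, [sample_rows, sample_cols], order=1, mode="nearest")
        dose_term = ((ev - ref.dose) / dd_norm) ** 2
        gamma_sq = np.minimum(gamma_sq, dose_term + dist_term)
    gamma = np.sqrt(gamma_sq)

    if roi_mask is None:
        roi_mask = np.ones_like(ref.dose, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != ref.dose.shape:
        raise ValidationError("ROI mask must match the grid shape")
    eval_mask = roi_mask & (ref.dose >= criteria.low_dose_cutoff_pct / 100.0 * ref_max)
    n_eval = int(eval_mask.sum())
    pass_rate = 100.0 * float(np.sum(gamma[eval_mask] <= 1.0)) / n_eval if n_eval else 0.0
    return GammaMap(gamma=gamma, pass_rate_pct=pass_rate, roi_mask=eval_mask, criteria=criteria)


# ----------------------------------------------------------------------------
# hidden target


def hidden_target_offsets(
    images: list[PlanarImage],
) -> tuple[dict[float, Offset2D], IsocenterOffset3D]:
    """BB-vs-field offsets on the four cardinal portal images plus the 3D
    combination; delegates to the Winston-Lutz detectors."""
    if len(images) != 4:
        raise ValidationError("hidden-target test needs exactly 4 cardinal images")
    results = [analyze_wl_image(img) for img in images]
    cardinal = cardinal_from_results(results)
    per_image = {float(r.gantry_deg) % 360.0: r.offset for r in results}
    return per_image, isocenter_from_cardinal(cardinal)


# ----------------------------------------------------------------------------
# isocenter dose report


@dataclass
class DoseComparisonReport:
    """Per-beam planned vs measured isocenter doses with totals.

    The total percent difference compares summed doses,
    ``100 * (sum(measured) - sum(planned)) / sum(planned)`` — not the mean
    of the per-beam percentages. ``*_display`` fields are rounded to one
    decimal; the unrounded values are retained.
    """

    planned_cgy: tuple[float, ...]
    measured_cgy: tuple[float, ...]
    percent_diff: tuple[float, ...]
    total_planned_cgy: float
    total_measured_cgy: float
    total_percent_diff: float

    @property
    def percent_diff_display(self) -> tuple[float, ...]:
        return tuple(round(p, 1) for p in self.percent_diff)

    @property
    def total_percent_diff_display(self) -> float:
        return round(self.total_percent_diff, 1)

    @property
    def max_abs_percent_diff_display(self) -> float:
        return max(self.percent_diff_display, key=abs)


def isocenter_dose_report(planned_cgy, measured_cgy) -> DoseComparisonReport:
    """Compare per-beam measured isocenter doses with planned doses."""
    planned = [float(p) for p in planned_cgy]
    measured = [float(m) for m in measured_cgy]
    if len(planned) != len(measured) or not planned:
        raise ValidationError("planned and measured lists must be equal, non-empty")
    if any(p <= 0 for p in planned):
        raise ValidationError("planned doses must be positive")
    diffs = tuple(100.0 * (m - p) / p for p, m in zip(planned, measured))
    tp, tm = sum(planned), sum(measured)
    return DoseComparisonReport(
        planned_cgy=tuple(planned),
        measured_cgy=tuple(measured),
        percent_diff=diffs,
        total_planned_cgy=tp,
        total_measured_cgy=tm,
        total_percent_diff=100.0 * (tm - tp) / tp,
    )


# ----------------------------------------------------------------------------
# DoseGrid CSV I/O — 3-line header (pitch, origin, units) then the raster


def write_dose_grid(grid: DoseGrid, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# pitch_mm,{grid.pitch_mm!r}\n")
        fh.write(f"# origin_mm,{grid.origin_mm[0]!r},{grid.origin_mm[1]!r}\n")
        fh.write("# units,cGy\n")
        writer = csv.writer(fh)
        for row in grid.dose:
            writer.writerow([repr(float(v)) for v in row])


def read_dose_grid(path: str | Path) -> DoseGrid:
    with open(path, newline="") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 4 or not lines[0].startswith("# pitch_mm"):
        raise ValidationError(f"{path} is not a dose-grid CSV")
    pitch = float(lines[0].split(",")[1])
    origin_parts = lines[1].split(",")
    origin = (float(origin_parts[1]), float(origin_parts[2]))
    rows = [
        [float(v) for v in line.split(",")]
        for line in lines[3:]
        if line.strip()
    ]
    return DoseGrid(dose=np.array(rows), pitch_mm=pitch, origin_mm=origin)
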