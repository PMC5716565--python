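"""Seeded synthetic phantom-data generators.

Every generator is a pure function of ``(params, seed)`` and returns its
product together with a :class:`GroundTruthManifest` recording the true
parameters, so recovery tests can compare analysis output against truth.

Rendering choices (fixture choices, not physics claims):

* Apertures and the BB are rendered with analytic error-function edges in
  isocenter-plane mm — the Gaussian edge blur (default sigma 0.5 mm) stands
  in for source penumbra and gives exact sub-pixel edge placement.
* The BB is an attenuation (dark) disc on the bright open field; polarity is
  configurable for film-like inputs.
* Noise is additive Gaussian on the normalized intensity, default off.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

from linacqa.beam_data import DetectorReadingTable
from linacqa.core_io import Offset2D, PlanarImage, SixDofShift, ValidationError
from linacqa.end_to_end import DoseGrid
from linacqa.mlc_qa import SweepingGapSeries

__all__ = [
    "GenerationError",
    "GroundTruthManifest",
    "default_geometry",
    "gen_bb_aperture_image",
    "gen_picket_fence_image",
    "gen_star_shot_image",
    "gen_line_pair_image",
    "gen_sweeping_gap_series",
    "FieldFluenceModel",
    "gen_detector_readings",
    "gen_dose_planes",
    "gen_shift_samples",
]


class GenerationError(ValueError):
    """Raised for physically impossible generator parameter combinations."""


@dataclass
class GroundTruthManifest:
    """True parameters behind one synthetic product; JSON-serializable."""

    generator: str
    seed: int | None
    params: dict

    def to_json(self) -> str:
        return json.dumps(
            {"generator": self.generator, "seed": self.seed, "params": self.params},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        d = json.loads(text)
        return cls(generator=d["generator"], seed=d["seed"], params=d["params"])


def default_geometry(**overrides) -> dict:
    """EPID-like default geometry: 0.392 mm pitch, SDD 1500, SAD 1000 mm."""
    geo = {
        "pixel_pitch_mm": 0.392,
        "source_detector_distance_mm": 1500.0,
        "source_axis_distance_mm": 1000.0,
        "shape": (128, 128),
        "gantry_deg": 0.0,
        "collimator_deg": 0.0,
        "table_deg": 0.0,
        "modality_tag": "MV",
    }
    geo.update(overrides)
    return geo


def _iso_grid(geometry: dict) -> tuple[np.ndarray, np.ndarray, float]:
    """Pixel-center coordinate grids (x, y) in isocenter-plane mm."""
    nrow, ncol = geometry["shape"]
    pitch_iso = (
        geometry["pixel_pitch_mm"]
        * geometry["source_axis_distance_mm"]
        / geometry["source_detector_distance_mm"]
    )
    x = (np.arange(ncol) - (ncol - 1) / 2.0) * pitch_iso
    y = (np.arange(nrow) - (nrow - 1) / 2.0) * pitch_iso
    return np.meshgrid(x, y), pitch_iso  # type: ignore[return-value]


def _make_image(pixels: np.ndarray, geometry: dict) -> PlanarImage:
    return PlanarImage(
        pixels=np.clip(pixels, 0.0, None),
        pixel_pitch_mm=geometry["pixel_pitch_mm"],
        source_detector_distance_mm=geometry["source_detector_distance_mm"],
        source_axis_distance_mm=geometry["source_axis_distance_mm"],
        gantry_deg=geometry["gantry_deg"],
        collimator_deg=geometry["collimator_deg"],
        table_deg=geometry["table_deg"],
        modality_tag=geometry["modality_tag"],
    )


def _smooth_interval(u: np.ndarray, half_width: float, sigma: float) -> np.ndarray:
    """erf-smoothed indicator of |u| <= half_width (1 inside, 0 outside)."""
    s = sigma * math.sqrt(2.0)
    if sigma <= 0:
        return (np.abs(u) <= half_width).astype(float)
    return 0.5 * (erf((half_width - u) / s) + erf((half_width + u) / s))


def _smooth_disc(r: np.ndarray, radius: float, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return (r <= radius).astype(float)
    return 0.5 * (1.0 - erf((r - radius) / (sigma * math.sqrt(2.0))))


# ----------------------------------------------------------------------------
# BB + aperture portal image


def gen_bb_aperture_image(
    bb_offset: Offset2D | tuple[float, float],
    aperture: dict,
    geometry: dict | None = None,
    blur_sigma_mm: float = 0.5,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    bb_diameter_mm: float = 5.0,
    field_offset: tuple[float, float] = (0.0, 0.0),
    plateau: float = 1.0,
    background: float = 0.05,
    bb_depth: float = 0.6,
    invert: bool = False,
) -> tuple[PlanarImage, GroundTruthManifest]:
    """Render a BB inside an open MLC/cone aperture at known sub-pixel offset.

    ``aperture`` is ``{"square": (w_mm, h_mm)}`` or ``{"cone": diameter_mm}``,
    sized at the isocenter plane. The BB disc is centered at ``bb_offset``
    (mm, relative to the raster center); the field is centered at
    ``field_offset``. Raises :class:`GenerationError` when the BB would
    overlap the field edge, which would corrupt both detections.
    """
    geometry = geometry or default_geometry()
    if isinstance(bb_offset, Offset2D):
        bb_offset = (bb_offset.x, bb_offset.y)
    (X, Y), pitch_iso = _iso_grid(geometry)
    bx, by = float(bb_offset[0]), float(bb_offset[1])
    fx, fy = float(field_offset[0]), float(field_offset[1])
    bb_r = bb_diameter_mm / 2.0
    margin = bb_r + 3.0 * blur_sigma_mm

    if "square" in aperture:
        w, h = aperture["square"]
        if abs(bx - fx) + margin > w / 2.0 or abs(by - fy) + margin > h / 2.0:
            raise GenerationError("BB overlaps the field edge")
        field_ind = _smooth_interval(X - fx, w / 2.0, blur_sigma_mm) * _smooth_interval(
            Y - fy, h / 2.0, blur_sigma_mm
        )
    elif "cone" in aperture:
        diam = float(aperture["cone"])
        if math.hypot(bx - fx, by - fy) + margin > diam / 2.0:
            raise GenerationError("BB overlaps the field edge")
        r = np.hypot(X - fx, Y - fy)
        field_ind = _smooth_disc(r, diam / 2.0, blur_sigma_mm)
    else:
        raise GenerationError("aperture must specify 'square' or 'cone'")

    r_bb = np.hypot(X - bx, Y - by)
    bb_ind = _smooth_disc(r_bb, bb_r, blur_sigma_mm)
    pixels = background + (plateau - background) * field_ind * (1.0 - bb_depth * bb_ind)
    if invert:
        pixels = (plateau + background) - pixels
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        pixels = pixels + rng.normal(0.0, noise_sigma * plateau, pixels.shape)
    manifest = GroundTruthManifest(
        generator="gen_bb_aperture_image",
        seed=seed,
        params={
            "bb_offset_mm": [bx, by],
            "field_offset_mm": [fx, fy],
            "aperture": {k: list(v) if isinstance(v, (tuple, list)) else v for k, v in aperture.items()},
            "bb_diameter_mm": bb_diameter_mm,
            "blur_sigma_mm": blur_sigma_mm,
            "noise_sigma": noise_sigma,
            "pitch_iso_mm": pitch_iso,
        },
    )
    return _make_image(pixels, geometry), manifest


# ----------------------------------------------------------------------------
# picket fence


def gen_picket_fence_image(
    n_pickets: int,
    spacing_mm: float,
    picket_fwhm_mm: float = 2.2,
    per_picket_error_mm: Sequence[float] | None = None,
    geometry: dict | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    peak: float = 1.0,
    background: float = 0.05,
) -> tuple[PlanarImage, GroundTruthManifest]:
    """Render bright picket bands (Gaussian cross-section along x, uniform
    along y) at the nominal spacing plus injected per-picket errors."""
    geometry = geometry or default_geometry(shape=(96, 640))
    if n_pickets < 1:
        raise GenerationError("need at least one picket")
    if spacing_mm <= picket_fwhm_mm and n_pickets > 1:
        raise GenerationError("spacing must exceed the picket width")
    errors = list(per_picket_error_mm or [0.0] * n_pickets)
    if len(errors) != n_pickets:
        raise GenerationError("per_picket_error_mm must have n_pickets entries")
    (X, Y), pitch_iso = _iso_grid(geometry)
    positions = [
        (i - (n_pickets - 1) / 2.0) * spacing_mm + errors[i] for i in range(n_pickets)
    ]
    half_span = max(abs(p) for p in positions) + 2.0 * picket_fwhm_mm
    if half_span > X.max():
        raise GenerationError("pickets do not fit within the raster")
    sigma = picket_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    pixels = np.full(X.shape, background)
    for p in positions:
        pixels = pixels + (peak - background) * np.exp(-((X - p) ** 2) / (2 * sigma**2))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        pixels = pixels + rng.normal(0.0, noise_sigma * peak, pixels.shape)
    manifest = GroundTruthManifest(
        generator="gen_picket_fence_image",
        seed=seed,
        params={
            "positions_mm": positions,
            "spacing_mm": spacing_mm,
            "gaps_mm": [positions[i + 1] - positions[i] for i in range(n_pickets - 1)],
            "picket_fwhm_mm": picket_fwhm_mm,
            "per_picket_error_mm": errors,
            "max_deviation_mm": max(abs(e) for e in errors),
            "noise_sigma": noise_sigma,
            "pitch_iso_mm": pitch_iso,
        },
    )
    return _make_image(pixels, geometry), manifest


# ----------------------------------------------------------------------------
# star shot


def gen_star_shot_image(
    n_spokes: int,
    spoke_angles_deg: Sequence[float] | None = None,
    center_offset: Offset2D | tuple[float, float] = (0.0, 0.0),
    slit_width_mm: float = 1.5,
    per_spoke_offset_mm: Sequence[float] | None = None,
    geometry: dict | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    plateau: float = 1.0,
    dip_depth: float = 0.7,
) -> tuple[PlanarImage, GroundTruthManifest]:
    """Render dark slit lines through a common (possibly offset) point.

    ``per_spoke_offset_mm`` displaces each line along its unit normal, e.g.
    a constant value ``r`` makes every spoke tangent to the circle of radius
    ``r`` about the center — the geometric truth for wobble-circle tests.
    """
    geometry = geometry or default_geometry(shape=(256, 256))
    if n_spokes < 2:
        raise GenerationError("need at least 2 spokes")
    if isinstance(center_offset, Offset2D):
        center_offset = (center_offset.x, center_offset.y)
    if spoke_angles_deg is None:
        spoke_angles_deg = [180.0 * i / n_spokes for i in range(n_spokes)]
    angles = [a % 180.0 for a in spoke_angles_deg]
    if len(angles) != n_spokes:
        raise GenerationError("spoke_angles_deg must have n_spokes entries")
    for i in range(n_spokes):
        for j in range(i + 1, n_spokes):
            if abs(angles[i] - angles[j]) < 1e-9 or abs(abs(angles[i] - angles[j]) - 180.0) < 1e-9:
                raise GenerationError("duplicate spoke angles (mod 180)")
    offsets = list(per_spoke_offset_mm or [0.0] * n_spokes)
    if len(offsets) != n_spokes:
        raise GenerationError("per_spoke_offset_mm must have n_spokes entries")
    (X, Y), pitch_iso = _iso_grid(geometry)
    cx, cy = float(center_offset[0]), float(center_offset[1])
    sigma = slit_width_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    pixels = np.full(X.shape, plateau)
    for ang, off in zip(angles, offsets):
        theta = math.radians(ang)
        nx, ny = -math.sin(theta), math.cos(theta)
        d = (X - cx) * nx + (Y - cy) * ny - off
        pixels = pixels * (1.0 - dip_depth * np.exp(-(d**2) / (2 * sigma**2)))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        pixels = pixels + rng.normal(0.0, noise_sigma * plateau, pixels.shape)
    manifest = GroundTruthManifest(
        generator="gen_star_shot_image",
        seed=seed,
        params={
            "center_mm": [cx, cy],
            "spoke_angles_deg": angles,
            "per_spoke_offset_mm": offsets,
            "tangent_radius_mm": max(abs(o) for o in offsets),
            "slit_width_mm": slit_width_mm,
            "noise_sigma": noise_sigma,
            "pitch_iso_mm": pitch_iso,
        },
    )
    return _make_image(pixels, geometry), manifest


# ----------------------------------------------------------------------------
# line-pair resolution pattern


def gen_line_pair_image(
    frequencies_lp_mm: Sequence[float],
    blur_sigma_mm: float = 0.2,
    group_height_px: int = 40,
    group_width_mm: float = 12.0,
    geometry: dict | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    n_harmonics: int = 301,
) -> tuple[PlanarImage, list[tuple[tuple[int, int, int, int], float]], GroundTruthManifest]:
    """Render stacked bar-pattern groups blurred by a known Gaussian PSF.

    Each group is a 0/1 square wave along x at one frequency, convolved
    analytically with the PSF via its Fourier series. Returns the image, the
    per-group ROI list suitable for :func:`linacqa.image_quality.compute_rmtf`,
    and a manifest with the exact oracle modulations.
    """
    freqs = [float(f) for f in frequencies_lp_mm]
    if not freqs or any(f <= 0 for f in freqs):
        raise GenerationError("frequencies must be positive")
    if geometry is None:
        # kV-like imaging chain: pitch at the detector surface
        nrows = group_height_px * len(freqs)
        ncols = int(round(group_width_mm / 0.05))
        geometry = default_geometry(
            pixel_pitch_mm=0.05,
            source_detector_distance_mm=1000.0,
            shape=(nrows, ncols),
            modality_tag="kV",
        )
    nrow, ncol = geometry["shape"]
    pitch = geometry["pixel_pitch_mm"]
    x_mm = (np.arange(ncol) - (ncol - 1) / 2.0) * pitch
    pixels = np.zeros((nrow, ncol))
    rois = []
    oracle_mod = {}
    for gi, f in enumerate(freqs):
        profile = np.full(ncol, 0.5)
        # Gaussian-blurred 50% duty square wave via its Fourier series
        for k in range(1, n_harmonics + 1, 2):
            atten = math.exp(-2.0 * (math.pi * k * f * blur_sigma_mm) ** 2)
            if atten < 1e-12:
                break
            profile += (2.0 / (math.pi * k)) * atten * np.sin(2 * math.pi * k * f * x_mm)
        r0, r1 = gi * group_height_px, (gi + 1) * group_height_px
        if r1 > nrow:
            raise GenerationError("groups do not fit within the raster")
        pixels[r0:r1, :] = profile
        rois.append(((r0, r1, 0, ncol), f))
        # oracle modulation: peak-to-trough of the analytic blurred wave
        fine_x = np.linspace(0, 1.0 / f, 2001)
        fine = np.full_like(fine_x, 0.5)
        for k in range(1, n_harmonics + 1, 2):
            atten = math.exp(-2.0 * (math.pi * k * f * blur_sigma_mm) ** 2)
            if atten < 1e-12:
                break
            fine += (2.0 / (math.pi * k)) * atten * np.sin(2 * math.pi * k * f * fine_x)
        hi, lo = float(fine.max()), float(fine.min())
        oracle_mod[str(f)] = (hi - lo) / (hi + lo)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        pixels = pixels + rng.normal(0.0, noise_sigma, pixels.shape)
    manifest = GroundTruthManifest(
        generator="gen_line_pair_image",
        seed=seed,
        params={
            "frequencies_lp_mm": freqs,
            "blur_sigma_mm": blur_sigma_mm,
            "oracle_modulation": oracle_mod,
            "noise_sigma": noise_sigma,
        },
    )
    return _make_image(pixels, geometry), rois, manifest


# ----------------------------------------------------------------------------
# sweeping gap series


def gen_sweeping_gap_series(
    b_gy_per_mm: float,
    delta_mm: float,
    dleak_gy: float,
    gaps_mm: Sequence[float] = (1.0, 5.0, 10.0, 20.0, 50.0, 100.0),
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> tuple[SweepingGapSeries, GroundTruthManifest]:
    """Doses from the linear sweeping-gap model
    ``D = Dleak + b * (gap + 2 * delta)`` with optional Gaussian noise
    (sigma as a fraction of the maximum dose)."""
    gaps = sorted(float(g) for g in set(gaps_mm))
    if len(gaps) < 2:
        raise GenerationError("need at least 2 distinct gaps")
    if any(g <= 0 for g in gaps):
        raise GenerationError("gaps must be positive")
    doses = np.array([dleak_gy + b_gy_per_mm * (g + 2.0 * delta_mm) for g in gaps])
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        doses = doses + rng.normal(0.0, noise_sigma * float(doses.max()), doses.shape)
    series = SweepingGapSeries(gaps_mm=np.array(gaps), doses_gy=doses, dleak_gy=dleak_gy)
    manifest = GroundTruthManifest(
        generator="gen_sweeping_gap_series",
        seed=seed,
        params={
            "b_gy_per_mm": b_gy_per_mm,
            "delta_mm": delta_mm,
            "dleak_gy": dleak_gy,
            "gaps_mm": gaps,
            "noise_sigma": noise_sigma,
        },
    )
    return series, manifest


# ----------------------------------------------------------------------------
# detector readings with volume averaging


@dataclass
class FieldFluenceModel:
    """Analytic 2D fluence: erf-shouldered flat-top square field.

    ``f(x, y) = s(x) * s(y)`` with ``s`` the Gaussian-smoothed indicator of
    the field half-width; overlapping penumbras naturally depress small-field
    on-axis values.
    """

    shoulder_sigma_mm: float = 2.5

    def __call__(self, x: np.ndarray, y: np.ndarray, field_size_mm: float) -> np.ndarray:
        half = field_size_mm / 2.0
        return _smooth_interval(np.asarray(x, dtype=float), half, self.shoulder_sigma_mm) * _smooth_interval(
            np.asarray(y, dtype=float), half, self.shoulder_sigma_mm
        )


def disc_average(
    model: Callable[[np.ndarray, np.ndarray, float], np.ndarray],
    field_size_mm: float,
    aperture_diameter_mm: float,
    n_grid: int = 101,
) -> float:
    """Mean of the 2D fluence over a centered disc of the detector diameter."""
    if aperture_diameter_mm <= 1e-6:
        return float(model(np.zeros(1), np.zeros(1), field_size_mm)[0])
    r = aperture_diameter_mm / 2.0
    ax = np.linspace(-r, r, n_grid)
    X, Y = np.meshgrid(ax, ax)
    mask = X**2 + Y**2 <= r**2
    vals = model(X, Y, field_size_mm)
    return float(vals[mask].mean())


def gen_detector_readings(
    true_profile_model: Callable[[np.ndarray, np.ndarray, float], np.ndarray] | None,
    detector_aperture_mm: Sequence[float],
    field_sizes_mm: Sequence[float],
) -> tuple[dict[str, DetectorReadingTable], GroundTruthManifest]:
    """Per-detector readings as disc averages of the fluence model.

    Detector ids encode the aperture (``d0.6mm`` etc.). Apertures larger
    than the field (plus the shoulder margin) are flagged in the manifest
    but still computed.
    """
    model = true_profile_model or FieldFluenceModel()
    apertures = [float(a) for a in detector_aperture_mm]
    if any(a < 0 for a in apertures):
        raise GenerationError("aperture diameters must be >= 0")
    fields = sorted(float(f) for f in field_sizes_mm)
    tables: dict[str, DetectorReadingTable] = {}
    warnings: list[str] = []
    for a in apertures:
        det_id = f"d{a:g}mm"
        readings = [disc_average(model, f, a) for f in fields]
        for f in fields:
            margin = getattr(model, "shoulder_sigma_mm", 0.0)
            if a > f + margin:
                warnings.append(f"{det_id} aperture exceeds field {f:g} mm")
        tables[det_id] = DetectorReadingTable(
            detector_id=det_id,
            field_sizes_mm=np.array(fields),
            readings=np.array(readings),
        )
    manifest = GroundTruthManifest(
        generator="gen_detector_readings",
        seed=None,
        params={
            "detector_aperture_mm": apertures,
            "field_sizes_mm": fields,
            "warnings": warnings,
        },
    )
    return tables, manifest


# ----------------------------------------------------------------------------
# dose planes


def _default_dose_model(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Plan-like dose: erf-shouldered 40 mm square target, 200 cGy peak."""
    return 200.0 * _smooth_interval(x, 20.0, 3.0) * _smooth_interval(y, 20.0, 3.0)


def gen_dose_planes(
    base: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    perturbation: dict | None = None,
    grid_pitch_mm: float = 1.0,
    shape: tuple[int, int] = (64, 64),
    seed: int | None = None,
) -> tuple[DoseGrid, DoseGrid, GroundTruthManifest]:
    """Reference and perturbed evaluated dose planes on identical grids.

    ``perturbation`` keys: ``scale_pct`` (uniform dose scaling, percent),
    ``shift_mm`` ((dx, dy), applied analytically by sampling the base model
    at shifted coordinates), ``noise_sigma`` (Gaussian, cGy).
    """
    if grid_pitch_mm <= 0:
        raise GenerationError("grid pitch must be positive")
    base = base or _default_dose_model
    pert = dict(perturbation or {})
    nrow, ncol = shape
    x = (np.arange(ncol) - (ncol - 1) / 2.0) * grid_pitch_mm
    y = (np.arange(nrow) - (nrow - 1) / 2.0) * grid_pitch_mm
    X, Y = np.meshgrid(x, y)
    ref = base(X, Y)
    dx, dy = pert.get("shift_mm", (0.0, 0.0))
    ev = base(X - dx, Y - dy)
    ev = ev * (1.0 + pert.get("scale_pct", 0.0) / 100.0)
    if pert.get("noise_sigma", 0.0) > 0:
        rng = np.random.default_rng(seed)
        ev = ev + rng.normal(0.0, pert["noise_sigma"], ev.shape)
    manifest = GroundTruthManifest(
        generator="gen_dose_planes",
        seed=seed,
        params={
            "scale_pct": pert.get("scale_pct", 0.0),
            "shift_mm": [dx, dy],
            "noise_sigma": pert.get("noise_sigma", 0.0),
            "grid_pitch_mm": grid_pitch_mm,
            "shape": list(shape),
        },
    )
    return (
        DoseGrid(dose=np.clip(ref, 0, None), pitch_mm=grid_pitch_mm),
        DoseGrid(dose=np.clip(ev, 0, None), pitch_mm=grid_pitch_mm),
        manifest,
    )


# ----------------------------------------------------------------------------
# 6-DOF setup-error samples


def gen_shift_samples(
    sigma_trans_mm: float,
    sigma_rot_deg: float,
    n: int,
    seed: int | None = None,
) -> tuple[list[SixDofShift], GroundTruthManifest]:
    """Independent zero-mean Gaussian 6-DOF setup errors."""
    if n < 1:
        raise GenerationError("n must be >= 1")
    if sigma_trans_mm < 0 or sigma_rot_deg < 0:
        raise GenerationError("sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    trans = rng.normal(0.0, sigma_trans_mm, (n, 3)) if sigma_trans_mm > 0 else np.zeros((n, 3))
    rots = rng.normal(0.0, sigma_rot_deg, (n, 3)) if sigma_rot_deg > 0 else np.zeros((n, 3))
    shifts = [
        SixDofShift(
            dx=float(t[0]), dy=float(t[1]), dz=float(t[2]),
            r_lr=float(r[0]), r_pa=float(r[1]), r_si=float(r[2]),
        )
        for t, r in zip(trans, rots)
    ]
    manifest = GroundTruthManifest(
        generator="gen_shift_samples",
        seed=seed,
        params={"sigma_trans_mm": sigma_trans_mm, "sigma_rot_deg": sigma_rot_deg, "n": n},
    )
    return shifts, manifest
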