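"""Shared domain types, file I/O, and coordinate conventions.

Coordinate conventions (fixed once, used everywhere):

* Pixel coordinates are 0-based and refer to pixel centers.
* Image axes follow the beam's-eye view at collimator 0: ``x`` increases to
  the viewer's right, ``y`` increases downward in the stored raster.
* All reported distances are at the isocenter plane: detector-plane
  millimetres divided by the magnification ``SDD / SAD``.
* In-plane offsets use left(-)/right(+) for x and up(-)/down(+) for y.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "ConfigurationError",
    "ValidationError",
    "Point2D",
    "Offset2D",
    "SixDofShift",
    "PlanarImage",
    "ScanProfile",
    "read_planar_image",
    "write_planar_image",
    "read_scan_profiles",
    "write_scan_profiles",
    "read_shift_log",
    "write_shift_log",
]


class FormatError(ValueError):
    """Raised when a file cannot be decoded in any supported format."""


class ConfigurationError(ValueError):
    """Raised when required geometry/metadata is missing."""


class ValidationError(ValueError):
    """Raised when parsed content violates a schema or invariant."""


@dataclass(frozen=True)
class Point2D:
    """A 2D point in isocenter-plane mm; x left(-)/right(+), y up(-)/down(+)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"non-finite point ({self.x}, {self.y})")

    def __sub__(self, other: "Point2D") -> "Offset2D":
        return Offset2D(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class Offset2D:
    """A 2D displacement in isocenter-plane mm, same sign convention as Point2D."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"non-finite offset ({self.x}, {self.y})")

    @property
    def norm(self) -> float:
        return math.hypot(self.x, self.y)


@dataclass(frozen=True)
class SixDofShift:
    """A six-degree-of-freedom couch shift.

    Translations in mm along the L/R, P/A and S/I patient axes; rotations in
    degrees about the same axes, restricted to (-180, 180].
    """

    dx: float = 0.0
    dy: float = 0.0
    dz: float = 0.0
    r_lr: float = 0.0
    r_pa: float = 0.0
    r_si: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.dx, self.dy, self.dz, self.r_lr, self.r_pa, self.r_si)
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError(f"non-finite shift components {vals}")
        for r in (self.r_lr, self.r_pa, self.r_si):
            if not (-180.0 < r <= 180.0):
                raise ValidationError(f"rotation {r} deg outside (-180, 180]")

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz], dtype=float)

    @property
    def rotation_deg(self) -> np.ndarray:
        return np.array([self.r_lr, self.r_pa, self.r_si], dtype=float)


@dataclass
class PlanarImage:
    """A calibrated 2D grayscale raster with projection geometry.

    Attributes
    ----------
    pixels
        Non-negative 2D array; row index is the raster y axis (downward),
        column index the x axis (rightward).
    pixel_pitch_mm
        Physical pixel pitch at the detector plane.
    source_axis_distance_mm, source_detector_distance_mm
        Projection geometry; ``magnification = SDD / SAD >= 1``.
    gantry_deg, collimator_deg, table_deg
        Acquisition angles.
    modality_tag
        One of ``{"MV", "kV", "film"}``.
    """

    pixels: np.ndarray
    pixel_pitch_mm: float
    source_detector_distance_mm: float
    source_axis_distance_mm: float = 1000.0
    gantry_deg: float = 0.0
    collimator_deg: float = 0.0
    table_deg: float = 0.0
    modality_tag: str = "MV"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValidationError("raster must be 2D with >= 2 rows and columns")
        if np.any(self.pixels < 0):
            raise ValidationError("raster must be non-negative")
        if self.pixel_pitch_mm <= 0:
            raise ValidationError("pixel_pitch_mm must be > 0")
        if self.source_axis_distance_mm <= 0:
            raise ValidationError("SAD must be > 0")
        if self.source_detector_distance_mm < self.source_axis_distance_mm:
            raise ValidationError("SDD must be >= SAD")
        if self.modality_tag not in {"MV", "kV", "film"}:
            raise ValidationError(f"unknown modality_tag {self.modality_tag!r}")

    @property
    def magnification(self) -> float:
        return self.source_detector_distance_mm / self.source_axis_distance_mm

    @property
    def pitch_iso_mm(self) -> float:
        """Pixel pitch projected back to the isocenter plane."""
        return self.pixel_pitch_mm / self.magnification

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def center_px(self) -> tuple[float, float]:
        """(col, row) of the raster center in pixel-center coordinates."""
        nrow, ncol = self.pixels.shape
        return ((ncol - 1) / 2.0, (nrow - 1) / 2.0)

    def px_to_iso(self, col: float, row: float) -> Point2D:
        """Convert pixel coordinates to isocenter-plane mm about raster center."""
        c0, r0 = self.center_px()
        return Point2D((col - c0) * self.pitch_iso_mm, (row - r0) * self.pitch_iso_mm)

    def iso_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """1D isocenter-plane mm coordinates (x per column, y per row)."""
        nrow, ncol = self.pixels.shape
        c0, r0 = self.center_px()
        x = (np.arange(ncol) - c0) * self.pitch_iso_mm
        y = (np.arange(nrow) - r0) * self.pitch_iso_mm
        return x, y


@dataclass
class ScanProfile:
    """A 1D water-tank scan: a PDD (depth axis) or a lateral profile.

    Values are renormalized so the profile maximum is 100.
    """

    positions: np.ndarray
    values: np.ndarray
    axis_tag: str
    field_size_mm: tuple[float, float] = (100.0, 100.0)
    detector_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.axis_tag not in {"depth", "inplane", "crossplane"}:
            raise ValidationError(f"unknown axis_tag {self.axis_tag!r}")
        if self.positions.ndim != 1 or self.positions.size != self.values.size:
            raise ValidationError("positions and values must be 1D and equal length")
        if self.positions.size < 2:
            raise ValidationError("profile needs >= 2 samples")
        if np.any(np.diff(self.positions) <= 0):
            raise ValidationError("positions must be strictly increasing")
        if np.any(self.values < 0):
            raise ValidationError("values must be >= 0")
        vmax = float(self.values.max())
        if vmax <= 0:
            raise ValidationError("profile has no positive values")
        self.values = self.values * (100.0 / vmax)


# ----------------------------------------------------------------------------
# planar image I/O


def _load_dicom_pixels(path: Path) -> tuple[np.ndarray, dict]:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise FormatError("DICOM support requires the optional pydicom package") from exc
    ds = pydicom.dcmread(str(path))
    meta: dict = {}
    spacing = getattr(ds, "ImagePlanePixelSpacing", None) or getattr(
        ds, "PixelSpacing", None
    )
    if spacing is not None:
        meta["pixel_pitch_mm"] = float(spacing[0])
    for tag, key in [
        ("RTImageSID", "source_detector_distance_mm"),
        ("RadiationMachineSAD", "source_axis_distance_mm"),
        ("GantryAngle", "gantry_deg"),
        ("BeamLimitingDeviceAngle", "collimator_deg"),
        ("PatientSupportAngle", "table_deg"),
    ]:
        if hasattr(ds, tag):
            meta[key] = float(getattr(ds, tag))
    return np.asarray(ds.pixel_array, dtype=float), meta


def read_planar_image(path: str | Path, meta: dict | None = None) -> PlanarImage:
    """Read an 8/16-bit grayscale TIFF/PNG (or single-frame DICOM) image.

    ``meta`` supplies any geometry absent from the file; keys mirror the
    :class:`PlanarImage` fields. Pixel values are never rescaled.
    """
    path = Path(path)
    meta = dict(meta or {})
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    file_meta: dict = {}
    if suffix in {".dcm", ".dicom"}:
        pixels, file_meta = _load_dicom_pixels(path)
    else:
        try:
            if suffix in {".tif", ".tiff"}:
                import tifffile

                pixels = np.asarray(tifffile.imread(str(path)), dtype=float)
            else:
                import imageio.v3 as iio

                pixels = np.asarray(iio.imread(str(path)), dtype=float)
        except Exception as exc:
            raise FormatError(f"could not decode {path}: {exc}") from exc
    if pixels.ndim == 3:  # collapse trivial channel axes from PNG writers
        if pixels.shape[2] in (3, 4) and np.allclose(
            pixels[..., 0], pixels[..., 1]
        ) and np.allclose(pixels[..., 0], pixels[..., 2]):
            pixels = pixels[..., 0]
        else:
            raise FormatError(f"{path} is not grayscale")
    merged = {**file_meta, **meta}
    if "pixel_pitch_mm" not in merged:
        raise ConfigurationError("pixel_pitch_mm missing from file and meta")
    if "source_detector_distance_mm" not in merged:
        raise ConfigurationError(
            "source_detector_distance_mm missing from file and meta"
        )
    allowed = {
        "pixel_pitch_mm",
        "source_detector_distance_mm",
        "source_axis_distance_mm",
        "gantry_deg",
        "collimator_deg",
        "table_deg",
        "modality_tag",
    }
    unknown = set(merged) - allowed
    if unknown:
        raise ConfigurationError(f"unknown meta keys: {sorted(unknown)}")
    return PlanarImage(pixels=pixels, **merged)


def write_planar_image(image: PlanarImage, path: str | Path) -> None:
    """Write the raster as 16-bit grayscale TIFF or PNG (values must fit)."""
    path = Path(path)
    arr = image.pixels
    if np.any(arr < 0) or np.any(arr > 65535):
        raise ValidationError("pixel values must lie in [0, 65535] for 16-bit output")
    data = np.round(arr).astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(str(path), data)
    else:
        import imageio.v3 as iio

        iio.imwrite(str(path), data)


# ----------------------------------------------------------------------------
# CSV I/O — single dialect: comma separator, mandatory header, '.' decimal

_PROFILE_COLUMNS = ["axis_tag", "field_w", "field_h", "detector", "position_mm", "value"]


def read_scan_profiles(path: str | Path) -> list[ScanProfile]:
    """Read scan profiles from CSV.

    One profile per (axis_tag, field, detector) block; rows are sorted by
    position and the profile is renormalized to max 100.
    """
    path = Path(path)
    groups: dict[tuple, list[tuple[float, float]]] = {}
    order: list[tuple] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(_PROFILE_COLUMNS) - set(reader.fieldnames):
            raise ValidationError(
                f"profile CSV must have columns {_PROFILE_COLUMNS}, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader):
            try:
                key = (
                    row["axis_tag"],
                    float(row["field_w"]),
                    float(row["field_h"]),
                    row["detector"],
                )
                pos, val = float(row["position_mm"]), float(row["value"])
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"bad value in row {i + 2}: {exc}") from exc
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append((pos, val))
    if not order:
        raise ValidationError(f"no profile rows in {path}")
    profiles = []
    for key in order:
        rows = sorted(groups[key])
        positions = [p for p, _ in rows]
        if len(set(positions)) != len(positions):
            raise ValidationError(f"duplicated positions in profile block {key}")
        profiles.append(
            ScanProfile(
                positions=np.array(positions),
                values=np.array([v for _, v in rows]),
                axis_tag=key[0],
                field_size_mm=(key[1], key[2]),
                detector_id=key[3],
            )
        )
    return profiles


def write_scan_profiles(profiles: Iterable[ScanProfile], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PROFILE_COLUMNS)
        for p in profiles:
            for pos, val in zip(p.positions, p.values):
                writer.writerow(
                    [
                        p.axis_tag,
                        p.field_size_mm[0],
                        p.field_size_mm[1],
                        p.detector_id,
                        repr(float(pos)),
                        repr(float(val)),
                    ]
                )


_SHIFT_COLUMNS = ["dx", "dy", "dz", "r_lr", "r_pa", "r_si"]


def read_shift_log(path: str | Path) -> list[SixDofShift]:
    """Read a 6-DOF registration shift log (mm / degrees), order preserved."""
    shifts: list[SixDofShift] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(_SHIFT_COLUMNS) - set(reader.fieldnames):
            raise ValidationError(
                f"shift CSV must have columns {_SHIFT_COLUMNS}, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader):
            try:
                vals = {c: float(row[c]) for c in _SHIFT_COLUMNS}
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"non-numeric value in shift log row {i + 2}"
                ) from exc
            shifts.append(SixDofShift(**vals))
    return shifts


def write_shift_log(shifts: Sequence[SixDofShift], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SHIFT_COLUMNS)
        for s in shifts:
            writer.writerow(
                [repr(float(getattr(s, c))) for c in _SHIFT_COLUMNS]
            )
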