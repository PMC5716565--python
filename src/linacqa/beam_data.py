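"""Scanned beam-data reduction: PDD queries, lateral-profile metrics, and
output-factor daisy-chaining across detectors.

Interpolation is piecewise-linear throughout so worked examples are exact.
Percent levels on lateral profiles are relative to the on-axis value, not
the global maximum, so off-axis horns do not bias penumbra widths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from linacqa.core_io import ScanProfile, ValidationError

__all__ = [
    "RangeError",
    "MetricError",
    "ChainingError",
    "ComparisonError",
    "DetectorReadingTable",
    "OutputFactorCurve",
    "ProfileMetrics",
    "pdd_at_depth",
    "profile_metrics",
    "daisy_chain_output_factors",
    "compare_detectors",
]


class RangeError(ValueError):
    pass


class MetricError(RuntimeError):
    pass


class ChainingError(RuntimeError):
    pass


class ComparisonError(RuntimeError):
    pass


@dataclass
class DetectorReadingTable:
    """Per-field-size readings of one detector (square side in mm, a.u.)."""

    detector_id: str
    field_sizes_mm: np.ndarray
    readings: np.ndarray

    def __post_init__(self) -> None:
        self.field_sizes_mm = np.asarray(self.field_sizes_mm, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        if self.field_sizes_mm.size != self.readings.size:
            raise ValidationError("field sizes and readings must align")
        if np.any(self.readings <= 0):
            raise ValidationError("readings must be positive")
        order = np.argsort(self.field_sizes_mm)
        self.field_sizes_mm = self.field_sizes_mm[order]
        self.readings = self.readings[order]
        if np.any(np.diff(self.field_sizes_mm) == 0):
            raise ValidationError("field sizes must be unique")

    def reading_at(self, field_mm: float) -> float:
        match = np.isclose(self.field_sizes_mm, field_mm)
        if not match.any():
            raise ChainingError(
                f"detector {self.detector_id!r} has no reading at {field_mm} mm"
            )
        return float(self.readings[match][0])

    def has(self, field_mm: float) -> bool:
        return bool(np.isclose(self.field_sizes_mm, field_mm).any())


@dataclass
class OutputFactorCurve:
    """Output (total scatter) factors relative to the reference field size."""

    field_sizes_mm: np.ndarray
    factors: np.ndarray
    reference_mm: float = 100.0
    detector_id: str = ""

    def __post_init__(self) -> None:
        self.field_sizes_mm = np.asarray(self.field_sizes_mm, dtype=float)
        self.factors = np.asarray(self.factors, dtype=float)
        if self.field_sizes_mm.size != self.factors.size:
            raise ValidationError("field sizes and factors must align")
        if np.any(self.factors <= 0):
            raise ValidationError("factors must be positive")
        ref_match = np.isclose(self.field_sizes_mm, self.reference_mm)
        if ref_match.any() and not np.allclose(self.factors[ref_match], 1.0):
            raise ValidationError("factor at the reference field size must be 1")


@dataclass(frozen=True)
class ProfileMetrics:
    fwhm_mm: float
    penumbra_left_mm: float
    penumbra_right_mm: float
    edge_left_mm: float
    edge_right_mm: float

    def __post_init__(self) -> None:
        if self.fwhm_mm <= 0:
            raise ValidationError("FWHM must be positive")
        if self.penumbra_left_mm < 0 or self.penumbra_right_mm < 0:
            raise ValidationError("penumbrae must be >= 0")


def pdd_at_depth(profile: ScanProfile, depth_mm: float) -> float:
    """Percent depth dose at ``depth_mm``, linear interpolation on the
    max-normalized curve."""
    if profile.axis_tag != "depth":
        raise ValidationError("pdd_at_depth requires a depth-axis profile")
    lo, hi = float(profile.positions[0]), float(profile.positions[-1])
    if not (lo <= depth_mm <= hi):
        raise RangeError(f"depth {depth_mm} outside scanned range [{lo}, {hi}]")
    return float(np.interp(depth_mm, profile.positions, profile.values))


def _crossing_outward(
    positions: np.ndarray, values: np.ndarray, level: float, side: str
) -> float:
    """Off-axis position where the profile falls through ``level``.

    ``side`` is "left" (negative positions) or "right". The search walks
    outward from the central axis and interpolates the first downward
    crossing, which is robust to noise in the far tail.
    """
    n = positions.size
    i0 = int(np.argmin(np.abs(positions)))
    if side == "right":
        idx = range(i0, n - 1)
        pairs = [(i, i + 1) for i in idx]
    else:
        idx = range(i0, 0, -1)
        pairs = [(i, i - 1) for i in idx]
    for a, b in pairs:
        va, vb = values[a], values[b]
        if va >= level >= vb:
            if va == vb:
                return float(positions[b])
            frac = (va - level) / (va - vb)
            return float(positions[a] + frac * (positions[b] - positions[a]))
    raise MetricError(f"profile never falls through {level:.1f}% on the {side}")


def profile_metrics(profile: ScanProfile) -> ProfileMetrics:
    """FWHM and 80%-to-20% penumbrae of a lateral profile.

    Percent levels are relative to the interpolated on-axis (position 0)
    value; crossings are found by linear interpolation walking outward from
    the axis.
    """
    if profile.axis_tag == "depth":
        raise ValidationError("profile_metrics requires a lateral profile")
    pos, val = profile.positions, profile.values
    if not (pos[0] < 0 < pos[-1]):
        raise MetricError("profile does not span the central axis")
    cax = float(np.interp(0.0, pos, val))
    if cax <= 0:
        raise MetricError("non-positive on-axis value")
    rel = val * (100.0 / cax)
    left50 = _crossing_outward(pos, rel, 50.0, "left")
    right50 = _crossing_outward(pos, rel, 50.0, "right")
    left80 = _crossing_outward(pos, rel, 80.0, "left")
    left20 = _crossing_outward(pos, rel, 20.0, "left")
    right80 = _crossing_outward(pos, rel, 80.0, "right")
    right20 = _crossing_outward(pos, rel, 20.0, "right")
    return ProfileMetrics(
        fwhm_mm=right50 - left50,
        penumbra_left_mm=abs(left20 - left80),
        penumbra_right_mm=abs(right20 - right80),
        edge_left_mm=left50,
        edge_right_mm=right50,
    )


def daisy_chain_output_factors(
    small_detector: DetectorReadingTable,
    reference_detector: DetectorReadingTable,
    intermediate_mm: float = 30.0,
    reference_mm: float = 100.0,
) -> OutputFactorCurve:
    """Daisy-chain output factors across two detectors.

    For fields smaller than the intermediate size, the small detector's
    reading ratio is renormalized through the intermediate field measured by
    the reference detector:

        OF(f) = D_small(f) / D_small(intermediate)
                * D_ref(intermediate) / D_ref(reference)

    For fields at or above the intermediate size the reference detector is
    used directly: OF(f) = D_ref(f) / D_ref(reference).
    """
    if not small_detector.has(intermediate_mm):
        raise ChainingError(
            f"small detector lacks the intermediate field {intermediate_mm} mm"
        )
    if not reference_detector.has(intermediate_mm) or not reference_detector.has(
        reference_mm
    ):
        raise ChainingError(
            "reference detector must include the intermediate and reference fields"
        )
    d_small_int = small_detector.reading_at(intermediate_mm)
    d_ref_int = reference_detector.reading_at(intermediate_mm)
    d_ref_ref = reference_detector.reading_at(reference_mm)
    chain = d_ref_int / d_ref_ref

    fields: list[float] = []
    factors: list[float] = []
    for f, d in zip(small_detector.field_sizes_mm, small_detector.readings):
        if f < intermediate_mm:
            fields.append(float(f))
            factors.append(float(d / d_small_int * chain))
    for f, d in zip(reference_detector.field_sizes_mm, reference_detector.readings):
        if f >= intermediate_mm:
            fields.append(float(f))
            factors.append(float(d / d_ref_ref))
    order = np.argsort(fields)
    return OutputFactorCurve(
        field_sizes_mm=np.array(fields)[order],
        factors=np.array(factors)[order],
        reference_mm=reference_mm,
        detector_id=f"{small_detector.detector_id}+{reference_detector.detector_id}",
    )


def compare_detectors(curves: list[OutputFactorCurve]) -> dict:
    """Pairwise percent differences between output-factor curves.

    Differences are evaluated on the common field sizes only; the largest
    absolute pairwise difference and spread per field size are flagged.
    """
    if len(curves) < 2:
        raise ComparisonError("need at least two curves")
    common = set(np.round(curves[0].field_sizes_mm, 6))
    for c in curves[1:]:
        common &= set(np.round(c.field_sizes_mm, 6))
    if not common:
        raise ComparisonError("no overlapping field sizes")
    fields = sorted(common)
    table = []
    for f in fields:
        vals = []
        for c in curves:
            i = int(np.argmin(np.abs(c.field_sizes_mm - f)))
            vals.append(float(c.factors[i]))
        pair_diffs = {}
        for a in range(len(curves)):
            for b in range(a + 1, len(curves)):
                ida = curves[a].detector_id or f"curve{a}"
                idb = curves[b].detector_id or f"curve{b}"
                pair_diffs[f"{ida}-{idb}"] = 100.0 * (vals[a] - vals[b]) / vals[b]
        table.append(
            {
                "field_mm": float(f),
                "factors": vals,
                "spread": float(max(vals) - min(vals)),
                "pair_diff_pct": pair_diffs,
            }
        )
    max_row = max(table, key=lambda r: r["spread"])
    return {
        "per_field": table,
        "max_spread": max_row["spread"],
        "max_spread_field_mm": max_row["field_mm"],
    }
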