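"""Relative modulation transfer function (RMTF) from line-pair phantom
images and the 50% frequency summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from linacqa.core_io import PlanarImage, ValidationError

__all__ = ["MTFCurve", "RangeError", "compute_rmtf", "f50", "modulation_from_profile"]


class RangeError(ValueError):
    pass


@dataclass
class MTFCurve:
    """RMTF samples (lp/mm vs dimensionless), normalized at one frequency."""

    frequencies: np.ndarray
    rmtf: np.ndarray
    norm_frequency: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.rmtf = np.asarray(self.rmtf, dtype=float)
        if self.frequencies.size != self.rmtf.size:
            raise ValidationError("frequencies and rmtf must align")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValidationError("frequencies must be strictly increasing")
        if np.any(self.rmtf < 0):
            raise ValidationError("rmtf must be >= 0")
        i = np.isclose(self.frequencies, self.norm_frequency)
        if i.any() and not np.allclose(self.rmtf[i], 1.0):
            raise ValidationError("rmtf at the normalization frequency must be 1")


def modulation_from_profile(
    profile: np.ndarray, pitch_mm: float, frequency_lp_mm: float
) -> float:
    """Modulation (P_high - P_low)/(P_high + P_low) of a bar-pattern profile.

    Peaks and troughs are located with a minimum separation of ~70% of the
    bar period, and their medians give the robust high/low plateau levels.
    """
    profile = np.asarray(profile, dtype=float)
    period_px = 1.0 / (frequency_lp_mm * pitch_mm)
    dist = max(1, int(0.7 * period_px))
    span = float(profile.max() - profile.min())
    if span <= 0:
        raise ValidationError("flat profile: no bars detectable")
    prom = 0.1 * span
    peaks, _ = signal.find_peaks(profile, distance=dist, prominence=prom)
    troughs, _ = signal.find_peaks(-profile, distance=dist, prominence=prom)
    if peaks.size < 2 or troughs.size < 2:
        raise ValidationError("fewer than two bar periods detected")
    p_high = float(np.median(profile[peaks]))
    p_low = float(np.median(profile[troughs]))
    if p_high + p_low <= 0:
        raise ValidationError("degenerate bar levels")
    return max(0.0, (p_high - p_low) / (p_high + p_low))


def compute_rmtf(
    image: PlanarImage,
    group_rois: list[tuple[tuple[int, int, int, int], float]],
    norm_frequency: float = 0.5,
) -> MTFCurve:
    """RMTF from line-pair group ROIs on one image.

    Each ROI is ``(row0, row1, col0, col1)`` (half-open pixel bounds) paired
    with its bar frequency in lp/mm; bars must run perpendicular to the
    column axis. The ROI's mean 1D profile (averaged over rows) yields the
    modulation, and every group is normalized by the modulation at
    ``norm_frequency``. Groups without detectable bars are dropped.
    """
    freqs = [f for _, f in group_rois]
    if not any(np.isclose(f, norm_frequency) for f in freqs):
        raise ValidationError(
            f"normalization frequency {norm_frequency} lp/mm not among the ROIs"
        )
    pitch = image.pitch_iso_mm if image.modality_tag == "MV" else image.pixel_pitch_mm
    mods: dict[float, float] = {}
    for (r0, r1, c0, c1), f in group_rois:
        roi = image.pixels[r0:r1, c0:c1]
        if roi.size == 0:
            continue
        profile = roi.mean(axis=0)
        try:
            mods[f] = modulation_from_profile(profile, pitch, f)
        except ValidationError:
            continue  # group flagged absent
    norm_key = min(mods, key=lambda f: abs(f - norm_frequency), default=None)
    if norm_key is None or not np.isclose(norm_key, norm_frequency):
        raise ValidationError("no detectable bars at the normalization frequency")
    m_norm = mods[norm_key]
    if m_norm <= 0:
        raise ValidationError("zero modulation at the normalization frequency")
    freqs_sorted = sorted(mods)
    return MTFCurve(
        frequencies=np.array(freqs_sorted),
        rmtf=np.array([mods[f] / m_norm for f in freqs_sorted]),
        norm_frequency=norm_frequency,
    )


def f50(curve: MTFCurve) -> float:
    """Frequency (lp/mm) of the first downward crossing of RMTF = 0.5."""
    f, r = curve.frequencies, curve.rmtf
    for i in range(f.size - 1):
        if r[i] >= 0.5 > r[i + 1]:
            frac = (r[i] - 0.5) / (r[i] - r[i + 1])
            return float(f[i] + frac * (f[i + 1] - f[i]))
    raise RangeError("RMTF never crosses 0.5 within the tabulated range")
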