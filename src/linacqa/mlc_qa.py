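"""MLC quality-assurance analyses: picket fence, star shot, transmission,
and the dynamic-leaf-gap fit from sweeping-gap dose series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from linacqa.core_io import PlanarImage, Point2D, ValidationError

__all__ = [
    "GeometryError",
    "FitError",
    "PicketFenceResult",
    "StarShotResult",
    "SweepingGapSeries",
    "DLGFit",
    "analyze_picket_fence",
    "analyze_star_shot",
    "mlc_transmission",
    "fit_dynamic_leaf_gap",
    "min_enclosing_circle",
]


class GeometryError(RuntimeError):
    """Raised for degenerate geometric configurations (e.g. parallel slits)."""


class FitError(RuntimeError):
    """Raised when a regression is singular or physically inconsistent."""


class DetectionError(RuntimeError):
    pass


# ----------------------------------------------------------------------------
# picket fence


@dataclass(frozen=True)
class PicketFenceResult:
    """Per-picket positions (isocenter mm along leaf travel), spacings and widths."""

    positions_mm: tuple[float, ...]
    distances_mm: tuple[float, ...]
    fwhm_mm: tuple[float, ...]
    max_deviation_mm: float
    deviations_mm: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.distances_mm) != len(self.positions_mm) - 1:
            raise ValidationError("distances must have len(positions) - 1 entries")
        if any(w <= 0 for w in self.fwhm_mm):
            raise ValidationError("FWHM must be positive")


def _band_centroid_and_fwhm(
    profile: np.ndarray, x_mm: np.ndarray, peak: int, base: float
) -> tuple[float, float]:
    """Centroid and half-prominence FWHM of the band around ``peak``."""
    level = base + 0.5 * (profile[peak] - base)
    lo = peak
    while lo > 0 and profile[lo - 1] >= level:
        lo -= 1
    hi = peak
    while hi < profile.size - 1 and profile[hi + 1] >= level:
        hi += 1
    if lo == 0 or hi == profile.size - 1:
        raise DetectionError("picket band touches the image border")
    # sub-pixel half-maximum crossings
    left = np.interp(level, [profile[lo - 1], profile[lo]], [x_mm[lo - 1], x_mm[lo]])
    right = np.interp(
        level, [profile[hi + 1], profile[hi]], [x_mm[hi + 1], x_mm[hi]]
    )
    fwhm = float(right - left)
    # centroid over the full band above the baseline, extended to ~2x FWHM
    halfwin = hi - lo + 1
    a, b = max(0, lo - halfwin), min(profile.size, hi + halfwin + 1)
    w = np.clip(profile[a:b] - base, 0.0, None)
    centroid = float(np.sum(w * x_mm[a:b]) / np.sum(w))
    return centroid, fwhm


def analyze_picket_fence(
    image: PlanarImage, nominal_spacing_mm: float
) -> PicketFenceResult:
    """Analyze a picket-fence exposure of parallel bright bands.

    The image is averaged along the direction orthogonal to leaf travel
    (rows), bands are detected on the mean 1D profile, and each picket
    position is the baseline-subtracted centroid of its band. Deviations are
    signed distances from the best-fit equispaced grid at the nominal
    spacing with free phase.
    """
    if nominal_spacing_mm <= 0:
        raise ValidationError("nominal spacing must be > 0")
    profile = image.pixels.mean(axis=0)
    x_mm, _ = image.iso_coords()
    base = float(np.median(profile[profile <= np.quantile(profile, 0.25)]))
    prominence = 0.4 * (float(profile.max()) - base)
    if prominence <= 0:
        raise DetectionError("flat profile: no pickets")
    min_dist = max(1, int(0.5 * nominal_spacing_mm / image.pitch_iso_mm))
    peaks, _ = signal.find_peaks(profile, prominence=prominence, distance=min_dist)
    if peaks.size < 2:
        raise DetectionError(f"only {peaks.size} picket band(s) detected")
    positions, widths = [], []
    for pk in peaks:
        c, w = _band_centroid_and_fwhm(profile, x_mm, int(pk), base)
        positions.append(c)
        widths.append(w)
    positions_arr = np.array(positions)
    distances = np.diff(positions_arr)
    # free-phase equispaced reference: positions_i ~ phase + i * nominal;
    # median phase keeps a single errant picket from dragging the grid
    idx = np.arange(positions_arr.size)
    phase = float(np.median(positions_arr - idx * nominal_spacing_mm))
    deviations = positions_arr - (phase + idx * nominal_spacing_mm)
    return PicketFenceResult(
        positions_mm=tuple(float(p) for p in positions_arr),
        distances_mm=tuple(float(d) for d in distances),
        fwhm_mm=tuple(float(w) for w in widths),
        max_deviation_mm=float(np.max(np.abs(deviations))),
        deviations_mm=tuple(float(d) for d in deviations),
    )


# ----------------------------------------------------------------------------
# star shot


@dataclass(frozen=True)
class StarShotResult:
    """Fitted spoke lines, their pairwise intersections, and the wobble circle."""

    lines: tuple[tuple[float, float], ...]  # (angle_deg mod 180, signed offset mm)
    intersections: tuple[tuple[float, float], ...]
    circle_center: Point2D
    circle_radius_mm: float


def min_enclosing_circle(
    points: np.ndarray,
) -> tuple[tuple[float, float], float]:
    """Exact minimum enclosing circle via Welzl's move-to-front algorithm."""
    pts = [tuple(map(float, p)) for p in np.asarray(points, dtype=float)]
    if not pts:
        raise ValidationError("no points")

    def circle_two(a, b):
        cx, cy = (a[0] + b[0]) / 2, (a[1] + b[1]) / 2
        r = math.dist(a, b) / 2
        return (cx, cy), r

    def circle_three(a, b, c):
        ax, ay = a
        bx, by = b
        cx, cy = c
        d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-14:
            return None
        ux = (
            (ax**2 + ay**2) * (by - cy)
            + (bx**2 + by**2) * (cy - ay)
            + (cx**2 + cy**2) * (ay - by)
        ) / d
        uy = (
            (ax**2 + ay**2) * (cx - bx)
            + (bx**2 + by**2) * (ax - cx)
            + (cx**2 + cy**2) * (bx - ax)
        ) / d
        return (ux, uy), math.dist((ux, uy), a)

    def contains(circle, p, eps=1e-9):
        (cx, cy), r = circle
        return math.dist((cx, cy), p) <= r + eps

    def welzl(P, R):
        if not P or len(R) == 3:
            if len(R) == 0:
                return ((0.0, 0.0), 0.0)
            if len(R) == 1:
                return (R[0], 0.0)
            if len(R) == 2:
                return circle_two(R[0], R[1])
            c = circle_three(R[0], R[1], R[2])
            if c is None:  # collinear boundary set
                best = None
                for i in range(3):
                    for j in range(i + 1, 3):
                        cand = circle_two(R[i], R[j])
                        if all(contains(cand, q) for q in R):
                            if best is None or cand[1] < best[1]:
                                best = cand
                return best
            return c
        p = P[-1]
        c = welzl(P[:-1], R)
        if c is not None and contains(c, p):
            return c
        return welzl(P[:-1], R + [p])

    rng = np.random.default_rng(0)
    order = list(rng.permutation(len(pts)))
    shuffled = [pts[i] for i in order]
    (cx, cy), r = welzl(shuffled, [])
    return (cx, cy), r


def _line_intersection(theta1, d1, theta2, d2):
    """Intersection of two lines in normal form n.x = d (theta = line direction).

    Line i passes through d_i * n_i with direction u_i, where n_i is the unit
    normal of u_i.
    """
    n1 = (-math.sin(theta1), math.cos(theta1))
    n2 = (-math.sin(theta2), math.cos(theta2))
    A = np.array([n1, n2], dtype=float)
    det = np.linalg.det(A)
    if abs(det) < 1e-12:
        return None
    sol = np.linalg.solve(A, np.array([d1, d2], dtype=float))
    return float(sol[0]), float(sol[1])


def analyze_star_shot(
    image: PlanarImage,
    r_min_frac: float = 0.15,
    r_max_frac: float = 0.85,
    n_radii: int = 24,
    angle_step_deg: float = 0.25,
) -> StarShotResult:
    """Analyze a star/spoke-shot exposure of dark slit lines.

    Circular intensity profiles are sampled at a ladder of radii about the
    image center; intensity dips on each circle give (radius, angle) ridge
    points that are grouped per spoke (mod 180 deg) and fitted with total
    least squares. All pairwise intersections of the fitted lines are then
    bounded by their exact minimum enclosing circle.
    """
    from scipy.ndimage import map_coordinates

    pixels = image.pixels
    nrow, ncol = pixels.shape
    c0, r0 = image.center_px()
    pitch = image.pitch_iso_mm
    rmax_px = min(c0, r0, ncol - 1 - c0, nrow - 1 - r0)
    radii_px = np.linspace(r_min_frac * rmax_px, r_max_frac * rmax_px, n_radii)
    thetas = np.deg2rad(np.arange(0.0, 360.0, angle_step_deg))

    # mean circular profile to seed per-spoke angle windows
    vmax, vmin = float(pixels.max()), float(pixels.min())
    if vmax - vmin <= 0:
        raise DetectionError("image has no contrast")

    dip_points: list[tuple[float, float]] = []  # (x_mm, y_mm)
    outer_rays: list[tuple[float, float, float]] = []  # (theta_deg, x, y) at r_max
    for r_px in radii_px:
        cols = c0 + r_px * np.cos(thetas)
        rows = r0 + r_px * np.sin(thetas)
        prof = map_coordinates(pixels, [rows, cols], order=1, mode="nearest")
        base = float(np.median(prof))
        depth = base - prof
        min_depth = 0.3 * (vmax - vmin)
        inv = np.clip(depth, 0.0, None)
        # local minima of the circular profile (wrap-aware)
        pad = int(3.0 / angle_step_deg) + 1
        ext = np.concatenate([inv[-pad:], inv, inv[:pad]])
        raw_peaks, _ = signal.find_peaks(
            ext, height=min_depth, distance=int(3.0 / angle_step_deg)
        )
        # map back to the circle and deduplicate wrap copies of the same dip
        peaks = sorted({int((pk - pad) % inv.size) for pk in raw_peaks})
        dedup: list[int] = []
        for pk in peaks:
            if dedup and min(pk - dedup[-1], inv.size - pk + dedup[0]) < pad:
                continue
            dedup.append(pk)
        peaks = np.array(dedup, dtype=int)
        for pk in peaks:
            # parabolic sub-sample refinement of the dip angle
            i0, i1, i2 = (pk - 1) % inv.size, pk, (pk + 1) % inv.size
            y0, y1, y2 = inv[i0], inv[i1], inv[i2]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
            theta = thetas[pk] + np.deg2rad(angle_step_deg) * delta
            x_mm = (r_px * math.cos(theta)) * pitch
            y_mm = (r_px * math.sin(theta)) * pitch
            dip_points.append((x_mm, y_mm))
            if r_px == radii_px[-1]:
                outer_rays.append((math.degrees(theta) % 360.0, x_mm, y_mm))
    if len(dip_points) < 4 or len(outer_rays) < 2:
        raise DetectionError("too few ridge points for line fitting")
    pts = np.array(dip_points)

    # seed one line per spoke by pairing outermost-radius rays ~180 deg apart;
    # angle-based grouping breaks when the common point is off-center, because
    # a ray's polar angle drifts with radius
    rays = sorted(outer_rays)
    paired = [False] * len(rays)
    seed_lines: list[tuple[np.ndarray, np.ndarray]] = []  # (point, point)
    for i in range(len(rays)):
        if paired[i]:
            continue
        best_j, best_err = None, 25.0  # partner must lie within 25 deg of opposite
        for j in range(i + 1, len(rays)):
            if paired[j]:
                continue
            err = abs(((rays[j][0] - rays[i][0]) % 360.0) - 180.0)
            if err < best_err:
                best_j, best_err = j, err
        pi = np.array(rays[i][1:])
        if best_j is None:
            seed_lines.append((pi, np.zeros(2)))  # lone ray: aim at the center
        else:
            paired[best_j] = True
            seed_lines.append((pi, np.array(rays[best_j][1:])))
        paired[i] = True

    def _fit_tls(P: np.ndarray) -> tuple[float, float]:
        mean = P.mean(axis=0)
        _, _, vt = np.linalg.svd(P - mean)
        u = vt[0]
        theta = math.atan2(u[1], u[0]) % math.pi
        n = np.array([-math.sin(theta), math.cos(theta)])
        return theta, float(n @ mean)

    # assign every ridge point to its nearest seed line, then TLS refit twice
    lines = []
    for a, b in seed_lines:
        u = b - a
        if np.linalg.norm(u) < 1e-9:
            continue
        theta = math.atan2(u[1], u[0]) % math.pi
        n = np.array([-math.sin(theta), math.cos(theta)])
        lines.append((theta, float(n @ a)))
    if len(lines) < 2:
        raise GeometryError("fewer than two spokes detected")
    for _ in range(2):
        dists = np.stack(
            [
                np.abs(
                    pts @ np.array([-math.sin(t), math.cos(t)]) - d
                )
                for t, d in lines
            ]
        )
        owner = np.argmin(dists, axis=0)
        close = dists[owner, np.arange(pts.shape[0])] < 2.0
        new_lines = []
        for li in range(len(lines)):
            P = pts[(owner == li) & close]
            if P.shape[0] >= 4:
                new_lines.append(_fit_tls(P))
            else:
                new_lines.append(lines[li])
        lines = new_lines

    # consistency check: nearly all ridge points must lie on a fitted line;
    # parallel slits defeat the opposite-ray pairing and fail this check
    final_d = np.stack(
        [np.abs(pts @ np.array([-math.sin(t), math.cos(t)]) - d) for t, d in lines]
    ).min(axis=0)
    if float(np.mean(final_d < 2.0)) < 0.8:
        raise GeometryError(
            "spoke structure inconsistent with concurrent lines "
            "(slits may be parallel)"
        )

    intersections = []
    for a in range(len(lines)):
        for b in range(a + 1, len(lines)):
            p = _line_intersection(lines[a][0], lines[a][1], lines[b][0], lines[b][1])
            if p is not None:
                intersections.append(p)
    if not intersections:
        raise GeometryError("all fitted lines are parallel")
    (cx, cy), radius = min_enclosing_circle(np.array(intersections))
    return StarShotResult(
        lines=tuple((math.degrees(t), d) for t, d in lines),
        intersections=tuple(intersections),
        circle_center=Point2D(cx, cy),
        circle_radius_mm=float(radius),
    )


# ----------------------------------------------------------------------------
# transmission


def mlc_transmission(
    dose_closed: float, dose_open: float, tolerance_pct: float = 2.0
) -> dict:
    """Leaf transmission as percent of the open-field dose, flagged vs tolerance."""
    if dose_open <= 0:
        raise ValidationError("open-field dose must be > 0")
    if dose_closed < 0:
        raise ValidationError("closed-field dose must be >= 0")
    pct = 100.0 * dose_closed / dose_open
    return {"transmission_pct": pct, "tolerance_pct": tolerance_pct, "pass": pct < tolerance_pct}


# ----------------------------------------------------------------------------
# dynamic leaf gap


@dataclass
class SweepingGapSeries:
    """Doses measured for a set of nominal sweeping-gap widths.

    ``dleak_gy`` is the separately measured leakage dose (leaves closed,
    offset from the measurement line); it is an input, not re-derived.
    """

    gaps_mm: np.ndarray
    doses_gy: np.ndarray
    dleak_gy: float

    def __post_init__(self) -> None:
        self.gaps_mm = np.asarray(self.gaps_mm, dtype=float)
        self.doses_gy = np.asarray(self.doses_gy, dtype=float)
        if self.gaps_mm.size != self.doses_gy.size:
            raise ValidationError("gaps and doses must have equal length")
        if self.gaps_mm.size < 2:
            raise ValidationError("need at least 2 gap settings")
        if np.any(self.gaps_mm <= 0):
            raise ValidationError("gaps must be positive")
        if np.any(np.diff(self.gaps_mm) <= 0):
            raise ValidationError("gaps must be strictly increasing")
        if np.any(self.doses_gy <= self.dleak_gy):
            raise ValidationError("all doses must exceed the leakage dose")


@dataclass(frozen=True)
class DLGFit:
    """Linear fit of leakage-subtracted dose vs nominal gap.

    ``delta_mm`` (the dynamic leaf shift) is the negative half of the fitted
    line's x-axis intercept.
    """

    slope_gy_per_mm: float
    x_intercept_mm: float
    delta_mm: float
    residual_rms_gy: float

    def __post_init__(self) -> None:
        if self.slope_gy_per_mm <= 0:
            raise FitError("slope must be positive")
        if not math.isclose(self.delta_mm, -self.x_intercept_mm / 2.0, rel_tol=0, abs_tol=1e-12):
            raise ValidationError("delta must equal -x_intercept/2")


def fit_dynamic_leaf_gap(series: SweepingGapSeries) -> DLGFit:
    """Fit ``D - Dleak = b * (gap + 2 * delta)`` by ordinary least squares.

    The leakage-subtracted doses are regressed on the nominal gap; the root
    of the fitted line on the gap axis gives the x-intercept and the leaf
    shift is its negative half.
    """
    gaps = series.gaps_mm
    y = series.doses_gy - series.dleak_gy
    if np.ptp(gaps) == 0:
        raise FitError("all gaps identical: singular fit")
    slope, intercept = np.polyfit(gaps, y, 1)
    if slope <= 0:
        raise FitError(f"non-positive fitted slope {slope}")
    x_int = -intercept / slope
    resid = y - (slope * gaps + intercept)
    return DLGFit(
        slope_gy_per_mm=float(slope),
        x_intercept_mm=float(x_int),
        delta_mm=float(-x_int / 2.0),
        residual_rms_gy=float(np.sqrt(np.mean(resid**2))),
    )
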