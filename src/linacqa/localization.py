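"""Image-guidance localization statistics: hidden-target residual errors,
cross-system comparisons, rotation-exceedance analysis, and rigid-fit
couch-rotation verification from embedded BBs.

Standard deviations use the n-1 denominator throughout. The rigid-fit Euler
decomposition applies rotations about the L/R axis first, then P/A, then
S/I (extrinsic x-y-z); below ~3 degrees the ordering is irrelevant to well
under 0.01 degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from linacqa.core_io import SixDofShift, ValidationError

__all__ = [
    "GeometryError",
    "ResidualStats",
    "residual_error_stats",
    "compare_systems",
    "rotation_exceedance",
    "rigid_from_bbs",
    "apply_shift",
]


class GeometryError(RuntimeError):
    pass


@dataclass(frozen=True)
class ResidualStats:
    """Per-axis and vector-length mean +/- sample standard deviation (mm)."""

    mean: tuple[float, float, float]
    std: tuple[float, float, float]
    vector_mean: float
    vector_std: float
    n: int

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.std) or self.vector_std < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.vector_mean < 0:
            raise ValidationError("vector-length mean must be >= 0")


def _as_samples(samples) -> np.ndarray:
    arr = np.asarray(
        [
            (s.dx, s.dy, s.dz) if isinstance(s, SixDofShift) else tuple(s)
            for s in samples
        ],
        dtype=float,
    )
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValidationError("samples must be (dx, dy, dz) triples")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite residual sample")
    return arr


def residual_error_stats(samples, ddof: int = 1) -> ResidualStats:
    """Mean and sample standard deviation per axis and of per-trial norms.

    The vector-length statistics are the mean/std of the per-trial Euclidean
    norms (not the norm of the per-axis means).
    """
    arr = _as_samples(samples)
    n = arr.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 samples")
    norms = np.linalg.norm(arr, axis=1)
    return ResidualStats(
        mean=tuple(float(v) for v in arr.mean(axis=0)),
        std=tuple(float(v) for v in arr.std(axis=0, ddof=ddof)),
        vector_mean=float(norms.mean()),
        vector_std=float(norms.std(ddof=ddof)),
        n=n,
    )


def compare_systems(pairs) -> ResidualStats:
    """Residual statistics of componentwise A-B differences over paired trials."""
    a_list, b_list = [], []
    for pair in pairs:
        if len(pair) != 2:
            raise ValidationError("each entry must be an (A, B) pair")
        a_list.append(pair[0])
        b_list.append(pair[1])
    a, b = _as_samples(a_list), _as_samples(b_list)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal lengths")
    return residual_error_stats(a - b)


def rotation_exceedance(angles_deg, thresholds_deg) -> dict[float, dict]:
    """Fraction of |angle| exceeding each threshold, with binomial standard error."""
    angles = np.abs(np.asarray(list(angles_deg), dtype=float))
    if angles.size == 0:
        raise ValidationError("empty angle list")
    out: dict[float, dict] = {}
    n = angles.size
    for t in thresholds_deg:
        k = int(np.sum(angles > t))
        p = k / n
        out[float(t)] = {
            "fraction": p,
            "count": k,
            "n": n,
            "se": math.sqrt(p * (1 - p) / n),
        }
    return out


def _euler_xyz_from_matrix(R: np.ndarray) -> tuple[float, float, float]:
    rot = Rotation.from_matrix(R)
    # extrinsic x-y-z: R = Rz @ Ry @ Rx, matching the documented L/R-first order
    return tuple(float(a) for a in rot.as_euler("xyz", degrees=True))


def rigid_from_bbs(points_pre: np.ndarray, points_post: np.ndarray) -> SixDofShift:
    """Least-squares rigid transform mapping ``points_pre`` onto ``points_post``.

    Kabsch/SVD solution with no scaling; the rotation is decomposed into
    degrees about the L/R, P/A and S/I axes and the translation is the
    displacement of the centroid after rotation.
    """
    pre = np.asarray(points_pre, dtype=float)
    post = np.asarray(points_post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 2 or pre.shape[1] != 3:
        raise ValidationError("point sets must be matching (n, 3) arrays")
    n = pre.shape[0]
    if n < 3:
        raise GeometryError("need at least 3 corresponding points")
    pre_c = pre - pre.mean(axis=0)
    post_c = post - post.mean(axis=0)
    # collinearity check: second singular value of the centered cloud
    s = np.linalg.svd(pre_c, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise GeometryError("points are collinear or coincident")
    H = pre_c.T @ post_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = post.mean(axis=0) - R @ pre.mean(axis=0)
    r_lr, r_pa, r_si = _euler_xyz_from_matrix(R)
    return SixDofShift(
        dx=float(t[0]), dy=float(t[1]), dz=float(t[2]),
        r_lr=r_lr, r_pa=r_pa, r_si=r_si,
    )


def apply_shift(shift: SixDofShift, points: np.ndarray) -> np.ndarray:
    """Forward transform: rotate (extrinsic x-y-z) then translate the points."""
    pts = np.asarray(points, dtype=float)
    R = Rotation.from_euler(
        "xyz", [shift.r_lr, shift.r_pa, shift.r_si], degrees=True
    ).as_matrix()
    return pts @ R.T + shift.translation
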