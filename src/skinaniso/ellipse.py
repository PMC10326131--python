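"""Direct least-squares ellipse fitting and anisotropy metrics.

Angular arrival-time profiles are plotted in Cartesian coordinates with the
arrival time as the distance from the origin, and an ellipse is fitted to
the point cloud by minimising algebraic distance under the ellipse
constraint ``4AC - B^2 = 1``.  The solver is the numerically stable block
decomposition of the constrained eigenproblem (Halir & Flusser), applied
after centering and rescaling the data; this avoids the singular-matrix
failure of the original single-eigenproblem formulation on near-circular or
noise-free data.

From the fitted ellipse the package derives the anisotropy measures:

* eccentricity ``e = sqrt(1 - b^2/a^2)`` — 0 for an isotropic (circular)
  profile, approaching 1 as the material becomes transversely isotropic;
* area ``A = pi*a*b`` — an omnidirectional average of arrival time, hence
  an inverse proxy for average stiffness;
* the classic anisotropic ratio ``AR = RRT_max / RRT_min`` computed on the
  raw readings;
* the Langer-line direction, perpendicular to the fitted semi-major axis
  (the semi-major axis is the slowest wave direction; the fastest is 90°
  from it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angular_io import AngularProfile


class InsufficientDataError(ValueError):
    """Fewer points than the conic fit requires."""


class DegenerateFitError(ValueError):
    """The best-fit conic is not a real ellipse (e.g. collinear data)."""


@dataclass(frozen=True)
class EllipseFit:
    """Geometric and algebraic description of a fitted ellipse.

    ``conic`` holds (A, B, C, D, E, F) of
    ``A x^2 + B xy + C y^2 + D x + E y + F = 0`` normalised to unit norm.
    ``tilt_deg`` is the counter-clockwise angle from the positive x-axis to
    the semi-major axis, reduced to [0, 180) since an ellipse axis is axial.
    """

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    tilt_deg: float
    conic: np.ndarray
    rms_residual: float

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("requires semi_major >= semi_minor > 0")
        if not (0.0 <= self.tilt_deg < 180.0):
            raise ValueError("tilt must lie in [0, 180)")
        a, b, c = self.conic[0], self.conic[1], self.conic[2]
        if not b * b - 4 * a * c < 0:
            raise ValueError("conic coefficients do not describe an ellipse")


@dataclass(frozen=True)
class AnisotropyMetrics:
    """Per-profile anisotropy summary derived from an ellipse fit."""

    eccentricity: float
    area: float
    anisotropic_ratio: float
    langer_angle_deg: float


def polar_to_cartesian(profile: AngularProfile) -> np.ndarray:
    """Map readings to points: x = r cos(angle), y = r sin(angle).

    Angles are counter-clockwise from the positive x-axis; the Euclidean
    distance from the origin is the arrival time in RRT units.  Returns an
    (n, 2) array.
    """
    theta = np.deg2rad(profile.angles_deg)
    return np.column_stack(
        (profile.rrt * np.cos(theta), profile.rrt * np.sin(theta))
    )


def _solve_conic_batch(points: np.ndarray) -> np.ndarray:
    """Constrained least-squares conic for each point cloud in a batch.

    points : (..., n, 2).  Returns conic coefficients (..., 6) in the
    *original* (uncentered) frame, unit-normalised.  Entries are NaN where
    the fit is degenerate (no admissible ellipse eigenvector).
    """
    pts = np.asarray(points, dtype=float)
    x = pts[..., 0]
    y = pts[..., 1]
    # precondition: center and isotropically rescale each cloud
    mx = x.mean(axis=-1, keepdims=True)
    my = y.mean(axis=-1, keepdims=True)
    xc = x - mx
    yc = y - my
    scale = np.sqrt((xc**2 + yc**2).mean(axis=-1, keepdims=True))
    scale = np.where(scale <= 0, 1.0, scale)
    xs = xc / scale
    ys = yc / scale

    d1 = np.stack((xs * xs, xs * ys, ys * ys), axis=-1)  # quadratic part
    d2 = np.stack((xs, ys, np.ones_like(xs)), axis=-1)  # linear part
    s1 = np.einsum("...ni,...nj->...ij", d1, d1)
    s2 = np.einsum("...ni,...nj->...ij", d1, d2)
    s3 = np.einsum("...ni,...nj->...ij", d2, d2)
    # T expresses the linear coefficients in terms of the quadratic ones;
    # pinv tolerates the singular S3 of degenerate (e.g. collinear) clouds,
    # which then surface as inadmissible eigenvectors below
    try:
        t = -np.linalg.solve(s3, np.swapaxes(s2, -1, -2))
    except np.linalg.LinAlgError:
        t = -np.linalg.pinv(s3) @ np.swapaxes(s2, -1, -2)
    m = s1 + s2 @ t
    # premultiply by C1^{-1} for the constraint 4AC - B^2 = 1
    m_red = np.empty_like(m)
    m_red[..., 0, :] = m[..., 2, :] / 2.0
    m_red[..., 1, :] = -m[..., 1, :]
    m_red[..., 2, :] = m[..., 0, :] / 2.0
    eigval, eigvec = np.linalg.eig(m_red)
    eigval = np.real(eigval)
    eigvec = np.real(eigvec)
    # admissible eigenvector: 4ac - b^2 > 0 (exactly one for ellipse data)
    cond = (
        4.0 * eigvec[..., 0, :] * eigvec[..., 2, :] - eigvec[..., 1, :] ** 2
    )
    admissible = cond > 0
    # among admissible columns pick the one with the largest constraint
    # value (scale-invariant choice; there is one up to numerical noise)
    score = np.where(admissible, cond, -np.inf)
    pick = np.argmax(score, axis=-1)
    a1 = np.take_along_axis(eigvec, pick[..., None, None], axis=-1)[..., 0]
    ok = np.take_along_axis(admissible, pick[..., None], axis=-1)[..., 0]
    a2 = np.einsum("...ij,...j->...i", t, a1)
    conic_s = np.concatenate((a1, a2), axis=-1)  # scaled, centered frame

    # undo the normalisation: substitute xs=(x-mx)/s, ys=(y-my)/s
    A, B, C, D, E, F = (conic_s[..., i] for i in range(6))
    s = scale[..., 0]
    mx0 = mx[..., 0]
    my0 = my[..., 0]
    Ao = A / s**2
    Bo = B / s**2
    Co = C / s**2
    Do = -2 * A * mx0 / s**2 - B * my0 / s**2 + D / s
    Eo = -2 * C * my0 / s**2 - B * mx0 / s**2 + E / s
    Fo = (
        A * mx0**2 / s**2
        + B * mx0 * my0 / s**2
        + C * my0**2 / s**2
        - D * mx0 / s
        - E * my0 / s
        + F
    )
    conic = np.stack((Ao, Bo, Co, Do, Eo, Fo), axis=-1)
    conic = conic / np.linalg.norm(conic, axis=-1, keepdims=True)
    conic = np.where(ok[..., None], conic, np.nan)
    return conic


def _conic_to_geometry(conic: np.ndarray):
    """Geometric parameters from conic coefficients, batched.

    Returns (cx, cy, semi_major, semi_minor, tilt_deg) arrays; NaN where the
    conic is not a real ellipse.
    """
    A, B, C, D, E, F = (conic[..., i] for i in range(6))
    disc = B * B - 4 * A * C
    with np.errstate(invalid="ignore", divide="ignore"):
        cx = (2 * C * D - B * E) / disc
        cy = (2 * A * E - B * D) / disc
        # constant term after translating to the center
        fc = A * cx**2 + B * cx * cy + C * cy**2 + D * cx + E * cy + F
        # eigenvalues of [[A, B/2], [B/2, C]]
        tr = A + C
        det = A * C - B * B / 4.0
        root = np.sqrt(np.maximum((tr / 2.0) ** 2 - det, 0.0))
        lam1 = tr / 2.0 - root  # smaller |...| -> longer axis
        lam2 = tr / 2.0 + root
        # axis^2 = -fc / lambda; require both positive for a real ellipse
        ax1_sq = -fc / lam1
        ax2_sq = -fc / lam2
        valid = (disc < 0) & (ax1_sq > 0) & (ax2_sq > 0)
        # a collinear cloud fitted through pinv degenerates to a sliver of
        # essentially zero width; treat such conics as non-ellipses
        valid &= np.minimum(ax1_sq, ax2_sq) > np.maximum(ax1_sq, ax2_sq) * 1e-14
        semi_major = np.sqrt(np.where(valid, np.maximum(ax1_sq, ax2_sq), np.nan))
        semi_minor = np.sqrt(np.where(valid, np.minimum(ax1_sq, ax2_sq), np.nan))
        # major-axis direction: eigenvector for the major axis' eigenvalue.
        # Two algebraic forms of the eigenvector; use whichever is better
        # conditioned (the other degenerates when the axis is coordinate-
        # aligned).
        lam_major = np.where(ax1_sq >= ax2_sq, lam1, lam2)
        v1x, v1y = B / 2.0, lam_major - A
        v2x, v2y = lam_major - C, B / 2.0
        use1 = v1x**2 + v1y**2 >= v2x**2 + v2y**2
        vx = np.where(use1, v1x, v2x)
        vy = np.where(use1, v1y, v2y)
        both_zero = (vx == 0) & (vy == 0)
        tilt = np.degrees(np.arctan2(vy, np.where(both_zero, 1.0, vx))) % 180.0
        # a circle has no defined tilt; report 0 for determinism
        tilt = np.where(np.isclose(semi_major, semi_minor, rtol=1e-12), 0.0, tilt)
    return cx, cy, semi_major, semi_minor, tilt


def fit_ellipse_batch(points: np.ndarray):
    """Fit every point cloud in a (..., n, 2) batch.

    Returns a dict of arrays (cx, cy, a, b, tilt_deg, conic, rms) with NaN
    marking degenerate fits.  This is the vectorised engine behind
    :func:`fit_ellipse_direct` and the Monte-Carlo study.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[-2] < 6:
        raise InsufficientDataError(
            f"need at least 6 points for a conic fit, got {pts.shape[-2]}"
        )
    conic = _solve_conic_batch(pts)
    cx, cy, a, b, tilt = _conic_to_geometry(conic)
    # rms of algebraic distances under the unit-norm conic
    x, y = pts[..., 0], pts[..., 1]
    vals = (
        conic[..., 0, None] * x * x
        + conic[..., 1, None] * x * y
        + conic[..., 2, None] * y * y
        + conic[..., 3, None] * x
        + conic[..., 4, None] * y
        + conic[..., 5, None]
    )
    rms = np.sqrt((vals**2).mean(axis=-1))
    return {"cx": cx, "cy": cy, "a": a, "b": b, "tilt_deg": tilt,
            "conic": conic, "rms": rms}


def fit_ellipse_direct(points: np.ndarray) -> EllipseFit:
    """Direct least-squares ellipse fit of a single (n, 2) point cloud.

    Deterministic for fixed input.  Raises :class:`DegenerateFitError` when
    the data admit no real ellipse (e.g. collinear points) and
    :class:`InsufficientDataError` below 6 points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    res = fit_ellipse_batch(pts[None, ...])
    a = float(res["a"][0])
    if not np.isfinite(a):
        raise DegenerateFitError("best-fit conic is not a real ellipse")
    return EllipseFit(
        center=(float(res["cx"][0]), float(res["cy"][0])),
        semi_major=a,
        semi_minor=float(res["b"][0]),
        tilt_deg=float(res["tilt_deg"][0]),
        conic=res["conic"][0],
        rms_residual=float(res["rms"][0]),
    )


def eccentricity_from_axes(a, b):
    """e = sqrt(1 - b^2/a^2) with a the semi-major axis (vectorised)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.sqrt(1.0 - (b / a) ** 2)


def metrics_from_fit(fit: EllipseFit, profile: AngularProfile | None = None) -> AnisotropyMetrics:
    """Anisotropy metrics from a fitted ellipse.

    area = pi*a*b; eccentricity as above; Langer direction is the tilt plus
    90° (mod 180): the semi-major axis marks the slowest wave, the Langer
    line the fastest.  The anisotropic ratio needs the raw readings, so it
    is NaN unless ``profile`` is supplied.
    """
    e = float(eccentricity_from_axes(fit.semi_major, fit.semi_minor))
    area = float(np.pi * fit.semi_major * fit.semi_minor)
    langer = (fit.tilt_deg + 90.0) % 180.0
    ar = anisotropic_ratio(profile) if profile is not None else float("nan")
    return AnisotropyMetrics(
        eccentricity=e, area=area, anisotropic_ratio=ar, langer_angle_deg=langer
    )


def anisotropic_ratio(profile: AngularProfile) -> float:
    """Classic anisotropic ratio: max arrival time over min arrival time."""
    rrt = profile.rrt
    if np.any(rrt <= 0):
        raise ValueError("anisotropic ratio requires positive readings")
    return float(rrt.max() / rrt.min())


def analyze_profile(profile: AngularProfile) -> tuple[EllipseFit, AnisotropyMetrics]:
    """Fit the profile's ellipse and compute all anisotropy metrics."""
    fit = fit_ellipse_direct(polar_to_cartesian(profile))
    return fit, metrics_from_fit(fit, profile)
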