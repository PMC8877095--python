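"""Bowl pose from the rim ellipse, projected volume levels, and volume
estimation (flat-surface level matching and the area-ratio regression).

All 2-D coordinates in this module are metric image-plane coordinates (mm);
pixel conversion happens at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely

from .camera import CameraIntrinsics, project
from .model import BowlModel

__all__ = [
    "EllipseParams",
    "BowlPose",
    "FARRegression",
    "fit_ellipse",
    "estimate_pose",
    "project_circle",
    "project_levels",
    "match_surface",
    "fullness",
    "compute_far",
    "build_far_regression",
    "volume_from_far",
    "density_ground_truth",
]


class PoseError(RuntimeError):
    pass


@dataclass
class EllipseParams:
    """Ellipse in image-plane mm: center, semi-axes a >= b, rotation."""

    center: np.ndarray
    a: float
    b: float
    angle: float
    rms: float | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not (self.a >= self.b > 0):
            raise ValueError(f"need a >= b > 0, got a={self.a}, b={self.b}")

    @property
    def area(self) -> float:
        return float(np.pi * self.a * self.b)

    def sample(self, n: int = 360) -> np.ndarray:
        """n points along the ellipse boundary."""
        t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        c, s = np.cos(self.angle), np.sin(self.angle)
        x = self.a * np.cos(t)
        y = self.b * np.sin(t)
        return np.column_stack([c * x - s * y, s * x + c * y]) + self.center


@dataclass
class BowlPose:
    """Rim-circle pose in the camera frame.

    ``normal`` is the unit normal of the rim plane pointing toward the
    camera (the interior is visible); ``center`` is the rim-circle center.
    ``alternate`` carries the second solution of the standard two-fold
    circle-pose ambiguity for diagnostics.
    """

    center: np.ndarray
    normal: np.ndarray
    alternate: "BowlPose | None" = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(self.normal)
        if abs(norm - 1.0) > 1e-9:
            self.normal = self.normal / norm
        if self.center[2] <= 0:
            raise ValueError("rim center must be in front of the camera")

    @property
    def tilt_deg(self) -> float:
        """Angle between the rim plane normal and the optical axis."""
        return float(np.degrees(np.arccos(np.clip(abs(self.normal[2]), -1, 1))))


@dataclass
class FARRegression:
    """Linear map from food-area ratio to volume, fitted on simulated fills."""

    slope: float
    intercept: float
    r_squared: float
    far_values: np.ndarray
    volumes_ml: np.ndarray
    capacity_ml: float

    def __post_init__(self) -> None:
        if len(self.far_values) < 3:
            raise ValueError("need at least 3 support points")
        if np.any(np.diff(self.volumes_ml) <= 0):
            raise ValueError("support volumes must be strictly increasing")


# ---------------------------------------------------------------------------
# ellipse fitting (direct least squares, Halir & Flusser formulation)
# ---------------------------------------------------------------------------


def _conic_from_points(points: np.ndarray) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise PoseError("degenerate point configuration for ellipse fit") from exc
    M = S1 + S2 @ T
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    eigval, eigvec = np.linalg.eig(M)
    cond = 4 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    ok = np.isreal(eigval) & (cond > 0)
    if not np.any(ok):
        raise PoseError("points do not determine an ellipse (collinear or hyperbolic)")
    a1 = np.real(eigvec[:, ok][:, 0])
    a2 = T @ a1
    return np.concatenate([a1, a2])  # A, B, C, D, E, F


def _conic_to_params(coef: np.ndarray) -> EllipseParams:
    A, B, C, D, E, F = coef
    den = B * B - 4 * A * C
    if den >= 0:
        raise PoseError("conic is not an ellipse")
    cx = (2 * C * D - B * E) / den
    cy = (2 * A * E - B * D) / den
    # evaluate at center to get the constant of the centered conic
    Fc = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    if Fc > 0:  # normalize sign so the quadratic form is positive definite
        A, B, C, Fc = -A, -B, -C, -Fc
    lam, vec = np.linalg.eigh(np.array([[A, B / 2], [B / 2, C]]))
    if lam[0] * Fc >= 0 or lam[1] * Fc >= 0:
        raise PoseError("conic is not a real ellipse")
    a = float(np.sqrt(-Fc / lam[0]))  # smaller quadratic-form eigenvalue
    b = float(np.sqrt(-Fc / lam[1]))
    if (a - b) / a < 1e-12:
        angle = 0.0  # circle: rotation indeterminate
    else:
        angle = float(np.arctan2(vec[1, 0], vec[0, 0]))  # major-axis direction
        angle = (angle + np.pi / 2) % np.pi - np.pi / 2
    return EllipseParams(center=np.array([cx, cy]), a=a, b=b, angle=angle)


def fit_ellipse(points: np.ndarray) -> EllipseParams:
    """Direct least-squares conic fit constrained to an ellipse.

    Requires >= 5 non-collinear points; the RMS orthogonal distance of the
    inputs to the fitted ellipse is stored on the result.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("need at least 5 (x, y) points")
    centroid = pts.mean(axis=0)
    scale = float(np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean()))
    if scale <= 0:
        raise PoseError("all points coincide")
    norm = (pts - centroid) / scale
    coef = _conic_from_points(norm)
    e = _conic_to_params(coef)
    e = EllipseParams(
        center=e.center * scale + centroid,
        a=e.a * scale,
        b=e.b * scale,
        angle=e.angle,
    )
    e.rms = float(np.sqrt(np.mean(point_ellipse_distance(pts, e) ** 2)))
    return e


def point_ellipse_distance(
    points: np.ndarray, e: EllipseParams, n_samples: int = 720
) -> np.ndarray:
    """Distance from each point to the ellipse boundary (dense polyline with
    exact point-to-segment distances)."""
    ring = shapely.linearrings(e.sample(n_samples))
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return shapely.distance(shapely.points(pts), ring)


# ---------------------------------------------------------------------------
# circle pose from its elliptical projection
# ---------------------------------------------------------------------------


def _ellipse_conic_matrix(e: EllipseParams) -> np.ndarray:
    """Symmetric 3x3 conic of the ellipse in homogeneous (x', y', 1)."""
    c, s = np.cos(e.angle), np.sin(e.angle)
    R = np.array([[c, -s], [s, c]])
    Dm = np.diag([1.0 / e.a**2, 1.0 / e.b**2])
    Q2 = R @ Dm @ R.T
    t = e.center
    M = np.zeros((3, 3))
    M[:2, :2] = Q2
    M[:2, 2] = -Q2 @ t
    M[2, :2] = -Q2 @ t
    M[2, 2] = t @ Q2 @ t - 1.0
    return M


def project_circle(
    center: np.ndarray,
    normal: np.ndarray,
    radius: float,
    k: CameraIntrinsics,
    n: int = 180,
) -> EllipseParams:
    """Pinhole projection of a 3-D circle, returned as fitted ellipse params."""
    center = np.asarray(center, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    # orthonormal basis of the circle plane
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts3 = center + radius * (np.outer(np.cos(t), e1) + np.outer(np.sin(t), e2))
    return fit_ellipse(project(pts3, k))


def estimate_pose(
    e: EllipseParams, diameter: float, k: CameraIntrinsics
) -> BowlPose:
    """Recover the pose of a circle of known diameter whose pinhole image is
    the given ellipse.

    The cone of rays through the ellipse is diagonalized; the two admissible
    circle poses are reconstructed and the one whose normal makes the
    smaller angle with the viewing ray (interior visible from above) is
    returned, with the other attached as ``alternate``.  Both candidates are
    validated by re-projection.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    R = diameter / 2.0
    A = _ellipse_conic_matrix(e)
    H = np.diag([k.f, k.f, 1.0])
    Q = H @ A @ H  # ray direction d satisfies d^T Q d = 0
    lam, vec = np.linalg.eigh(Q)
    if np.sum(lam > 0) == 1:
        lam, vec = -lam, vec
    pos = np.where(lam > 0)[0]
    neg = np.where(lam < 0)[0]
    if len(pos) != 2 or len(neg) != 1:
        raise PoseError("ellipse does not bound a valid viewing cone")
    i1, i2 = pos[np.argsort(-lam[pos])]  # lam1 >= lam2 > 0
    i3 = neg[0]
    l1, l2, l3 = lam[i1], lam[i2], lam[i3]
    e1, e2v, e3 = vec[:, i1], vec[:, i2], vec[:, i3]

    g = np.sqrt((l1 - l2) / (l1 - l3))
    h = np.sqrt((l2 - l3) / (l1 - l3))
    z0 = l2 * R / np.sqrt(-l1 * l3)

    candidates = []
    for s1 in (+1, -1):
        for s2 in (+1, -1):
            n_vec = s1 * g * e1 + s2 * h * e3
            c_vec = z0 * (-s1 * (l3 / l2) * g * e1 - s2 * (l1 / l2) * h * e3)
            for flip in (+1, -1):
                c = flip * c_vec
                if c[2] <= 0:
                    continue
                nrm = n_vec if n_vec @ c < 0 else -n_vec  # toward the camera
                try:
                    reproj = project_circle(c, nrm, R, k)
                except Exception:
                    continue
                err = _ellipse_param_distance(reproj, e)
                candidates.append((err, c, nrm))
    if not candidates:
        raise PoseError("no circle pose at positive depth projects to this ellipse")
    candidates.sort(key=lambda t: t[0])
    tol = max(1e-6 * e.a, 10 * candidates[0][0])
    good = [c for c in candidates if c[0] <= tol]
    best_err = candidates[0][0]
    if best_err > 1e-3 * e.a:
        raise PoseError(
            f"re-projection mismatch {best_err:.3g} mm: ellipse inconsistent "
            "with a circle of the given diameter"
        )
    # dedupe near-identical candidates, keep the two distinct poses
    poses: list[tuple[np.ndarray, np.ndarray]] = []
    for _, c, nrm in good:
        if all(np.linalg.norm(nrm - p[1]) > 1e-3 for p in poses):
            poses.append((c, nrm))
    # prefer the normal closest to the viewing direction (interior visible)
    poses.sort(key=lambda p: -(p[1] @ (-p[0] / np.linalg.norm(p[0]))))
    alt = None
    if len(poses) > 1:
        alt = BowlPose(center=poses[1][0], normal=poses[1][1])
    return BowlPose(center=poses[0][0], normal=poses[0][1], alternate=alt)


def _ellipse_param_distance(p: EllipseParams, q: EllipseParams) -> float:
    """Mean boundary distance between two ellipses (sampled)."""
    return float(np.mean(point_ellipse_distance(p.sample(90), q)))


# ---------------------------------------------------------------------------
# levels, surface matching, FAR
# ---------------------------------------------------------------------------


def _level_circle(
    m: BowlModel, pose: BowlPose, z: float
) -> tuple[np.ndarray, float]:
    """3-D center and radius of the horizontal fill circle at height z."""
    center = pose.center - (m.depth - z) * pose.normal
    return center, float(m.radius_at_height(z))


def project_levels(
    m: BowlModel,
    pose: BowlPose,
    k: CameraIntrinsics,
    increment_ml: float = 50.0,
    volumes_ml: np.ndarray | None = None,
) -> list[tuple[float, EllipseParams]]:
    """Project the fill circles of cumulative volumes increment, 2x, ...,
    capacity into the image as ellipses."""
    if volumes_ml is None:
        if increment_ml <= 0:
            raise ValueError("increment must be positive")
        volumes_ml = np.arange(increment_ml, m.capacity_ml, increment_ml)
        volumes_ml = np.append(volumes_ml, m.capacity_ml)
    out = []
    for v in np.asarray(volumes_ml, dtype=float):
        z = float(m.height_at_volume(v))
        center, radius = _level_circle(m, pose, z)
        if radius <= 0:
            continue
        out.append((float(v), project_circle(center, pose.normal, radius, k)))
    return out


def match_surface(
    surface_points: np.ndarray,
    levels: list[tuple[float, EllipseParams]],
    *,
    model: BowlModel | None = None,
    pose: BowlPose | None = None,
    k: CameraIntrinsics | None = None,
    refine_factor: int = 10,
) -> float:
    """Volume whose projected level best matches the observed flat liquid
    surface (minimum mean squared point-to-ellipse distance), refined once
    with ``refine_factor`` x finer increments when the model/pose is given."""
    pts = np.asarray(surface_points, dtype=float)
    if pts.shape[0] < 5:
        raise ValueError("need at least 5 surface points")
    if not levels:
        raise ValueError("no levels to match against")
    surf = fit_ellipse(pts)
    rim = levels[-1][1]
    if surf.a > rim.a * 1.05 and surf.b > rim.b * 1.05:
        raise PoseError("surface ellipse larger than the rim: liquid above rim?")

    def cost(ell: EllipseParams) -> float:
        return float(np.mean(point_ellipse_distance(pts, ell) ** 2))

    vols = np.array([v for v, _ in levels])
    costs = np.array([cost(ell) for _, ell in levels])
    v_best = float(vols[np.argmin(costs)])
    if model is None or pose is None or k is None or len(vols) < 2:
        return v_best

    # typical level spacing (the final level is the capacity remainder)
    coarse = float(np.median(np.diff(vols))) if len(vols) > 1 else v_best
    fine = coarse / refine_factor
    lo = max(fine, v_best - coarse)
    hi = min(model.capacity_ml, v_best + coarse)
    fine_vols = np.arange(lo, hi + fine / 2, fine)
    fine_levels = project_levels(model, pose, k, volumes_ml=fine_vols)
    f_costs = [cost(ell) for _, ell in fine_levels]
    return float(fine_levels[int(np.argmin(f_costs))][0])


def fullness(volume_ml: float, capacity_ml: float) -> float:
    """Percent fullness: 100 * volume / capacity."""
    if capacity_ml <= 0:
        raise ValueError("capacity must be positive")
    if volume_ml < 0:
        raise ValueError("volume must be non-negative")
    if volume_ml > capacity_ml:
        warnings.warn("volume exceeds capacity (food mounded above the rim?)",
                      stacklevel=2)
    return 100.0 * volume_ml / capacity_ml


def compute_far(liquid_px: int, rim_px: int) -> float:
    """Food-area ratio: visible-liquid pixels over within-rim pixels."""
    if rim_px <= 0:
        raise ValueError("rim pixel count must be positive")
    if not 0 <= liquid_px <= rim_px:
        raise ValueError("need 0 <= liquid_px <= rim_px")
    return liquid_px / rim_px


def build_far_regression(
    m: BowlModel,
    pose: BowlPose,
    k: CameraIntrinsics,
    volumes_ml: np.ndarray | None = None,
    n_points: int = 9,
) -> FARRegression:
    """Simulate fills at the given volumes, compute projected-area ratios
    (surface-ellipse area / rim-ellipse area), and fit volume = a*FAR + b."""
    if volumes_ml is None:
        volumes_ml = np.linspace(0.1, 0.95, n_points) * m.capacity_ml
    volumes_ml = np.sort(np.asarray(volumes_ml, dtype=float))
    if len(volumes_ml) < 3:
        raise ValueError("need at least 3 support volumes")
    if volumes_ml[0] <= 0 or volumes_ml[-1] > m.capacity_ml * (1 + 1e-9):
        raise ValueError("support volumes must lie in (0, capacity]")
    rim_center, rim_radius = _level_circle(m, pose, m.depth)
    rim = project_circle(rim_center, pose.normal, rim_radius, k)
    fars = []
    for v in volumes_ml:
        z = float(m.height_at_volume(v))
        center, radius = _level_circle(m, pose, z)
        if radius <= 0:
            fars.append(0.0)
            continue
        fars.append(project_circle(center, pose.normal, radius, k).area / rim.area)
    fars = np.asarray(fars)
    if np.ptp(fars) < 1e-2 * max(np.mean(fars), 1e-12):
        raise PoseError(
            "area ratio does not vary with volume (vertical-walled bowl): "
            "the area-ratio regression is degenerate"
        )
    slope, intercept = np.polyfit(fars, volumes_ml, 1)
    pred = slope * fars + intercept
    ss_res = float(np.sum((volumes_ml - pred) ** 2))
    ss_tot = float(np.sum((volumes_ml - volumes_ml.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return FARRegression(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        far_values=fars,
        volumes_ml=volumes_ml,
        capacity_ml=m.capacity_ml,
    )


def volume_from_far(far: float, reg: FARRegression) -> float:
    """Volume from the regression line, clamped to [0, capacity]."""
    if not 0 <= far <= 1 + 1e-9:
        raise ValueError("FAR must lie in [0, 1]")
    v = reg.slope * far + reg.intercept
    return float(np.clip(v, 0.0, reg.capacity_ml))


def density_ground_truth(wc_g: float, vc_ml: float, wf_g: float) -> float:
    """Ground-truth food volume from weights: density = wc/vc, vf = wf/density."""
    if wc_g <= 0 or vc_ml <= 0 or wf_g <= 0:
        raise ValueError("weights and cup volume must be positive")
    return wf_g * vc_ml / wc_g
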