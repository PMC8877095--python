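"""Single-image reconstruction of a bowl's interior cross-section.

Pipeline: fit smooth border curves to the paired ruler landmarks, measure
the observed ruler widths and midpoint offsets, recover per-landmark ray
lengths by constrained nonlinear least squares (law-of-cosines chord
residuals, flat-bottom equality constraints), convert rays to a planar
cross-section, symmetrize, and revolve into a :class:`~bowlrecon.model.BowlModel`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize

from .annotations import RulerAnnotation
from .camera import CameraIntrinsics, pixel_to_plane, ray_angle
from .model import BowlModel, HalfProfile, monotone_profile, revolve

__all__ = [
    "BorderFit",
    "RayFan",
    "CrossSection",
    "SolverDiagnostics",
    "fit_borders",
    "pair_and_measure",
    "initial_rays",
    "inter_ray_angles",
    "objective_J",
    "flat_bottom_residuals",
    "optimize_rays",
    "rays_to_cross_section",
    "symmetrize",
    "revolve",
    "reconstruct",
]

PROFILE_GRID_N = 501


class ReconstructionError(RuntimeError):
    pass


@dataclass
class BorderFit:
    """Polynomial border curves y' = p(x') in image-plane mm."""

    upper: Polynomial
    lower: Polynomial
    midline: Polynomial
    degree: int
    max_residual: float


@dataclass
class RayFan:
    """Per-landmark quantities the ray optimizer acts on.

    V : signed midpoint offsets on the image plane (mm), positive in the
        left half image plane, sorted descending (left -> right).
    W : observed ruler widths (mm).
    theta : I - 1 inter-ray angles (rad).
    r : I ray lengths (mm), filled by the optimizer.
    """

    V: np.ndarray
    W: np.ndarray
    flat_bottom: np.ndarray
    theta: np.ndarray | None = None
    r: np.ndarray | None = None
    #: True when the annotation ran right-to-left and was reversed to sort V
    reversed_annotation: bool = False

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if self.V.shape != self.W.shape or self.V.ndim != 1:
            raise ValueError("V and W must be 1-D arrays of equal length")
        if np.any(self.W <= 0):
            raise ValueError("all observed widths must be positive")
        if self.theta is not None and len(self.theta) != len(self.V) - 1:
            raise ValueError("theta must have I - 1 entries")


@dataclass
class SolverDiagnostics:
    iterations: int
    initial_J: float
    final_J: float
    max_constraint_violation: float
    message: str


@dataclass
class CrossSection:
    """Reconstructed ruler-plane points: u horizontal (mm, positive toward
    the left half image), w depth below the optical center (mm)."""

    u: np.ndarray
    w: np.ndarray
    flat_bottom: np.ndarray


# ---------------------------------------------------------------------------
# border fitting and measurement
# ---------------------------------------------------------------------------


def fit_borders(a: RulerAnnotation, k: CameraIntrinsics) -> BorderFit:
    """Least-squares polynomial fit (degree <= 5) of the two border point
    sets in image-plane coordinates, plus their midline."""
    up = pixel_to_plane(a.upper, k)
    lo = pixel_to_plane(a.lower, k)
    n = a.n_landmarks
    degree = min(5, n - 2)
    if degree < 5:
        warnings.warn(
            f"only {n} landmark pairs: border fit degree reduced to {degree}",
            stacklevel=2,
        )

    for name, pts in (("upper", up), ("lower", lo)):
        x = pts[:, 0]
        if len(np.unique(x)) != len(x):
            raise ReconstructionError(f"duplicate x-abscissae in {name} border")
        if np.ptp(x) < 2.0 * np.ptp(pts[:, 1]) and np.ptp(x) < 1e-9 + 0.05 * np.ptp(pts):
            raise ReconstructionError(
                "border points are nearly vertical; re-orient the camera so the "
                "ruler is parallel to the bottom edge of the image"
            )

    p_up = Polynomial.fit(up[:, 0], up[:, 1], degree).convert()
    p_lo = Polynomial.fit(lo[:, 0], lo[:, 1], degree).convert()
    mid = (p_up + p_lo) / 2
    resid = max(
        float(np.max(np.abs(p_up(up[:, 0]) - up[:, 1]))),
        float(np.max(np.abs(p_lo(lo[:, 0]) - lo[:, 1]))),
    )
    return BorderFit(upper=p_up, lower=p_lo, midline=mid, degree=degree, max_residual=resid)


def pair_and_measure(
    a: RulerAnnotation, k: CameraIntrinsics, borders: BorderFit
) -> RayFan:
    """Measure per-pair observed widths W and signed midpoint offsets V.

    The bar abscissa of pair i is the mean x' of the two landmarks; the
    width is the vertical chord between the fitted border curves there
    (the ruler is assumed parallel to the image bottom edge).  V is
    positive in the left half image plane, so V = -x'.
    """
    up = pixel_to_plane(a.upper, k)
    lo = pixel_to_plane(a.lower, k)
    x_bar = 0.5 * (up[:, 0] + lo[:, 0])
    w = borders.lower(x_bar) - borders.upper(x_bar)
    if np.any(w <= 0):
        raise ReconstructionError(
            "fitted border curves cross: non-positive observed width"
        )
    V = -x_bar
    n = len(V)
    order = np.argsort(-V, kind="stable")  # descending: left of image first
    if np.array_equal(order, np.arange(n)):
        rev = False
    elif np.array_equal(order, np.arange(n)[::-1]):
        rev = True
    else:
        raise ReconstructionError(
            "landmark offsets are not monotone along the ruler; landmarks "
            "mis-ordered or duplicated"
        )
    inv = np.empty_like(order)
    inv[order] = np.arange(n)
    flat = np.sort(inv[a.flat_bottom])
    return RayFan(V=V[order], W=w[order], flat_bottom=flat, reversed_annotation=rev)


def initial_rays(fan: RayFan, D: float, k: CameraIntrinsics) -> np.ndarray:
    """Initial ray lengths from the pinhole width relation r0 = f D / W."""
    if D <= 0:
        raise ValueError("ruler width must be positive")
    return k.f * D / fan.W


def inter_ray_angles(fan: RayFan, k: CameraIntrinsics) -> np.ndarray:
    """Angles between consecutive landmark rays:
    theta_i = arctan(V_i / f) - arctan(V_{i+1} / f)."""
    V = fan.V
    if np.any(np.diff(V) >= 0):
        raise ReconstructionError(
            "landmark offsets V must be strictly decreasing; landmarks are "
            "mis-sorted or duplicated"
        )
    alpha = ray_angle(V, k.f)
    theta = alpha[:-1] - alpha[1:]
    fan.theta = theta
    return theta


# ---------------------------------------------------------------------------
# ray-length optimization
# ---------------------------------------------------------------------------


def _chords(r: np.ndarray, theta: np.ndarray) -> np.ndarray:
    r0, r1 = r[:-1], r[1:]
    return np.sqrt(np.maximum(r0**2 + r1**2 - 2 * r0 * r1 * np.cos(theta), 0.0))


def objective_J(r: np.ndarray, theta: np.ndarray, C: float | np.ndarray) -> float:
    """Sum of squared differences between the law-of-cosines chord estimates
    and the known marker spacings."""
    r = np.asarray(r, dtype=float)
    C = np.broadcast_to(np.asarray(C, dtype=float), (len(r) - 1,))
    return float(np.sum((_chords(r, theta) - C) ** 2))


def _objective_grad(r: np.ndarray, theta: np.ndarray, C: np.ndarray) -> np.ndarray:
    c_hat = _chords(r, theta)
    c_hat = np.where(c_hat == 0, 1e-300, c_hat)
    resid = c_hat - C
    cos_t = np.cos(theta)
    d_prev = (r[:-1] - r[1:] * cos_t) / c_hat  # dC_i/dr_i
    d_next = (r[1:] - r[:-1] * cos_t) / c_hat  # dC_i/dr_{i+1}
    grad = np.zeros_like(r)
    grad[:-1] += 2 * resid * d_prev
    grad[1:] += 2 * resid * d_next
    return grad


def flat_bottom_residuals(
    r: np.ndarray, fan: RayFan, k: CameraIntrinsics
) -> np.ndarray:
    """Equality-constraint residuals forcing consecutive flat-bottom points
    onto one vertical depth: r_k cos(alpha_k) - r_{k+1} cos(alpha_{k+1})."""
    ss = fan.flat_bottom
    if len(ss) < 2:
        warnings.warn("flat-bottom region has fewer than 2 landmarks; "
                      "no depth constraints emitted", stacklevel=2)
        return np.zeros(0)
    cos_a = np.cos(ray_angle(fan.V[ss], k.f))
    prod = np.asarray(r)[ss] * cos_a
    return prod[:-1] - prod[1:]


def _chord_step(r_adjacent: float, theta: float, C: float, guess: float) -> float:
    """Solve the law-of-cosines chord equation for the next ray length,
    choosing the quadratic root nearest the pinhole estimate."""
    base = r_adjacent * np.cos(theta)
    disc = C**2 - (r_adjacent * np.sin(theta)) ** 2
    if disc <= 0:
        return base  # grazing interval: closest-point fallback
    lo, hi = base - np.sqrt(disc), base + np.sqrt(disc)
    return lo if abs(lo - guess) <= abs(hi - guess) else hi


def _chain_init(
    fan: RayFan, C_arr: np.ndarray, r0: np.ndarray, k: CameraIntrinsics
) -> np.ndarray:
    """Near-exact starting point for the solver: pin the flat-bottom depth
    by least squares over the bottom intervals, then march the chord
    equation outward to the rims.

    The chord objective admits many exact solutions (each interval's
    quadratic has two roots); starting in the branch consistent with the
    pinhole initial rays keeps the optimizer out of folded configurations.
    """
    alpha = ray_angle(fan.V, k.f)
    r = np.array(r0, dtype=float)
    ss = fan.flat_bottom
    if len(ss) >= 2:
        d_tan = -np.diff(np.tan(alpha[ss]))  # tan(alpha) decreases left->right
        Cb = C_arr[ss[:-1]]
        denom = float(np.sum(d_tan * d_tan))
        if denom > 0 and np.all(d_tan > 0):
            w = float(np.sum(Cb * d_tan) / denom)
            r[ss] = w / np.cos(alpha[ss])
    left, right = int(ss[0]), int(ss[-1])
    theta = fan.theta
    for i in range(left - 1, -1, -1):
        r[i] = _chord_step(r[i + 1], theta[i], C_arr[i], r0[i])
    for i in range(right + 1, len(r)):
        r[i] = _chord_step(r[i - 1], theta[i - 1], C_arr[i - 1], r0[i])
    return r


def optimize_rays(
    fan: RayFan,
    C: float | np.ndarray,
    r0: np.ndarray,
    k: CameraIntrinsics,
    *,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> tuple[np.ndarray, SolverDiagnostics]:
    """Minimize the chord objective subject to the flat-bottom equality
    constraints (SLSQP, bounded to [0.2, 5] x the pinhole initial rays).

    The user-supplied pinhole rays seed a chain continuation whose result is
    the actual solver start; this keeps the search in the geometrically
    consistent branch of the chord equations.
    """
    r0 = np.asarray(r0, dtype=float)
    if np.any(r0 <= 0):
        raise ValueError("initial rays must be positive")
    theta = fan.theta if fan.theta is not None else inter_ray_angles(fan, k)
    C_arr = np.broadcast_to(np.asarray(C, dtype=float), (len(r0) - 1,)).copy()

    ss = fan.flat_bottom
    cos_all = np.cos(ray_angle(fan.V, k.f))
    constraints = []
    if len(ss) >= 2:
        cos_b = cos_all[ss]

        def cons_f(r: np.ndarray) -> np.ndarray:
            prod = r[ss] * cos_b
            return prod[:-1] - prod[1:]

        def cons_jac(r: np.ndarray) -> np.ndarray:
            jac = np.zeros((len(ss) - 1, len(r)))
            rows = np.arange(len(ss) - 1)
            jac[rows, ss[:-1]] = cos_b[:-1]
            jac[rows, ss[1:]] = -cos_b[1:]
            return jac

        constraints.append({"type": "eq", "fun": cons_f, "jac": cons_jac})
    else:
        warnings.warn("flat-bottom region has fewer than 2 landmarks; "
                      "optimizing without depth constraints", stacklevel=2)

    start = _chain_init(fan, C_arr, r0, k) if len(ss) >= 1 else r0
    start = np.clip(start, 0.2 * r0, 5.0 * r0)
    res = minimize(
        objective_J,
        start,
        args=(theta, C_arr),
        jac=_objective_grad,
        method="SLSQP",
        bounds=list(zip(0.2 * r0, 5.0 * r0)),
        constraints=constraints,
        options={"maxiter": max_iter, "ftol": tol},
    )
    viol = (
        float(np.max(np.abs(flat_bottom_residuals(res.x, fan, k))))
        if len(ss) >= 2
        else 0.0
    )
    j0 = objective_J(r0, theta, C_arr)
    j_star = objective_J(res.x, theta, C_arr)
    diag = SolverDiagnostics(
        iterations=int(res.nit),
        initial_J=j0,
        final_J=j_star,
        max_constraint_violation=viol,
        message=str(res.message),
    )
    if not res.success and not (j_star <= j0 and viol < 1e-6):
        raise ReconstructionError(f"ray optimization failed: {diag}")
    if viol > 1e-6 * float(np.max(r0)):
        raise ReconstructionError(
            f"flat-bottom constraint violated after optimization: {diag}"
        )
    fan.r = res.x
    return res.x, diag


def rays_to_cross_section(
    r: np.ndarray, fan: RayFan, k: CameraIntrinsics
) -> CrossSection:
    """Intersect the optimized rays with the ruler's vertical plane:
    u = r sin(alpha), w = r cos(alpha)."""
    alpha = ray_angle(fan.V, k.f)
    return CrossSection(
        u=np.asarray(r) * np.sin(alpha),
        w=np.asarray(r) * np.cos(alpha),
        flat_bottom=fan.flat_bottom,
    )


# ---------------------------------------------------------------------------
# symmetrization and revolution
# ---------------------------------------------------------------------------


def symmetrize(
    cs: CrossSection, *, n_grid: int = PROFILE_GRID_N, n_dense: int = 4000
) -> HalfProfile:
    """Turn a reconstructed cross-section into a symmetric half profile.

    Steps: cubic-spline the points (parametrized by chord length); shift
    horizontally so the midpoint of the two endpoints sits at u = 0; rotate
    about that center so both endpoints share one depth; split at the
    deepest point; resample both halves on a uniform z grid and average.
    """
    u, w = np.asarray(cs.u, dtype=float), np.asarray(cs.w, dtype=float)
    if len(u) < 4:
        raise ReconstructionError("need at least 4 cross-section points")
    t = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(u), np.diff(w)))])
    if np.any(np.diff(t) <= 0):
        raise ReconstructionError("coincident consecutive cross-section points")
    spl_u = CubicSpline(t, u)
    spl_w = CubicSpline(t, w)
    td = np.linspace(0.0, t[-1], n_dense)
    ud, wd = spl_u(td), spl_w(td)

    # shift: curve center (midpoint of the endpoints) to u = 0
    uc = 0.5 * (ud[0] + ud[-1])
    wc = 0.5 * (wd[0] + wd[-1])
    ud -= uc

    # rotate about the curve center so the endpoints share one depth
    # (arctan of the endpoint-line slope, so curve orientation is irrelevant)
    depth_scale = max(np.max(wd) - min(wd[0], wd[-1]), 1e-12)
    pre_mismatch = abs(wd[0] - wd[-1])
    du_end = ud[-1] - ud[0]
    if abs(du_end) < 1e-9:
        raise ReconstructionError("cross-section endpoints coincide horizontally")
    phi = np.arctan((wd[-1] - wd[0]) / du_end)
    cos_p, sin_p = np.cos(phi), np.sin(phi)
    du, dw = ud, wd - wc
    ud = du * cos_p + dw * sin_p
    wd = -du * sin_p + dw * cos_p + wc
    if pre_mismatch > 0.2 * depth_scale:
        warnings.warn(
            f"endpoint depths differed by {pre_mismatch:.2f} mm before "
            "rotation (> 20% of depth): the ruler may not be central or the "
            "camera not overhead",
            stacklevel=2,
        )

    i_bot = int(np.argmax(wd))
    w_bot = wd[i_bot]
    depth = float(w_bot - 0.5 * (wd[0] + wd[-1]))
    z_grid = np.linspace(0.0, max(depth, 0.0), n_grid)
    if depth <= 1e-9:
        # degenerate flat plate: zero-depth "bowl" of the observed extent
        rho = np.full(n_grid, 0.5 * abs(ud[-1] - ud[0]))
        eps = max(1e-9, abs(depth))
        return HalfProfile(z=np.linspace(0.0, eps, n_grid), rho=rho)

    halves = []
    for z_b, rho_b in (
        (w_bot - wd[i_bot::-1], np.abs(ud[i_bot::-1])),  # deepest -> first endpoint
        (w_bot - wd[i_bot:], np.abs(ud[i_bot:])),        # deepest -> last endpoint
    ):
        z_m, rho_m = monotone_profile(z_b, rho_b)
        halves.append(np.interp(z_grid, z_m, rho_m))
    rho_grid = 0.5 * (halves[0] + halves[1])
    return HalfProfile(z=z_grid, rho=rho_grid)


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------


@dataclass
class ReconstructionResult:
    model: BowlModel
    fan: RayFan
    cross_section: CrossSection
    borders: BorderFit
    solver: SolverDiagnostics
    initial_rays: np.ndarray = field(repr=False, default=None)


def reconstruct(
    a: RulerAnnotation,
    k: CameraIntrinsics,
    *,
    full_result: bool = False,
) -> BowlModel | ReconstructionResult:
    """Full pipeline: annotation + intrinsics -> revolved bowl model."""
    borders = fit_borders(a, k)
    fan = pair_and_measure(a, k, borders)
    inter_ray_angles(fan, k)
    r0 = initial_rays(fan, a.width, k)
    C = a.spacing_per_interval()
    if fan.reversed_annotation:
        C = C[::-1]
    r_star, diag = optimize_rays(fan, C, r0, k)
    cs = rays_to_cross_section(r_star, fan, k)
    profile = symmetrize(cs)
    model = revolve(profile)
    if full_result:
        return ReconstructionResult(
            model=model,
            fan=fan,
            cross_section=cs,
            borders=borders,
            solver=diag,
            initial_rays=r0,
        )
    return model
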