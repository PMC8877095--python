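"""Forward simulator: parametric bowls, projected ruler annotations with
pixel noise, and simulated liquid fills with exact ground truth.

Everything the reconstruction and volume pipelines consume can be generated
here, so tests and acceptance runs need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .annotations import RulerAnnotation
from .camera import CameraIntrinsics, plane_to_pixel, project
from .model import BowlModel, HalfProfile, monotone_profile
from .pose import BowlPose, EllipseParams, project_circle

__all__ = [
    "ParametricBowl",
    "SimulationConfig",
    "SimulatedRuler",
    "FillObservation",
    "make_profile",
    "simulate_ruler_annotation",
    "simulate_fill",
    "fronto_parallel_pose",
    "tilted_pose",
    "DEFAULT_INTRINSICS",
]

FAMILIES = ("cylinder", "spherical-cap", "power-wall", "cone-frustum")

#: a plausible smartphone-style camera: 4 mm focal length, 1.5 um pixels
DEFAULT_INTRINSICS = CameraIntrinsics(
    f=4.0, sx=0.0015, sy=0.0015, image_width=4000, image_height=3000
)


@dataclass(frozen=True)
class ParametricBowl:
    """Axisymmetric bowl with a flat bottom of radius ``rb``, rim radius
    ``rr`` and depth ``h`` (all mm).

    Families: ``cylinder`` (rb == rr, vertical wall), ``spherical-cap``
    (wall on a sphere through bottom and rim circles), ``power-wall``
    (rho(z) = rb + (rr - rb) (z/h)^p), ``cone-frustum`` (power-wall, p=1).

    ``fillet`` > 0 rounds the interior bottom-wall junction with a tangent
    circular arc of that radius, as on real (non-sharp) dining bowls; the
    arc replaces the outer part of the flat bottom and the foot of the wall.
    """

    family: str
    rb: float
    rr: float
    h: float
    p: float = 2.0
    fillet: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.h <= 0:
            raise ValueError("depth must be positive")
        if self.rb < 0 or self.rr <= 0:
            raise ValueError("radii must be non-negative (rim > 0)")
        if self.family == "cylinder" and self.rb != self.rr:
            raise ValueError("cylinder requires rb == rr")
        if self.family != "cylinder" and self.rr < self.rb:
            raise ValueError("rim radius must be >= bottom radius")
        if self.family == "power-wall" and self.p <= 0:
            raise ValueError("power-wall exponent must be positive")
        if self.fillet < 0 or self.fillet >= self.h:
            raise ValueError("fillet radius must lie in [0, depth)")

    # -- geometry -----------------------------------------------------------

    def _sphere(self) -> tuple[float, float]:
        """(center height zc, sphere radius) of the spherical-cap wall."""
        zc = (self.rr**2 - self.rb**2 + self.h**2) / (2 * self.h)
        return zc, float(np.hypot(self.rb, zc))

    def _wall_radius(self, z: np.ndarray) -> np.ndarray:
        """Sharp (un-filleted) wall radius rho(z)."""
        if self.family == "cylinder":
            return np.full_like(z, float(self.rr))
        if self.family == "spherical-cap":
            zc, rs = self._sphere()
            return np.sqrt(np.maximum(rs**2 - (zc - z) ** 2, 0.0))
        p = 1.0 if self.family == "cone-frustum" else self.p
        return self.rb + (self.rr - self.rb) * np.clip(z / self.h, 0, 1) ** p

    def half_cross_section(self, n: int = 4000) -> np.ndarray:
        """Dense (x, z) polyline of the interior from the bowl center (0, 0)
        along the flat bottom and up the wall to the rim, fillet applied."""
        z_wall = np.linspace(0.0, self.h, n)
        wall = np.column_stack([self._wall_radius(z_wall), z_wall])
        x_bottom_edge = float(self.rb)
        arc = np.empty((0, 2))
        if self.fillet > 0:
            rf = self.fillet

            def clearance(xc: float) -> float:
                d = np.linalg.norm(wall - [xc, rf], axis=1)
                return float(d.min()) - rf

            # fillet center (xc, rf): tangent to the bottom plane, tangent to
            # the wall; slide it inward until it just clears the wall
            lo, hi = 0.0, float(self.rb)
            if clearance(hi) < 0 < clearance(lo):
                xc = brentq(clearance, lo, hi, xtol=1e-10)
                center = np.array([xc, rf])
                i_t = int(np.argmin(np.linalg.norm(wall - center, axis=1)))
                tangent = wall[i_t]
                a1 = -np.pi / 2  # pointing down: bottom tangency at (xc, 0)
                a2 = float(np.arctan2(tangent[1] - rf, tangent[0] - xc))
                ang = np.linspace(a1, a2, 256)[1:]
                arc = center + rf * np.column_stack([np.cos(ang), np.sin(ang)])
                wall = wall[i_t + 1 :]
                x_bottom_edge = xc
            # else: junction already smoother than the fillet; leave as-is
        n_bot = max(int(n * x_bottom_edge / self.h), 8)
        bottom = np.column_stack(
            [np.linspace(0.0, x_bottom_edge, n_bot), np.zeros(n_bot)]
        )
        poly = np.vstack([bottom, arc, wall])
        keep = np.ones(len(poly), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(poly, axis=0), axis=1) > 1e-12
        return poly[keep]

    def radius_at(self, z: np.ndarray | float) -> np.ndarray | float:
        """Interior radius rho(z) for z in [0, h]."""
        z = np.asarray(z, dtype=float)
        if np.any(z < -1e-9) or np.any(z > self.h * (1 + 1e-9)):
            raise ValueError("z outside [0, depth]")
        if self.fillet == 0:
            return self._wall_radius(z)[()]
        poly = self.half_cross_section()
        z_m, rho_m = monotone_profile(poly[:, 1], poly[:, 0])
        return np.interp(z, z_m, rho_m)[()]

    def capacity_ml(self) -> float:
        """Capacity in mL: closed form for sharp bowls, fine quadrature of
        the filleted profile otherwise."""
        if self.fillet > 0:
            prof = make_profile(self, n=4001)
            return float(np.trapezoid(np.pi * prof.rho**2, prof.z) / 1000.0)
        if self.family == "cylinder":
            v = np.pi * self.rr**2 * self.h
        elif self.family == "spherical-cap":
            zc, rs = self._sphere()
            v = np.pi * (rs**2 * self.h - (zc**3 - (zc - self.h) ** 3) / 3.0)
        else:
            p = 1.0 if self.family == "cone-frustum" else self.p
            d = self.rr - self.rb
            v = np.pi * self.h * (
                self.rb**2 + 2 * self.rb * d / (p + 1) + d**2 / (2 * p + 1)
            )
        return float(v / 1000.0)


def make_profile(b: ParametricBowl, n: int = 501) -> HalfProfile:
    """Sample the bowl's half profile on a uniform z grid."""
    z = np.linspace(0.0, b.h, n)
    if b.fillet == 0:
        return HalfProfile(z=z, rho=np.atleast_1d(b._wall_radius(z)))
    poly = b.half_cross_section()
    z_m, rho_m = monotone_profile(poly[:, 1], poly[:, 0])
    return HalfProfile(z=z, rho=np.interp(z, z_m, rho_m))


@dataclass(frozen=True)
class SimulationConfig:
    """Scene layout for the ruler photograph.

    ``camera_height`` is the optical-center height above the bowl's interior
    bottom (mm); the camera looks straight down at the bowl center with the
    ruler laid along the image x axis.
    """

    camera_height: float = 400.0
    intrinsics: CameraIntrinsics = DEFAULT_INTRINSICS
    ruler_width: float = 19.0
    marker_spacing: float = 12.7
    noise_px: float = 0.5
    seed: int = 0
    #: markers within this height (mm) of the bottom are labeled flat --
    #: visual labeling cannot distinguish a sub-millimeter rise
    flat_label_tol: float = 1.0

    def __post_init__(self) -> None:
        if self.camera_height <= 0:
            raise ValueError("camera height must be positive")
        if self.ruler_width <= 0 or self.marker_spacing <= 0:
            raise ValueError("ruler width and marker spacing must be positive")
        if self.noise_px < 0:
            raise ValueError("noise must be non-negative")
        if self.flat_label_tol < 0:
            raise ValueError("flat-bottom labeling tolerance must be >= 0")


@dataclass
class SimulatedRuler:
    """A simulated annotation and its exact ground truth."""

    annotation: RulerAnnotation
    r_true: np.ndarray
    marker_points: np.ndarray  # (I, 3) centerline scene points
    marker_heights: np.ndarray  # z above the bowl bottom
    profile: HalfProfile
    bowl: ParametricBowl
    config: SimulationConfig = field(repr=False, default=None)


def _cross_section_polyline(b: ParametricBowl, n_wall: int = 6000) -> np.ndarray:
    """Dense (x, z) polyline of the central cross-section, left rim ->
    bottom -> right rim.  x is the horizontal coordinate in the ruler plane,
    z the height above the interior bottom."""
    half = b.half_cross_section(n=n_wall)
    left = half[::-1].copy()
    left[:, 0] = -left[:, 0]
    poly = np.vstack([left, half[1:]])
    keep = np.ones(len(poly), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(poly, axis=0), axis=1) > 1e-12
    return poly[keep]


def cross_section_arc_length(b: ParametricBowl) -> float:
    """Total arc length of the central interior cross-section."""
    poly = _cross_section_polyline(b)
    return float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))


def simulate_ruler_annotation(
    b: ParametricBowl, cfg: SimulationConfig | None = None
) -> SimulatedRuler:
    """Lay a marked tape across the bowl, project its borders to pixels and
    add landmark noise.

    Markers are arc-length samples at the configured spacing along the
    central cross-section, starting at one rim.  Border points sit half a
    tape width from the centerline along the surface direction perpendicular
    to the cross-section plane: straight offsets on the flat bottom,
    circumferential chords on the wall.
    """
    cfg = cfg or SimulationConfig()
    if cfg.camera_height <= b.h:
        raise ValueError("camera must be above the bowl rim")
    k = cfg.intrinsics
    poly = _cross_section_polyline(b)
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if cfg.marker_spacing > total:
        raise ValueError(
            f"marker spacing {cfg.marker_spacing} mm exceeds the cross-section "
            f"arc length {total:.1f} mm"
        )
    # markers at the regular spacing starting from one rim, plus a final
    # marker at the far rim (a physical tape is cut to span the bowl, so its
    # end interval is shorter than the marker spacing)
    n_regular = int(np.floor(total / cfg.marker_spacing)) + 1
    s_marks = np.arange(n_regular) * cfg.marker_spacing
    if total - s_marks[-1] < 0.25 * cfg.marker_spacing:
        s_marks = s_marks[:-1]  # avoid a near-degenerate end interval
    s_marks = np.append(s_marks, total)
    spacing: float | np.ndarray = np.diff(s_marks)
    if np.allclose(spacing, cfg.marker_spacing):
        spacing = cfg.marker_spacing
    n_markers = len(s_marks)
    x_m = np.interp(s_marks, s, poly[:, 0])
    z_m = np.interp(s_marks, s, poly[:, 1])

    half = cfg.ruler_width / 2.0
    upper3 = np.empty((n_markers, 3))
    lower3 = np.empty((n_markers, 3))
    Z = cfg.camera_height - z_m
    on_bottom = z_m < 1e-6
    for i in range(n_markers):
        if on_bottom[i] or abs(x_m[i]) < half:
            # flat bottom (or degenerate near-axis point): straight offset
            upper3[i] = (x_m[i], -half, Z[i])
            lower3[i] = (x_m[i], +half, Z[i])
        else:
            rho_c = abs(x_m[i])
            delta = half / rho_c  # half-width as arc on the circle of revolution
            upper3[i] = (x_m[i] * np.cos(delta), -rho_c * np.sin(delta), Z[i])
            lower3[i] = (x_m[i] * np.cos(delta), +rho_c * np.sin(delta), Z[i])

    upper_px = plane_to_pixel(project(upper3, k), k)
    lower_px = plane_to_pixel(project(lower3, k), k)
    rng = np.random.default_rng(cfg.seed)
    if cfg.noise_px > 0:
        upper_px = upper_px + rng.normal(0.0, cfg.noise_px, upper_px.shape)
        lower_px = lower_px + rng.normal(0.0, cfg.noise_px, lower_px.shape)

    flat_idx = np.where(z_m < max(cfg.flat_label_tol, 1e-9))[0]
    if flat_idx.size == 0:
        # no marker labeled flat: take the deepest marker
        flat_idx = np.array([int(np.argmax(Z))])
    annotation = RulerAnnotation(
        upper=upper_px,
        lower=lower_px,
        spacing=spacing,
        width=cfg.ruler_width,
        flat_bottom=flat_idx,
        image_width=k.image_width,
        image_height=k.image_height,
    )
    marker_points = np.column_stack([x_m, np.zeros(n_markers), Z])
    return SimulatedRuler(
        annotation=annotation,
        r_true=np.linalg.norm(marker_points, axis=1),
        marker_points=marker_points,
        marker_heights=z_m,
        profile=make_profile(b),
        bowl=b,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# simulated fills
# ---------------------------------------------------------------------------


def fronto_parallel_pose(m: BowlModel, camera_height: float) -> BowlPose:
    """Bowl sitting level, centered under the camera."""
    return BowlPose(
        center=np.array([0.0, 0.0, camera_height - m.depth]),
        normal=np.array([0.0, 0.0, -1.0]),
    )


def tilted_pose(
    m: BowlModel, camera_height: float, tilt_deg: float, azimuth_deg: float = 0.0
) -> BowlPose:
    """Rim plane tilted by ``tilt_deg`` about an axis at ``azimuth_deg``."""
    t = np.radians(tilt_deg)
    a = np.radians(azimuth_deg)
    normal = np.array(
        [np.sin(t) * np.cos(a), np.sin(t) * np.sin(a), -np.cos(t)]
    )
    return BowlPose(
        center=np.array([0.0, 0.0, camera_height - m.depth]), normal=normal
    )


@dataclass
class FillObservation:
    volume_ml: float
    fill_height: float
    rim_ellipse: EllipseParams
    surface_ellipse: EllipseParams
    surface_points: np.ndarray  # image-plane mm, optionally noisy
    rim_area: float
    surface_area: float

    @property
    def far(self) -> float:
        return self.surface_area / self.rim_area


def simulate_fill(
    m: BowlModel,
    pose: BowlPose,
    k: CameraIntrinsics,
    volume_ml: float,
    *,
    n_surface_points: int = 12,
    noise_px: float = 0.0,
    seed: int = 0,
) -> FillObservation:
    """Pose and project the rim circle and the flat liquid surface at the
    given fill volume; emit sampled surface points (optionally noisy) and
    exact projected ellipse areas."""
    if not 0 < volume_ml <= m.capacity_ml * (1 + 1e-9):
        raise ValueError(f"volume must lie in (0, capacity={m.capacity_ml:.1f}]")
    z = float(m.height_at_volume(min(volume_ml, m.capacity_ml)))
    rim_center = pose.center
    rim = project_circle(rim_center, pose.normal, m.diameter / 2.0, k)
    surf_center = pose.center - (m.depth - z) * pose.normal
    surf_radius = float(m.radius_at_height(z))
    if surf_radius <= 0:
        raise ValueError("fill surface has zero radius (empty bowl)")
    surface = project_circle(surf_center, pose.normal, surf_radius, k)
    pts = surface.sample(n_surface_points)
    if noise_px > 0:
        rng = np.random.default_rng(seed)
        sigma = np.array([k.sx, k.sy]) * noise_px  # pixel noise in plane mm
        pts = pts + rng.normal(0.0, 1.0, pts.shape) * sigma
    return FillObservation(
        volume_ml=float(volume_ml),
        fill_height=z,
        rim_ellipse=rim,
        surface_ellipse=surface,
        surface_points=pts,
        rim_area=rim.area,
        surface_area=surface.area,
    )
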