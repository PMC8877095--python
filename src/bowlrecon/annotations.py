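"""Read/write/validate ruler annotations, rim/surface point sets, and bowl
models.

Formats (all plain text, hand-editable):

* ruler landmarks — CSV with columns ``index, border, x_px, y_px`` where
  ``border`` is ``upper`` or ``lower`` and pixel coordinates use the usual
  top-left origin;
* ruler metadata — YAML sidecar with the physical constants, the
  flat-bottom index range (1-based, inclusive) and the image dimensions;
* rim / surface points — CSV with columns ``x_px, y_px``;
* bowl model — JSON storing the half-profile samples plus derived
  parameters.

Pixel coordinates are converted to the centered convention on read (and
back on write) using the image dimensions stored in the sidecar.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .model import BowlModel, HalfProfile, revolve

__all__ = [
    "RulerAnnotation",
    "RimAnnotation",
    "read_ruler_annotation",
    "write_ruler_annotation",
    "read_point_csv",
    "write_point_csv",
    "read_bowl_model",
    "write_bowl_model",
    "export_obj",
]

BOWL_MODEL_FORMAT_VERSION = 1


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass
class RulerAnnotation:
    """Paired ruler-border landmarks plus the physical ruler constants.

    ``upper`` / ``lower`` are ``(I, 2)`` arrays of centered pixel
    coordinates, index-paired along the ruler.  ``upper`` is the border with
    the smaller image y at each pair.  ``spacing`` is the physical arc
    length between adjacent markers: a scalar, or a per-interval array of
    length ``I - 1`` when the endpoint intervals differ.  ``flat_bottom``
    is the contiguous 0-based index range of pairs on the flat bottom.
    """

    upper: np.ndarray
    lower: np.ndarray
    spacing: float | np.ndarray
    width: float
    flat_bottom: np.ndarray
    image_width: int
    image_height: int

    def __post_init__(self) -> None:
        self.upper = np.asarray(self.upper, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        if self.upper.ndim != 2 or self.upper.shape[1] != 2:
            raise AnnotationError("upper border must be an (I, 2) array")
        if self.upper.shape != self.lower.shape:
            raise AnnotationError(
                f"border length mismatch: {self.upper.shape[0]} upper vs "
                f"{self.lower.shape[0]} lower landmarks"
            )
        if self.n_landmarks < 4:
            raise AnnotationError("need at least 4 landmark pairs")
        if not (np.all(np.isfinite(self.upper)) and np.all(np.isfinite(self.lower))):
            raise AnnotationError("non-finite landmark coordinates")
        if np.ndim(self.spacing) > 0:
            self.spacing = np.asarray(self.spacing, dtype=float)
            if self.spacing.shape != (self.n_landmarks - 1,):
                raise AnnotationError(
                    "per-interval spacing list must have I - 1 entries"
                )
            if np.any(self.spacing <= 0):
                raise AnnotationError("marker spacing must be positive")
        elif self.spacing <= 0:
            raise AnnotationError("marker spacing must be positive")
        if self.width <= 0:
            raise AnnotationError("ruler width must be positive")
        self.flat_bottom = np.asarray(self.flat_bottom, dtype=int)
        if self.flat_bottom.size == 0:
            raise AnnotationError("flat-bottom index set must be non-empty")
        if np.any(np.diff(self.flat_bottom) != 1):
            raise AnnotationError("flat-bottom index set must be contiguous")
        if self.flat_bottom.min() < 0 or self.flat_bottom.max() >= self.n_landmarks:
            raise AnnotationError("flat-bottom indices out of range")

    @property
    def n_landmarks(self) -> int:
        return self.upper.shape[0]

    def spacing_per_interval(self) -> np.ndarray:
        if np.ndim(self.spacing) > 0:
            return np.asarray(self.spacing, dtype=float)
        return np.full(self.n_landmarks - 1, float(self.spacing))


@dataclass
class RimAnnotation:
    """Rim (and optionally liquid-surface) observations from a meal image."""

    rim_points: np.ndarray
    surface_points: np.ndarray | None = None
    liquid_pixel_count: int | None = None
    rim_pixel_count: int | None = None

    def __post_init__(self) -> None:
        self.rim_points = np.asarray(self.rim_points, dtype=float)
        if self.rim_points.ndim != 2 or self.rim_points.shape[0] < 5:
            raise AnnotationError("need at least 5 rim points")
        if self.surface_points is not None:
            self.surface_points = np.asarray(self.surface_points, dtype=float)
            if self.surface_points.shape[0] < 5:
                raise AnnotationError("need at least 5 surface points")
        if (self.liquid_pixel_count is None) != (self.rim_pixel_count is None):
            raise AnnotationError("pixel counts must be given together")
        if self.rim_pixel_count is not None:
            if self.rim_pixel_count <= 0 or self.liquid_pixel_count < 0:
                raise AnnotationError("pixel counts must be non-negative (rim > 0)")
            if self.liquid_pixel_count > self.rim_pixel_count:
                raise AnnotationError("liquid pixel count exceeds rim pixel count")


def _center_offset(width: int, height: int) -> np.ndarray:
    return np.array([width / 2.0, height / 2.0])


def read_ruler_annotation(points_path: str | Path, meta_path: str | Path) -> RulerAnnotation:
    """Read a landmark CSV plus its metadata sidecar.

    Coordinates are converted from top-left-origin to centered pixels.
    """
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict):
        raise AnnotationError(f"{meta_path}: not a mapping")
    try:
        width = float(meta["ruler_width_mm"])
        spacing = meta.get("marker_spacing_mm")
        fb = meta["flat_bottom"]
        img_w = int(meta["image_width_px"])
        img_h = int(meta["image_height_px"])
    except KeyError as exc:
        raise AnnotationError(f"{meta_path}: missing required key {exc}") from exc
    if "interval_spacings_mm" in meta:
        spacing = np.asarray(meta["interval_spacings_mm"], dtype=float)
    elif spacing is None:
        raise AnnotationError(f"{meta_path}: need marker_spacing_mm or interval_spacings_mm")
    else:
        spacing = float(spacing)
    try:
        flat = np.arange(int(fb["first"]) - 1, int(fb["last"]))
    except (TypeError, KeyError) as exc:
        raise AnnotationError(
            f"{meta_path}: flat_bottom must map 'first' and 'last' (1-based)"
        ) from exc

    rows: dict[str, dict[int, tuple[float, float]]] = {"upper": {}, "lower": {}}
    with open(points_path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"index", "border", "x_px", "y_px"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise AnnotationError(
                f"{points_path}: expected columns {sorted(required)}"
            )
        for row in reader:
            border = row["border"].strip().lower()
            if border not in rows:
                raise AnnotationError(f"{points_path}: unknown border {border!r}")
            idx = int(row["index"])
            if idx in rows[border]:
                raise AnnotationError(f"{points_path}: duplicate {border} index {idx}")
            rows[border][idx] = (float(row["x_px"]), float(row["y_px"]))

    if sorted(rows["upper"]) != sorted(rows["lower"]):
        raise AnnotationError(
            f"{points_path}: border length mismatch: {len(rows['upper'])} upper vs "
            f"{len(rows['lower'])} lower landmarks"
        )
    order = sorted(rows["upper"])
    upper = np.array([rows["upper"][i] for i in order]) - _center_offset(img_w, img_h)
    lower = np.array([rows["lower"][i] for i in order]) - _center_offset(img_w, img_h)
    return RulerAnnotation(
        upper=upper,
        lower=lower,
        spacing=spacing,
        width=width,
        flat_bottom=flat,
        image_width=img_w,
        image_height=img_h,
    )


def write_ruler_annotation(
    a: RulerAnnotation, points_path: str | Path, meta_path: str | Path
) -> None:
    off = _center_offset(a.image_width, a.image_height)
    with open(points_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "border", "x_px", "y_px"])
        for border, pts in (("upper", a.upper), ("lower", a.lower)):
            for i, (x, y) in enumerate(pts + off, start=1):
                writer.writerow([i, border, repr(float(x)), repr(float(y))])
    meta: dict = {
        "ruler_width_mm": float(a.width),
        "flat_bottom": {
            "first": int(a.flat_bottom[0]) + 1,
            "last": int(a.flat_bottom[-1]) + 1,
        },
        "image_width_px": int(a.image_width),
        "image_height_px": int(a.image_height),
    }
    if np.ndim(a.spacing) > 0:
        meta["interval_spacings_mm"] = [float(c) for c in a.spacing]
    else:
        meta["marker_spacing_mm"] = float(a.spacing)
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_point_csv(path: str | Path, image_width: int, image_height: int) -> np.ndarray:
    """Read an ``x_px, y_px`` CSV into centered pixel coordinates."""
    pts = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"x_px", "y_px"} <= set(reader.fieldnames):
            raise AnnotationError(f"{path}: expected columns x_px, y_px")
        for row in reader:
            pts.append((float(row["x_px"]), float(row["y_px"])))
    if not pts:
        raise AnnotationError(f"{path}: empty point file")
    return np.asarray(pts) - _center_offset(image_width, image_height)


def write_point_csv(
    points: np.ndarray, path: str | Path, image_width: int, image_height: int
) -> None:
    pts = np.asarray(points, dtype=float) + _center_offset(image_width, image_height)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x_px", "y_px"])
        for x, y in pts:
            writer.writerow([repr(float(x)), repr(float(y))])


# -- bowl model persistence --------------------------------------------------


def write_bowl_model(model: BowlModel, path: str | Path) -> None:
    data = {
        "format": "bowlrecon-model",
        "version": BOWL_MODEL_FORMAT_VERSION,
        "profile": {
            "z_mm": [float(v) for v in model.profile.z],
            "rho_mm": [float(v) for v in model.profile.rho],
        },
        "derived": {
            "diameter_mm": model.diameter,
            "depth_mm": model.depth,
            "capacity_ml": model.capacity_ml,
        },
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def read_bowl_model(path: str | Path) -> BowlModel:
    """Read a bowl-model JSON; derived parameters are recomputed from the
    stored profile and checked against the stored values."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise AnnotationError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(data, dict) or data.get("format") != "bowlrecon-model":
        raise AnnotationError(f"{path}: not a bowl-model file")
    if data.get("version") != BOWL_MODEL_FORMAT_VERSION:
        raise AnnotationError(
            f"{path}: unsupported model version {data.get('version')!r} "
            f"(expected {BOWL_MODEL_FORMAT_VERSION})"
        )
    prof = data["profile"]
    model = revolve(HalfProfile(z=np.asarray(prof["z_mm"]), rho=np.asarray(prof["rho_mm"])))
    stored = data.get("derived", {})
    cap = stored.get("capacity_ml")
    if cap is not None and abs(cap - model.capacity_ml) > 1e-3 * max(1.0, abs(cap)):
        raise AnnotationError(
            f"{path}: stored capacity {cap} mL disagrees with profile "
            f"({model.capacity_ml:.3f} mL)"
        )
    return model


def export_obj(model: BowlModel, path: str | Path, n_theta: int = 72) -> None:
    """Export the revolved interior surface as a Wavefront OBJ mesh
    (visualization only; the half profile is the canonical form)."""
    z, rho = model.profile.z, model.profile.rho
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    with open(path, "w") as fh:
        fh.write("# bowlrecon revolved interior surface\n")
        for zi, ri in zip(z, rho):
            for t in theta:
                fh.write(f"v {ri * np.cos(t):.4f} {ri * np.sin(t):.4f} {zi:.4f}\n")
        n_z = len(z)
        for i in range(n_z - 1):
            for j in range(n_theta):
                a = i * n_theta + j + 1
                b = i * n_theta + (j + 1) % n_theta + 1
                c = a + n_theta
                d = b + n_theta
                fh.write(f"f {a} {b} {d} {c}\n")
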