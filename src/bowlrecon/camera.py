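"""Pinhole-camera conventions shared by every other module.

Conventions
-----------
* Pixel coordinates are *centered*: (0, 0) is the image center, x grows to
  the right, y grows downward.  Readers of annotation files convert from
  top-left-origin pixels (see :mod:`bowlrecon.annotations`).
* Image-plane coordinates are metric (mm) and keep the downward-y
  orientation of the pixel grid.
* The camera (scene) frame has its origin at the optical center, +Z along
  the optical axis toward the scene, +X parallel to the image x axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "CameraIntrinsics",
    "pixel_to_plane",
    "plane_to_pixel",
    "project",
    "ray_angle",
    "read_intrinsics",
    "write_intrinsics",
]


class BehindCameraError(ValueError):
    """A scene point with Z <= 0 was projected."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole parameters.

    Parameters
    ----------
    f : float
        Focal length in mm.
    sx, sy : float
        Pixel pitch (mm per pixel) along the image x and y directions.
    ox, oy : float
        Principal-point offset in pixels, relative to the image center.
    image_width, image_height : int, optional
        Image dimensions in pixels; required to convert top-left-origin
        annotation coordinates to centered coordinates.
    undistorted : bool
        Asserts that lens distortion has been removed upstream.
    """

    f: float
    sx: float = 1.0
    sy: float = 1.0
    ox: float = 0.0
    oy: float = 0.0
    image_width: int | None = None
    image_height: int | None = None
    undistorted: bool = True

    def __post_init__(self) -> None:
        for name in ("f", "sx", "sy"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("ox", "oy"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def focal_px(self) -> float:
        """Focal length expressed in horizontal pixels (f / sx)."""
        return self.f / self.sx


def _as_points(p: Any, dim: int) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.shape[-1] != dim:
        raise ValueError(f"expected points with last axis {dim}, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite coordinates")
    return arr


def pixel_to_plane(p: Any, k: CameraIntrinsics) -> np.ndarray:
    """Centered pixel coordinates -> metric image-plane coordinates (mm).

    ``x' = sx * (x + ox)``, ``y' = sy * (y + oy)``.  Accepts a single
    ``(x, y)`` pair or an ``(..., 2)`` array.
    """
    arr = _as_points(p, 2)
    out = np.empty_like(arr)
    out[..., 0] = k.sx * (arr[..., 0] + k.ox)
    out[..., 1] = k.sy * (arr[..., 1] + k.oy)
    return out


def plane_to_pixel(p: Any, k: CameraIntrinsics) -> np.ndarray:
    """Exact algebraic inverse of :func:`pixel_to_plane`."""
    arr = _as_points(p, 2)
    out = np.empty_like(arr)
    out[..., 0] = arr[..., 0] / k.sx - k.ox
    out[..., 1] = arr[..., 1] / k.sy - k.oy
    return out


def project(s: Any, k: CameraIntrinsics) -> np.ndarray:
    """Project camera-frame points ``(X, Y, Z)`` onto the image plane (mm).

    ``x' = f X / Z``, ``y' = f Y / Z``.  Raises :class:`BehindCameraError`
    for any point with ``Z <= 0``.
    """
    arr = _as_points(s, 3)
    z = arr[..., 2]
    if np.any(z <= 0):
        raise BehindCameraError("cannot project points with Z <= 0")
    out = np.empty(arr.shape[:-1] + (2,))
    out[..., 0] = k.f * arr[..., 0] / z
    out[..., 1] = k.f * arr[..., 1] / z
    return out


def ray_angle(V: Any, f: float) -> np.ndarray | float:
    """Angle between the optical axis and the ray through an image-plane
    offset ``V`` (mm): ``arctan(V / f)``.

    ``V`` is signed, positive for offsets in the left half image plane.
    """
    if f <= 0:
        raise ValueError("focal length must be positive")
    return np.arctan(np.asarray(V, dtype=float) / f)[()]


# -- intrinsics config file -------------------------------------------------

_KEYMAP = {
    "f_mm": "f",
    "sx_mm_per_px": "sx",
    "sy_mm_per_px": "sy",
    "ox_px": "ox",
    "oy_px": "oy",
    "image_width_px": "image_width",
    "image_height_px": "image_height",
    "undistorted": "undistorted",
}


def read_intrinsics(path: str | Path) -> CameraIntrinsics:
    """Load intrinsics from a YAML/JSON config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "f_mm" not in raw:
        raise ValueError(f"{path}: not an intrinsics file (missing 'f_mm')")
    unknown = set(raw) - set(_KEYMAP)
    if unknown:
        raise ValueError(f"{path}: unknown intrinsics keys {sorted(unknown)}")
    kwargs = {_KEYMAP[key]: val for key, val in raw.items()}
    return CameraIntrinsics(**kwargs)


def write_intrinsics(k: CameraIntrinsics, path: str | Path) -> None:
    inv = {v: k_ for k_, v in _KEYMAP.items()}
    data = {}
    for field, key in inv.items():
        val = getattr(k, field)
        if val is not None:
            data[key] = val
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
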