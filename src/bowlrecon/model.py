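"""Bowl-of-revolution model: half profile, derived parameters, level table."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = ["HalfProfile", "BowlModel", "revolve", "monotone_profile"]


def monotone_profile(z: np.ndarray, rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Force z non-decreasing along a profile branch, keeping the last
    sample of every equal-z run (so flat-bottom samples collapse to the
    bottom edge radius)."""
    z = np.maximum.accumulate(np.asarray(z, dtype=float))
    rho = np.asarray(rho, dtype=float)
    keep = np.ones(len(z), dtype=bool)
    keep[:-1] = np.diff(z) > 0
    return z[keep], rho[keep]


@dataclass
class HalfProfile:
    """Interior radius rho(z) sampled on a uniform z grid.

    z = 0 at the deepest interior point, z = depth at the rim; both in mm.
    """

    z: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.z.ndim != 1 or self.z.shape != self.rho.shape:
            raise ValueError("z and rho must be 1-D arrays of equal length")
        if self.z.size < 2:
            raise ValueError("profile needs at least two samples")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z grid must be strictly increasing")
        if self.z[0] != 0:
            raise ValueError("profile must start at z = 0")
        if np.any(self.rho < 0):
            raise ValueError("negative radius in profile")

    @property
    def depth(self) -> float:
        return float(self.z[-1])

    def radius_at(self, z: float | np.ndarray) -> np.ndarray | float:
        return np.interp(z, self.z, self.rho)[()]


@dataclass
class BowlModel:
    """Reconstructed bowl interior.

    Derived quantities (capacity, diameter, the level<->volume table) are
    computed from the stored half profile at construction time, so a model
    read back from disk is always self-consistent.
    """

    profile: HalfProfile
    diameter: float = field(init=False)
    depth: float = field(init=False)
    capacity_ml: float = field(init=False)
    #: cumulative volume (mL) below each profile grid height
    level_volumes_ml: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        z, rho = self.profile.z, self.profile.rho
        vol_mm3 = cumulative_trapezoid(np.pi * rho**2, z, initial=0.0)
        self.level_volumes_ml = vol_mm3 / 1000.0
        self.capacity_ml = float(self.level_volumes_ml[-1])
        self.depth = self.profile.depth
        self.diameter = float(2.0 * rho[-1])

    # -- level <-> volume lookups (monotone interpolation on the table) ----

    def height_at_volume(self, v_ml: float | np.ndarray) -> np.ndarray | float:
        """Fill height z (mm) holding volume ``v_ml`` (mL)."""
        v = np.asarray(v_ml, dtype=float)
        if np.any(v < 0) or np.any(v > self.capacity_ml * (1 + 1e-9)):
            raise ValueError("volume outside [0, capacity]")
        return np.interp(v, self.level_volumes_ml, self.profile.z)[()]

    def volume_at_height(self, z: float | np.ndarray) -> np.ndarray | float:
        """Cumulative volume (mL) below height ``z`` (mm)."""
        return np.interp(z, self.profile.z, self.level_volumes_ml)[()]

    def radius_at_height(self, z: float | np.ndarray) -> np.ndarray | float:
        return self.profile.radius_at(z)


def revolve(profile: HalfProfile) -> BowlModel:
    """Rotate a half profile 360 degrees about the vertical axis.

    Capacity is the solid-of-revolution volume pi * integral(rho^2 dz) by
    composite trapezoid quadrature on the stored grid.
    """
    return BowlModel(profile=profile)
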