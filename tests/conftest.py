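import numpy as np
import pytest

from bowlrecon.camera import CameraIntrinsics
from bowlrecon.model import revolve
from bowlrecon.simulate import (
    DEFAULT_INTRINSICS,
    ParametricBowl,
    SimulationConfig,
    fronto_parallel_pose,
    make_profile,
    simulate_ruler_annotation,
)


@pytest.fixture(scope="session")
def intrinsics() -> CameraIntrinsics:
    return DEFAULT_INTRINSICS


@pytest.fixture(scope="session")
def unit_intrinsics() -> CameraIntrinsics:
    """Identity pixel pitch, f = 3 mm: handy for hand-computed examples."""
    return CameraIntrinsics(f=3.0, sx=1.0, sy=1.0, image_width=100, image_height=100)


@pytest.fixture(scope="session")
def mid_bowl() -> ParametricBowl:
    return ParametricBowl("spherical-cap", 35, 62, 50, fillet=12)


@pytest.fixture(scope="session")
def mid_bowl_model(mid_bowl):
    return revolve(make_profile(mid_bowl))


@pytest.fixture(scope="session")
def mid_bowl_pose(mid_bowl_model):
    return fronto_parallel_pose(mid_bowl_model, 450.0)


@pytest.fixture
def sim_config():
    def factory(noise_px=0.0, seed=0, **kwargs):
        kwargs.setdefault("camera_height", 450.0)
        kwargs.setdefault("ruler_width", 6.0)
        kwargs.setdefault("marker_spacing", 5.0)
        return SimulationConfig(noise_px=noise_px, seed=seed, **kwargs)

    return factory


@pytest.fixture(scope="session")
def noiseless_mid_sim(mid_bowl):
    cfg = SimulationConfig(
        camera_height=450.0, ruler_width=6.0, marker_spacing=5.0, noise_px=0.0
    )
    return simulate_ruler_annotation(mid_bowl, cfg), cfg


def flat_plate_annotation(
    k: CameraIntrinsics, depth_mm: float = 400.0, n: int = 9,
    spacing_mm: float = 12.7, width_mm: float = 19.0,
):
    """Fronto-parallel flat plate: all landmark pairs on the plane Z = depth."""
    from bowlrecon.annotations import RulerAnnotation
    from bowlrecon.camera import plane_to_pixel, project

    x = (np.arange(n) - (n - 1) / 2) * spacing_mm
    up3 = np.column_stack([x, np.full(n, -width_mm / 2), np.full(n, depth_mm)])
    lo3 = np.column_stack([x, np.full(n, width_mm / 2), np.full(n, depth_mm)])
    return RulerAnnotation(
        upper=plane_to_pixel(project(up3, k), k),
        lower=plane_to_pixel(project(lo3, k), k),
        spacing=spacing_mm,
        width=width_mm,
        flat_bottom=np.arange(n),
        image_width=k.image_width,
        image_height=k.image_height,
    )
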