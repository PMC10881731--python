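import numpy as np
import pytest

from vesseltort.synthetic import SceneSpec, VesselSpec, generate_scene


def sinusoid_vessel(
    amplitude: float,
    wavelength: float = 50.0,
    span: float | None = None,
    caliber: float = 6.0,
    vessel_class: str = "artery",
    start=(150.0, 30.0),
    direction=(0.0, 1.0),
    vessel_id: int = 0,
) -> VesselSpec:
    if span is None:
        span = 3 * wavelength / 2 + 20
    return VesselSpec(
        id=vessel_id,
        start=start,
        direction=direction,
        arc_span=span,
        amplitude=amplitude,
        wavelength=wavelength,
        caliber=caliber,
        vessel_class=vessel_class,
    )


def single_vessel_scene(vessel: VesselSpec, size: int = 300):
    spec = SceneSpec(
        height=size,
        width=size,
        vessels=(vessel,),
        od_location=(size - 20, size - 20),
        fovea_location=(10, 10),
    )
    return generate_scene(spec)


@pytest.fixture(scope="session")
def straight_artery_scene():
    """One straight artery of caliber 8, clear of the optic-disc region."""
    vessel = sinusoid_vessel(0.0, caliber=8.0, span=200.0, start=(100.0, 30.0))
    return single_vessel_scene(vessel, size=300)


@pytest.fixture(scope="session")
def sinusoid_scene():
    """One sinusoidal vein (amplitude 10, wavelength 50, span 100)."""
    vessel = sinusoid_vessel(10.0, wavelength=50.0, span=100.0, vessel_class="vein")
    return single_vessel_scene(vessel, size=300)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
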