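import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from retmosaic import SimConfig, SomaField, SomaPoint, Window, simulate_hardcore

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

WINDOW_SIDE = 353.55


@pytest.fixture(scope="session")
def window():
    return Window(WINDOW_SIDE, WINDOW_SIDE)


@pytest.fixture(scope="session")
def hardcore_field():
    """One standard random hard-core array (175 cells, 10 μm core)."""
    return simulate_hardcore(SimConfig(seed=11), field_id="hc11")


@pytest.fixture(scope="session")
def csr_field(window):
    """Complete-spatial-randomness field: uniform centres, 10 μm somata."""
    rng = np.random.default_rng(42)
    xy = rng.uniform(0, WINDOW_SIDE, (175, 2))
    points = [SomaPoint(f"p{i:03d}", x, y) for i, (x, y) in enumerate(xy)]
    return SomaField(window, points, field_id="csr42")


def interior_ids(field, margin_um=35.0):
    """Reference somata at least one arbor radius away from the window border."""
    w = field.window
    return [
        p.id
        for p in field.points
        if margin_um < p.x_um < w.width_um - margin_um
        and margin_um < p.y_um < w.height_um - margin_um
    ]
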