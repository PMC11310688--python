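import numpy as np
import pytest

import cargokin as ck


@pytest.fixture
def circle_geom() -> ck.CellGeometry:
    """20 µm circular cell centred at (20, 20) µm."""
    return ck.circular_cell(20.0, center=(20.0, 20.0))


@pytest.fixture
def clean_render() -> ck.RenderParams:
    """Noiseless imaging model at 0.1 µm/px."""
    return ck.RenderParams(
        pixel_size=0.1, psf_sigma=0.15, amplitude=1000.0, background=100.0,
        noise_model="none",
    )


def straight_traj(tid, t, x0, y0, vx=0.0, vy=0.0):
    t = np.asarray(t, dtype=float)
    return ck.Trajectory(tid, t, x0 + vx * t, y0 + vy * t)
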