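import math

import numpy as np
import pytest

from septasm import (
    Filament,
    FilamentSet,
    KernelParams,
    SigmoidParams,
    SimulationConfig,
)
from septasm.synthetic_data import FilamentSpec, SceneSpec, render_topograph

#: published best-fit kernel parameters (high-salt / low-pH condition)
ALPHA_STAR = 5.6
KP_HIGH = 1.8e-5
KP_LOW = 9.1e-7


@pytest.fixture
def best_fit_params():
    return KernelParams(k_p=KP_HIGH, alpha=ALPHA_STAR)


@pytest.fixture
def standard_sigmoid():
    return SigmoidParams(a=0.9, b=0.1, c=60.0)


@pytest.fixture
def standard_config():
    return SimulationConfig(dt=1.0, j_max=12, t_end=300.0)


def straight_filament(x0, y0, x1, y1, n=50):
    """Geometric filament for pairing tests (no image behind it)."""
    pts = np.column_stack([np.linspace(x0, x1, n), np.linspace(y0, y1, n)])
    return Filament(
        points=pts,
        length=math.hypot(x1 - x0, y1 - y0),
        orientation=math.degrees(math.atan2(y1 - y0, x1 - x0)) % 180.0,
    )


def single_filament_scene(angle_deg=0.0, length=320.0, psf=0.0, noise=0.0,
                          size=(256, 512), start=(60.0, 120.0), width=6.0):
    u = (math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg)))
    fil = FilamentSpec(
        p0=start, p1=(start[0] + length * u[0], start[1] + length * u[1]),
        width=width,
    )
    spec = SceneSpec(size_px=size, filaments=[fil], psf_sigma=psf,
                     noise_sigma=noise, seed=0)
    return render_topograph(spec)
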