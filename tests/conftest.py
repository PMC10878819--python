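import numpy as np
import pytest

import cbcontrol as c


@pytest.fixture(scope="session", autouse=True)
def warm_kernels():
    """Trigger numba compilation once, on a tiny world."""
    cfg = c.AbmConfig(N=4, N_l=4, T_max=10, record_stride=5)
    c.run(cfg, 0)


@pytest.fixture
def small_cfg():
    """A fast ABM configuration for structural tests."""
    return c.AbmConfig(N_l=100, T_max=30_000, record_stride=500)


@pytest.fixture
def std_params():
    """Reference ODE parameters at the simulation-estimated operating point."""
    return c.ModelParams(r_i=0.01, r_o=0.45, q=0.1, p0=0.02)


def random_params(rng, n, include_near_boundary=True):
    """Sample valid ODE parameter sets, some deliberately near alpha = 0."""
    out = []
    for i in range(n):
        r_o = float(rng.uniform(0.05, 1.0))
        if include_near_boundary and i % 10 == 0:
            q = min(0.999, c.q_threshold(r_o) + float(rng.uniform(-1e-3, 1e-3)))
            q = max(0.0, q)
        else:
            q = float(rng.uniform(0.0, 0.95))
        out.append(c.ModelParams(
            r_i=float(10 ** rng.uniform(-3, -1)),
            r_o=r_o,
            q=q,
            p0=float(rng.uniform(1e-3, 1.0)),
        ))
    return out
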