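import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import telediff as td

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# Reference (fitted) transport parameters of the hydrogel phantom study.
REF = td.TransportParams(D=4e-5, tau=1.0, k=1.5e-4)


@pytest.fixture(scope="session")
def ref_params():
    return REF


@pytest.fixture(scope="session")
def ic():
    return td.InitialCondition()


@pytest.fixture(scope="session")
def grid2d():
    return td.Grid(L=10.0, N=200, geometry="cartesian-2d")


@pytest.fixture(scope="session")
def gridr():
    return td.Grid(L=10.0, N=200, geometry="radial-1d")


@pytest.fixture(scope="session")
def sim2d_solution(ic, grid2d):
    """2-D solve at the reference parameters, 600 s at 1 s cadence."""
    cfg = td.SolverConfig(save_times=np.arange(0.0, 601.0, 1.0), store_fields=False)
    return td.solve(REF, ic, grid2d, cfg)


@pytest.fixture(scope="session")
def sim2d_trace(sim2d_solution):
    return sim2d_solution.trace.normalized()


@pytest.fixture(scope="session")
def noiseless_obs(ic):
    """Noiseless normed central trace, 0.5 s sampling over 600 s."""
    return td.synth_center_trace(REF, ic, sampling_dt=0.5, duration=600.0)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_obs):
    return td.fit_params(noiseless_obs)


@pytest.fixture(scope="session")
def noisy_fit(ic):
    obs = td.synth_center_trace(
        REF, ic, sampling_dt=0.5, duration=600.0, noise_sigma=0.005, seed=7
    )
    return td.fit_params(obs)


@pytest.fixture(scope="session")
def stack_bundle(ic):
    """Synthetic 8-bit stack (sigma = 1 level) with its ground truth and quantification."""
    spec = td.AcquisitionSpec(
        pixel_size=0.05, frame_shape=(200, 200), noise_sigma=1.0, seed=11
    )
    stack, gt = td.synth_image_stack(REF, ic, spec)
    quant = td.quantify(stack)
    return stack, gt, quant


@pytest.fixture(scope="session")
def stack_fit(stack_bundle):
    _stack, _gt, quant = stack_bundle
    cfg = td.FitConfig(averaging_radius=quant.trace.averaging_radius)
    return td.fit_params(quant.trace, cfg)
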