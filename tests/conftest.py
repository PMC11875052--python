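import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cortune as c

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tp_grid():
    return c.default_twophoton_grid()


@pytest.fixture
def wf_grid():
    return c.default_widefield_grid()


@pytest.fixture(scope="session")
def low_noise_session():
    """A shared low-noise two-photon session with its ground truth.

    150 neurons from the broadband preset, faint noise and drift; used by
    the tuning, correlation, and recovery tests so the (few-second)
    synthesis cost is paid once.
    """
    grid = c.default_twophoton_grid()
    pop = c.generate_ground_truth(150, "uniform", grid, seed=2)
    noise = c.NoiseConfig(trace_sigma=0.2, drift_amplitude=0.02, seed=3)
    sess = c.synthesize_session(pop, grid, noise)
    rois = c.RoiSet(
        roi_traces=sess.roi_traces,
        neuropil_traces=sess.neuropil_traces,
        positions_um=sess.positions_um,
        cell_flags=np.ones(len(pop), dtype=bool),
        frame_rate_hz=grid.frame_rate_hz,
    )
    dff = c.preprocess_roiset(rois)
    tensor = c.unmix_trials(dff, sess.log, grid)
    tensor.is_dff = True
    return {"grid": grid, "population": pop, "session": sess, "tensor": tensor}
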