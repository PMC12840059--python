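"""Shared fixtures: small deterministic phantoms and streams."""

import numpy as np
import pytest

from panoce.phantom import (AcquisitionSpec, BackgroundLaw, PhantomSpec,
                            StiffnessField, default_acquisition,
                            make_stiffness_field, simulate_frame_stream)


@pytest.fixture(scope="session")
def two_layer_field() -> StiffnessField:
    """100 kPa silicone over 50 kPa tissue, boundary at row 75."""
    vals = np.full((500, 400), 100.0)
    vals[75:] = 50.0
    return StiffnessField(vals, (4.0, 10.0), 75)


@pytest.fixture(scope="session")
def two_layer_stream(two_layer_field):
    acq = default_acquisition(two_layer_field, phase_noise_sd_rad=0.0,
                              speckle=False)
    return simulate_frame_stream(two_layer_field, acq, seed=1)


@pytest.fixture(scope="session")
def homogeneous_field() -> StiffnessField:
    """Degenerate phantom: tissue stiffness equal to the 100 kPa silicone."""
    spec = PhantomSpec("custom",
                       BackgroundLaw("lognormal", np.log(100.0), 0.0),
                       rng_seed=1)
    return make_stiffness_field(spec)


@pytest.fixture(scope="session")
def homogeneous_stream(homogeneous_field):
    acq = default_acquisition(homogeneous_field, phase_noise_sd_rad=0.0,
                              speckle=False)
    return simulate_frame_stream(homogeneous_field, acq, seed=1)
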