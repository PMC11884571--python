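import numpy as np
import pytest

from stretchfield import synthgen


@pytest.fixture(scope="session")
def speckle_512():
    """Medium speckle image, fixed seed, reused across correlation tests."""
    return synthgen.generate_speckle(
        synthgen.SpeckleSpec(image_size=(512, 512), seed=7)
    )


@pytest.fixture(scope="session")
def monolayer_static():
    """Static monolayer (no drift, constant amplitude, all relaxed)."""
    spec = synthgen.MonolayerSpec(n_cells=40, image_size=(384, 384), seed=11)
    schedule = synthgen.ActuationSchedule(
        [synthgen.ActuationFrame(120.0 * k, "relaxed") for k in range(4)]
    )
    return synthgen.generate_monolayer_sequence(spec, schedule)
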