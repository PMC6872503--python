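import numpy as np
import pytest

import neurocausal as nc


class FunctionPredictor:
    """Stand-in classifier driven by an arbitrary volume -> probability map."""

    def __init__(self, fn):
        self.fn = fn

    def predict_disease_probability(self, volumes):
        volumes = np.asarray(volumes, dtype=np.float64)
        if volumes.ndim == 3:
            volumes = volumes[None]
        return np.array([self.fn(v) for v in volumes])

    def predict_proba(self, volumes):
        p = self.predict_disease_probability(volumes)
        return np.column_stack([1 - p, p])


@pytest.fixture
def function_predictor():
    return FunctionPredictor


@pytest.fixture(scope="session")
def strong_cohort_16():
    """Separable 16^3 cohort with one planted box; shared across tests."""
    spec = nc.ImageCohortSpec(grid_shape=(16, 16, 16), n_cases=15, n_controls=15,
                              signal_regions=(((4, 11), (4, 11), (4, 11)),),
                              effect_size=5.0, noise_sd=1.0,
                              smoothness_sigma=1.0, seed=7)
    return spec, *nc.generate_image_cohort(spec)


@pytest.fixture(scope="session")
def tiny_arch():
    """Small conv schedule that fits 12^3-16^3 grids and trains in seconds."""
    return nc.ArchitectureConfig(conv_specs=((5, 2, 2, 6), (3, 1, 1, 8)),
                                 n_maxpool=2)
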