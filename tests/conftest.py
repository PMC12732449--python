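import warnings

import numpy as np
import pytest

import hhgm_quant as hq

# segmentation emits benign contract warnings (empty layers etc.) that are
# asserted explicitly where relevant
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_culture():
    """A modest two-channel culture with truth, shared across tests."""
    stack, truth = hq.generate_culture(
        seed=2,
        shape=(12, 256, 256),
        fiber_kwargs={"n_fibers": 60, "rotation_rate_deg_per_um": 0.25},
        cell_kwargs={"n_cells": 14, "a_range": (8.0, 12.0)},
    )
    return stack, truth


@pytest.fixture(scope="session")
def noiseless_cells():
    """20 isolated noiseless cell shells with truth."""
    stack, truth = hq.generate_cells(
        seed=5, shape=(12, 512, 512), n_cells=20, noise=False, background=0.0,
    )
    return stack, truth


@pytest.fixture(scope="session")
def fiber_stack():
    """Default-SNR fiber stack with truth."""
    return hq.generate_fibers(seed=3, shape=(6, 256, 256), n_fibers=18,
                              theta_spread_deg=25.0,
                              rotation_rate_deg_per_um=0.0)


def modal_theta(field):
    """Mode of the valid θ values at 1° resolution."""
    th = field.theta_deg[field.valid]
    hist, edges = np.histogram(th, bins=180, range=(0, 180))
    return edges[np.argmax(hist)] + 0.5
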