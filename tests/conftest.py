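"""Shared fixtures.

The expensive artifacts — the simulation campaign, the trained surrogate,
the synthetic-twin target and its calibration — are session-scoped and
shared between the integration and acceptance tests; everything else
builds small objects locally.
"""

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles

from cardiotwin.anatomy import build_slab_mesh, slab_preset, transmural_coordinate, rule_based_fibers
from cardiotwin.blnm import BLNMConfig, train
from cardiotwin.calibrate import nelder_mead_calibrate
from cardiotwin.synthetic_twin import generate_dataset, surrogate_virtual_patient

CAMPAIGN_SEED = 1234
# fixed interior ground truth for recovery/coverage studies
THETA_TRUE_NORM = np.array([0.25, -0.30, 0.10, 0.40, -0.20, 0.15, -0.35])


@pytest.fixture(scope="session")
def campaign():
    """Default 40-simulation LHS campaign on the slab preset."""
    return generate_dataset(n_sims=40, seed=CAMPAIGN_SEED)


@pytest.fixture(scope="session")
def surrogate(campaign):
    """BLNM trained on the campaign's training split."""
    cfg = BLNMConfig(n_layers=4, n_neurons=16, n_states=10, disentanglement=1)
    return train(cfg, campaign, max_iters=3000, seed=0)


@pytest.fixture(scope="session")
def twin_target(surrogate, campaign):
    """Noisy synthetic-twin target generated by the surrogate at known
    ground truth (noise sd 0.1, nondimensional)."""
    return surrogate_virtual_patient(surrogate, campaign, THETA_TRUE_NORM,
                                     noise_sd=0.1, noise_seed=77)


@pytest.fixture(scope="session")
def calibration(surrogate, campaign, twin_target):
    """Multi-start Nelder-Mead estimate against the noisy twin target."""
    return nelder_mead_calibrate(surrogate, campaign, twin_target.ecg_noisy,
                                 n_trials=30, seed=5)


@pytest.fixture(scope="session")
def small_slab():
    return build_slab_mesh(10.0, 10.0, 4.0, 2.0)


@pytest.fixture(scope="session")
def small_anatomy():
    """Coarse slab anatomy for structural (non-propagating) checks."""
    return slab_preset(lx=8.0, ly=8.0, lz=4.0, h=2.0)
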