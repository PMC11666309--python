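"""Shared fixtures.

The session-scoped wild type is evolved once at a reduced scale (small grid,
1 kb founder, elevated per-type rate, simplified two-Gaussian target) chosen
so that the full life cycle of the model — gene discovery, genome expansion,
streamlining to a stationary structure — completes within the session.  The
simplified target matters: it makes the adaptive plateau reachable at this
mutation supply, so the wild type is structurally stationary (like a real
wild type) and perturbation experiments measure the streamlining response
rather than residual adaptation.  Every test needing an evolved, non-trivial
genome reuses this WT.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from bitevol.chemistry import FitnessParams, build_target
from bitevol.experiment import ExperimentConfig, evolve_wild_type

#: Scaled-down target: two narrow Gaussians a handful of triangle kernels
#: can approximate well, so adaptation saturates within the WT phase.
TEST_TARGET = ((0.35, 0.35, 0.035), (0.65, 0.45, 0.04))

#: Reduced-scale study conditions used across the suite (frozen once):
#: N=64 control grid, per-type rate 5e-5 so an evolved ~1.7 kb genome draws
#: ~0.6 events per replication (the regime where robustness selection acts),
#: a 20,000-generation WT phase reaching structural stationarity, and
#: 3,000-generation perturbation runs with 5 replicates.
TEST_WT_CONFIG = ExperimentConfig(
    n=64,
    mu=5e-5,
    founder_length=1_000,
    wt_generations=20_000,
    generations=3_000,
    coalescence_margin=300,
    sample_every=1_000,
    robustness_every=10**9,
    robustness_offspring=200,
    replicates=5,
    seed=42,
    target_gaussians=TEST_TARGET,
)


@pytest.fixture(scope="session")
def default_target():
    return build_target()


@pytest.fixture(scope="session")
def default_params():
    return FitnessParams()


@pytest.fixture(scope="session")
def test_wt():
    """One desk WT evolved at the reduced scale; used by the robustness
    scaling and directional-evolution tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return evolve_wild_type(TEST_WT_CONFIG)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
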