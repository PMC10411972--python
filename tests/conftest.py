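import dataclasses

import numpy as np
import pytest

from msnsim import biophysics, engine, morphology, synthetic


@pytest.fixture(scope="session")
def fixtures():
    """Canonical morphologies with known analytic properties."""
    return synthetic.fixture_morphologies()


@pytest.fixture(scope="session")
def wt_spec():
    return biophysics.default_model_spec("wt")


@pytest.fixture(scope="session")
def passive_spec(wt_spec):
    """The wild-type model stripped of voltage-gated channels."""
    return dataclasses.replace(wt_spec, channels=())


@pytest.fixture(scope="session")
def passive_sphere(fixtures, passive_spec):
    """Single spherical compartment with leak only."""
    return engine.discretize(fixtures["sphere"], passive_spec, 10.0)


@pytest.fixture(scope="session")
def wt_morphology():
    return morphology.synthesize_morphology(morphology.morphogen_preset("wt"), 1)


@pytest.fixture(scope="session")
def wt_model(wt_morphology, wt_spec):
    """Active wild-type model used across calibration tests."""
    return engine.discretize(wt_morphology, wt_spec, 20.0)


def random_tree(seed: int, n_primary=3, depth=2) -> morphology.Morphology:
    """Small random dendritic tree for oracle comparisons."""
    params = morphology.MorphogenParams(
        n_primary=n_primary,
        mean_branch_length_um=40.0,
        branch_length_sd_um=12.0,
        branching_prob=0.6,
        max_depth=depth,
        target_total_length_um=1.0,
        target_tolerance=1e9,  # no length constraint for oracle trees
        node_step_um=8.0,
    )
    return morphology.synthesize_morphology(params, seed)
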