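"""Shared fixtures.

The heavy objects (phantom anatomy, the full pipeline run on every noise
seed) are session-scoped so the accuracy and direction-of-effect checks
share one computation.
"""

import dataclasses

import numpy as np
import pytest

import cerebseg as cs
from cerebseg.phantom import make_atlas

N_NOISE_SEEDS = 10
NOISE_SIGMA = 5.0


@pytest.fixture(scope="session")
def default_phantom():
    """Noiseless, bias-free 128^3 phantom (seed 42)."""
    return cs.generate_phantom(cs.PhantomConfig(seed=42))


@pytest.fixture(scope="session")
def phantom_atlas(default_phantom):
    return make_atlas(default_phantom)


@pytest.fixture(scope="session")
def small_phantom():
    """64^3 phantom for cheap unit tests."""
    return cs.generate_phantom(cs.PhantomConfig(grid_shape=64, seed=7))


@pytest.fixture(scope="session")
def noiseless_result(default_phantom, phantom_atlas):
    case = default_phantom
    return cs.segment_cerebellum(case.t1, case.brain_mask(),
                                 case.cerebral_mask(), phantom_atlas,
                                 cs.PipelineConfig(seed=42))


@pytest.fixture(scope="session")
def multiseed_reports(default_phantom, phantom_atlas):
    """Per-seed EvalReports with and without brain-stem removal.

    Ten noisy phantoms (sigma 5) sharing the default anatomy; returns a
    list of dicts with 'before' and 'after' reports against the
    ground-truth cerebellum.
    """
    truth = default_phantom.cerebellum_mask()
    cfg = cs.PipelineConfig(seed=42)
    cfg_off = dataclasses.replace(cfg, remove_brainstem=False)
    rows = []
    for seed in range(N_NOISE_SEEDS):
        case = cs.generate_phantom(
            cs.PhantomConfig(noise_sigma=NOISE_SIGMA, seed=seed))
        after = cs.segment_cerebellum(case.t1, case.brain_mask(),
                                      case.cerebral_mask(), phantom_atlas, cfg)
        before = cs.segment_cerebellum(case.t1, case.brain_mask(),
                                       case.cerebral_mask(), None, cfg_off)
        rows.append({"seed": seed,
                     "after": cs.evaluate(truth, after.final),
                     "before": cs.evaluate(truth, before.final)})
    return rows


@pytest.fixture()
def rng():
    return np.random.default_rng(20150428)


def random_mask(rng, shape=(16, 16, 16), density=0.5):
    return rng.random(shape) < density
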