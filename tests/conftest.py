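"""Shared fixtures: synthetic bundles and pipeline runs (session-scoped)."""

import numpy as np
import pytest

from diffarch.genome import BinTable
from diffarch.matrix import ContactMatrix
from diffarch.pipeline import RunConfig, run_pipeline
from diffarch.simulate import GeneratorConfig, generate


@pytest.fixture(scope="session")
def default_bundle():
    """Default two-condition synthetic genome (2 x 20 Mb, seed 1)."""
    return generate(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_bundle):
    """Full pipeline run on the default genome, with recovery report."""
    bundle, truth = default_bundle
    return run_pipeline(bundle, RunConfig(seed=1), truth=truth)


@pytest.fixture(scope="session")
def splits_only_result():
    """Pipeline run where condition 2 splits every eligible TAD, merges none."""
    cfg = GeneratorConfig(seed=1, n_tad_splits=-1, n_tad_merges=0)
    bundle, truth = generate(cfg)
    return run_pipeline(bundle, RunConfig(seed=1), truth=truth), truth


def make_null_matrix(seed: int, n: int = 1500, resolution: int = 10_000,
                     scale: float = 1200.0, alpha: float = 1.0) -> ContactMatrix:
    """Distance decay + Poisson noise only: the loop caller's null model."""
    rng = np.random.default_rng(seed)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    mu = scale * (d + 1.0) ** (-alpha)
    c = rng.poisson(np.triu(mu)).astype(float)
    c = np.triu(c) + np.triu(c, 1).T
    return ContactMatrix(BinTable("chrN", n * resolution, resolution), c)
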