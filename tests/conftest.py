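"""Shared fixtures: small synthetic studies and one full default-scale run.

The default-configuration pipeline run is session-scoped because several
end-to-end checks (planted-hairpin recovery, overhang statistics, gap-locus
reporting) interrogate the same run.
"""

from __future__ import annotations

import numpy as np
import pytest

from spongemir.config import PipelineConfig, SimConfig
from spongemir.pipeline import run_pipeline
from spongemir.simdata import generate_genome, plant_hairpins, simulate_study

#: seed of the reference simulation used by the end-to-end checks
DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default simulated study (21 hairpins, 1 gapped)."""
    cfg = PipelineConfig(seed=DEFAULT_SEED)
    return cfg, run_pipeline(cfg)


@pytest.fixture(scope="session")
def decoy_only_run():
    """Same-size genome with no planted hairpins: background only."""
    cfg = PipelineConfig(seed=DEFAULT_SEED)
    cfg.sim.n_hairpins = 0
    cfg.sim.n_gap_hairpins = 0
    return cfg, run_pipeline(cfg)


@pytest.fixture()
def small_sim():
    """A small, fast study: 1 x 8 kb scaffold, 4 hairpins, light background."""
    cfg = SimConfig(seed=7, n_scaffolds=1, scaffold_lengths=[8000],
                    n_hairpins=4, n_gap_hairpins=0, background_reads=500)
    genome, truth, decoys, reads = simulate_study(cfg)
    return cfg, genome, truth, decoys, reads


@pytest.fixture()
def planted_genome():
    cfg = SimConfig(seed=3, n_scaffolds=2, scaffold_lengths=[6000, 6000],
                    n_hairpins=5, n_gap_hairpins=1, background_reads=0)
    genome, truth = plant_hairpins(generate_genome(cfg), cfg)
    return cfg, genome, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20160212)
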