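"""Shared fixtures: a small simulated two-sample bundle plus its
on-disk form. Everything is generated at test time from fixed seeds."""
from __future__ import annotations

import pytest

from vircon.simulate import SimulationConfig, SimBundle, simulate_bundle, write_bundle

SMALL_CONFIG = dict(
    seed=7,
    n_chroms=3,
    chrom_length=600_000,
    n_genes_per_chrom=25,
    n_planted_blocks=6,
    n_candidate_genes=8,
    n_decoy_genes=10,
    n_effect_per_class=2,
)


@pytest.fixture(scope="session")
def small_bundle() -> SimBundle:
    return simulate_bundle(SimulationConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def bundle_paths(small_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return write_bundle(small_bundle, outdir)
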