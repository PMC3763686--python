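import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from legsyn.benchmark import run_synthetic_pipeline
from legsyn.synthetic_data import SimConfig


@pytest.fixture(scope="session")
def default_pipeline():
    """Full search->assign->map->synteny run on the default synthetic genome
    pair (shared across tests; the run takes tens of seconds)."""
    return run_synthetic_pipeline(SimConfig())


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale simulation for fast end-to-end and CLI tests."""
    return SimConfig(
        seed=5,
        n_chrom_a=1,
        genes_per_chrom=10,
        markers_per_chrom=8,
        chrom_len=300_000,
        inversions_per_chrom=0.0,
        fractionation_loss=0.0,
        tandem_families=[(3, 6000)],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
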