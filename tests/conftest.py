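import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from crefkit.synthetic import (
    gen_cref,
    make_planted_model,
    random_pwm_library,
)


@pytest.fixture(scope="session")
def pwm_lib():
    """Six sharp random PWMs with the default threshold profiles."""
    return random_pwm_library(n_motifs=6, length=15, seed=1)


@pytest.fixture(scope="session")
def planted_sim():
    """A clean (noise-free, uncorrupted) planted count matrix."""
    model = make_planted_model(
        n_genes=300, n_motifs=120, n_levels=5,
        gene_block=60, motif_block=24, depth=50, seed=11,
    )
    return gen_cref(model)


@pytest.fixture(scope="session")
def corrupted_sim():
    """The planted matrix with 2% sparse corruption, no count noise."""
    model = make_planted_model(
        n_genes=300, n_motifs=120, n_levels=5,
        gene_block=60, motif_block=24, depth=50,
        corruption_fraction=0.02, seed=12,
    )
    return gen_cref(model)
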