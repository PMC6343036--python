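import numpy as np
import pytest

from hrscan.alignio import AlignmentBlock
from hrscan.simdata import SimConfig, evolve_alignment


@pytest.fixture
def tiny_block():
    """Hand-built 4-strain block with one obvious mosaic child."""
    seqs = {
        "childR": "AAAACCCCGGGG",
        "parentA": "AAAATTTTGGGG",
        "parentB": "TTTTCCCCAAAA",
        "out": "AAAACCCCGGGG",
    }
    ids = list(seqs)
    return AlignmentBlock.from_strings(ids, [seqs[s] for s in ids])


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded simulation shared by read-only tests."""
    cfg = SimConfig(n_strains=6, genome_length=20_000, event_rate=0.6, seed=42)
    block, truth = evolve_alignment(cfg)
    return cfg, block, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
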