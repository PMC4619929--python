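import numpy as np
import pytest

from ppcm.gold_standard import ProteinPair
from ppcm.phylo_profiles import PhyloProfileMatrix
from ppcm.synthetic import SyntheticConfig, generate_bundle


@pytest.fixture
def toy_matrix() -> PhyloProfileMatrix:
    """Six proteins over ten taxa with hand-readable rows."""
    rows = {
        "pA": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
        "pB": [1, 0, 1, 0, 1, 0, 1, 0, 1, 0],
        "pC": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],  # identical to pA
        "pD": [0, 0, 0, 0, 0, 1, 1, 1, 1, 1],  # complement of pA
        "pE": [1, 1, 1, 1, 1, 1, 1, 1, 1, 1],  # constant one
        "pF": [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],  # constant zero
    }
    return PhyloProfileMatrix(
        proteins=list(rows),
        taxa=[f"t{i}" for i in range(10)],
        presence=np.array(list(rows.values()), dtype=np.uint8),
    )


@pytest.fixture
def pair_ab() -> ProteinPair:
    return ProteinPair("pA", "pB")


TINY_CONFIG = SyntheticConfig(
    n_proteins=60,
    n_taxa=16,
    n_positive_pairs=12,
    ratio=3,
    coevolution_strength=0.6,
    go_sharing_strength=0.7,
    n_terms_per_aspect=30,
    seed=11,
)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small multi-species bundle shared by integration-style tests."""
    return generate_bundle(TINY_CONFIG)


@pytest.fixture(scope="session")
def tiny_config():
    return TINY_CONFIG
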