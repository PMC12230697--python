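import numpy as np
import pytest

from asoforge.chemistry import FragmentLibrary
from asoforge.egt import EGTConfig
from asoforge.patterns import DNA, PS, ModificationPattern
from asoforge.sequences import AsoSequence, validate_sequence


@pytest.fixture(scope="session")
def library() -> FragmentLibrary:
    return FragmentLibrary.default()


@pytest.fixture(scope="session")
def hif1a() -> AsoSequence:
    return validate_sequence("GTTACTGCCTTCTTAC")


@pytest.fixture(scope="session")
def tiny_config() -> EGTConfig:
    # smallest config that still exercises multi-head attention
    return EGTConfig(num_layers=1, num_heads=2, node_dim=8, edge_dim=4, seed=0)


def all_dna_pattern(length: int, chem: str = "LNA") -> ModificationPattern:
    return ModificationPattern(
        sugar=(DNA,) * length, linkage=(PS,) * (length - 1), modification_type=chem
    )


def pattern_from_bits(bits, chem: str) -> ModificationPattern:
    sugar = tuple(chem if b else DNA for b in bits)
    return ModificationPattern(
        sugar=sugar, linkage=(PS,) * (len(bits) - 1), modification_type=chem
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
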