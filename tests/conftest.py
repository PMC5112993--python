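import numpy as np
import pytest

from funcascade import (
    Dataset,
    FunctionScheme,
    load_property_tables,
)


@pytest.fixture(scope="session")
def tables():
    """The five packaged property scales."""
    return load_property_tables()


@pytest.fixture(scope="session")
def polarity(tables):
    return tables[0]


@pytest.fixture
def scheme4():
    return FunctionScheme.generic(4)


@pytest.fixture
def cascade_dataset(scheme4):
    """Five proteins with hand-enumerable evidence for every cascade branch.

    p1/p2 are homologues (mutual hits), p3 interacts with p2, p4/p5 are
    orphan twins reachable only through PseAAC (identical homopolymer
    sequences, orthogonal in PseAAC space to everything else).
    """
    return Dataset(
        sequences={
            "p1": "CCCC",
            "p2": "CCCC",
            "p3": "CCCC",
            "p4": "AAAA",
            "p5": "AAAA",
        },
        annotations={
            "p1": frozenset({1}),
            "p2": frozenset({1, 2}),
            "p3": frozenset({2}),
            "p4": frozenset({3}),
            "p5": frozenset({3}),
        },
        similarity_hits=[("p1", "p2", 10.0), ("p2", "p1", 10.0)],
        interaction_edges=[("p3", "p2", 5.0)],
    )


def random_sequence(rng: np.random.Generator, min_len=2, max_len=30) -> str:
    from funcascade import AMINO_ACIDS

    length = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
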