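"""Shared toy systems for the test suite.

All fixtures are generated in memory; nothing is read from disk.
"""

import numpy as np
import pytest

from chimeraopt import BlockPartition, ContactMap, ParentSet


@pytest.fixture
def toy_parents():
    """Three parents, 12 aligned columns, AHR = [0, 4), two ATR blocks.

    Block 1 = columns [4, 8), block 2 = columns [8, 12).  Block 2 is
    identical between A and B, so the distinct space is 2 x 3 = 6 with a
    fixed AHR.
    """
    parents = ParentSet(
        names=("A", "B", "T"),
        sequences=(
            "MKLVAADDKKRR",
            "MKIVAAEEKKRR",
            "MKLVGGDDQQRR",
        ),
        domain_split=4,
    )
    partition = BlockPartition(breakpoints=(8,), domain_split=4)
    return parents, partition


@pytest.fixture
def toy_contacts(toy_parents):
    """Hand-placed contacts over the 12-column toy alignment."""
    parents, _ = toy_parents
    contacts = (
        (2, 6, 1.0),   # AHR-ATR
        (4, 9, 0.8),   # block1-block2
        (5, 7, 1.0),   # within block1
        (6, 10, 0.5),  # block1-block2
        (8, 11, 1.0),  # within block2
    )
    return ContactMap(contacts, cutoff_angstrom=4.5, n_models=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_toy_system(rng, n_parents=3, n_ahr=3, block_lens=(3, 3, 3), alphabet="ACDEFGHIK"):
    """A small random parent set + partition + contact map for oracle tests."""
    letters = list(alphabet)
    L = n_ahr + sum(block_lens)
    cols = rng.choice(letters, size=(n_parents, L))
    names = tuple("ABT"[:n_parents])
    split = n_ahr
    edges = [split]
    for b in block_lens:
        edges.append(edges[-1] + b)
    parents = ParentSet(names, tuple("".join(r) for r in cols), split)
    partition = BlockPartition(tuple(edges[1:-1]), split)
    n_contacts = max(3, L)
    pairs = set()
    while len(pairs) < n_contacts:
        i, j = sorted(rng.choice(L, size=2, replace=False))
        if j - i >= 2:
            pairs.add((int(i), int(j)))
    contacts = tuple((i, j, float(rng.integers(1, 6)) / 5.0) for i, j in sorted(pairs))
    cmap = ContactMap(contacts, 4.5, 5)
    return parents, partition, cmap
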