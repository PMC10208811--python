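import dendropy
import numpy as np
import pytest

from bmrscale import SpeciesRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True,
                             rooting="default-rooted")


@pytest.fixture
def three_tip_tree():
    # hand-worked covariance: diag (2,2,2), cov(A,B)=1, cov(A,C)=cov(B,C)=0
    return tree_from_newick("((A:1,B:1):1,C:2);")


def make_records(group: str, x: np.ndarray, y: np.ndarray, prefix: str = "sp"):
    """Species records whose log10 mass/BMR equal the given vectors."""
    return [
        SpeciesRecord(f"{prefix}_{group}_{i}", group, 10.0 ** xi, 10.0 ** yi)
        for i, (xi, yi) in enumerate(zip(x, y))
    ]


@pytest.fixture
def two_group_records(rng):
    """Two clades sharing slope 0.72 with intercepts 0.4 apart, mild noise."""
    records = []
    for group, a in (("Alpha", 0.5), ("Beta", 0.9)):
        x = rng.uniform(0.5, 4.0, 40)
        y = a + 0.72 * x + rng.normal(0, 0.05, 40)
        records += make_records(group, x, y)
    return records
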