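import numpy as np
import pytest

from cellphylo import build_study_fixture, sample_tree_set
from cellphylo.trees import parse_newick


@pytest.fixture(scope="session")
def fixture():
    return build_study_fixture()


@pytest.fixture(scope="session")
def tree_sample_small(fixture):
    """200 calibration-consistent chronograms for quick integration tests."""
    return sample_tree_set(fixture.topology, fixture.calibrations, 200, seed=101)


@pytest.fixture(scope="session")
def chronogram_one(fixture):
    """A single fixture chronogram (branch lengths in Ma)."""
    return sample_tree_set(fixture.topology, fixture.calibrations, 1, seed=7)[0]


@pytest.fixture()
def tree3():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture()
def tree5():
    return parse_newick("(((A:0.3,B:0.5):0.4,(C:0.2,D:0.7):0.3):0.2,E:1.1);")


def random_tree_newick(rng, n_tips: int) -> str:
    """Random rooted binary tree with uniform branch lengths in (0.05, 1)."""
    nodes = [f"T{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la, lb = rng.uniform(0.05, 1.0, 2)
        nodes.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return nodes[0] + ";"
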