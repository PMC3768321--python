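import numpy as np
import pytest

from morphorates.io_core import CharacterMatrix, tree_from_newick
from morphorates.synthetic import SimulationConfig, simulate_study


def make_matrix(labels, rows, **kwargs):
    """Build a CharacterMatrix from int / set / None cell shorthand."""
    cells = []
    for row in rows:
        cells.append(
            [
                None
                if s is None
                else (frozenset(s) if isinstance(s, (set, frozenset, tuple)) else frozenset([s]))
                for s in row
            ]
        )
    return CharacterMatrix(list(labels), cells, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def balanced_quartet():
    """((A,B),(C,D)) with unit branch durations."""
    return tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def small_study():
    """A 25-taxon synthetic study bundle shared across tests."""
    return simulate_study(SimulationConfig(n_taxa=25, n_characters=60, seed=42))
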