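import numpy as np
import pytest

from oatol.pedigree import Pedigree
from oatol.simulate import DesignSpec, default_truth, generate_breeding_design


@pytest.fixture(scope="session")
def trio_pedigree() -> Pedigree:
    """Sire, dam and one offspring."""
    return Pedigree(["s", "d", "o"], [None, None, "s"], [None, None, "d"])


@pytest.fixture(scope="session")
def sib_pedigree() -> Pedigree:
    """Two founder pairs: full sibs, paternal half sib, unrelated."""
    return Pedigree(
        ["s", "d", "d2", "s3", "d3", "o1", "o2", "h", "u"],
        [None, None, None, None, None, "s", "s", "s", "s3"],
        [None, None, None, None, None, "d", "d", "d2", "d3"],
    )


@pytest.fixture(scope="session")
def two_set_design():
    """One block with two 3x3 factorial sets: the 18-family design."""
    spec = DesignSpec(n_blocks=1, sets_per_block=2, seed=5)
    ped, tanks = generate_breeding_design(spec)
    return spec, ped, tanks


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated experiment (4 blocks)."""
    from oatol.simulate import simulate_study

    return simulate_study(DesignSpec(n_blocks=4, seed=11), default_truth())
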