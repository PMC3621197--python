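import numpy as np
import pandas as pd
import pytest

from arsenicqtl.pedigree import build_pedigree


@pytest.fixture
def trio():
    """Father, mother, one child."""
    return build_pedigree(["dad", "mom", "kid"], ["0", "0", "dad"],
                          ["0", "0", "mom"], [1, 2, 2])


@pytest.fixture
def nuclear():
    """Two parents, three offspring."""
    return build_pedigree(
        ["f", "m", "c1", "c2", "c3"],
        ["0", "0", "f", "f", "f"],
        ["0", "0", "m", "m", "m"],
        [1, 2, 1, 2, 1],
        household=["H1"] * 5,
    )


@pytest.fixture
def three_gen():
    """Founder couple, two sibs with married-in spouses, one grandchild each:
    contains parent-offspring, sibling, avuncular and first-cousin pairs."""
    return build_pedigree(
        ids=["f", "m", "c1", "c2", "s1", "s2", "g1", "g2"],
        father=["0", "0", "f", "f", "0", "0", "c1", "s2"],
        mother=["0", "0", "m", "m", "0", "0", "s1", "c2"],
        sex=[1, 2, 1, 2, 2, 1, 1, 2],
    )


@pytest.fixture
def half_sib_ped():
    """One father, two mothers, one child by each."""
    return build_pedigree(
        ["f", "m1", "m2", "k1", "k2"],
        ["0", "0", "0", "f", "f"],
        ["0", "0", "0", "m1", "m2"],
        [1, 2, 2, 1, 2],
    )


@pytest.fixture
def species_records():
    """Ten records with two below the MMA detection limit."""
    rng = np.random.default_rng(42)
    n = 10
    df = pd.DataFrame({
        "iAs": rng.uniform(0.5, 5.0, n),
        "MMA": rng.uniform(0.5, 8.0, n),
        "DMA": rng.uniform(5.0, 40.0, n),
    }, index=[f"I{k}" for k in range(n)])
    df.loc["I3", "MMA"] = 0.05
    df.loc["I7", "MMA"] = 0.02
    return df
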