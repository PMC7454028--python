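import numpy as np
import pandas as pd
import pytest

from temporal_demes import GroupedGenotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def toy_two_groups():
    """2 groups x 4 individuals x 1 locus — small enough to enumerate by hand."""
    pairs = [
        [(1, 1)], [(1, 2)], [(2, 2)], [(1, 2)],
        [(1, 1)], [(1, 1)], [(1, 2)], [(2, 2)],
    ]
    return GroupedGenotypes.from_pairs(
        pairs, labels={"deme": ["A"] * 4 + ["B"] * 4}
    )


@pytest.fixture
def microsat_table():
    """Two sites x two stages, three microsatellite loci, one missing call."""
    rng = np.random.default_rng(7)
    n = 24
    calls = np.empty((n, 3, 2), dtype=np.int64)
    for l, alleles in enumerate([(100, 102, 104), (150, 154), (200, 202, 208, 210)]):
        calls[:, l, :] = rng.choice(alleles, size=(n, 2))
    calls[3, 1] = (-1, -1)
    labels = pd.DataFrame(
        {
            "site": ["Em01"] * 12 + ["Em08"] * 12,
            "stage": (["veg"] * 6 + ["rep"] * 6) * 2,
        },
        index=[f"i{k}" for k in range(n)],
    )
    return GroupedGenotypes(calls, ["msA", "msB", "msC"], labels)
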