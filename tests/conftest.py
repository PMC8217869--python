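import numpy as np
import pytest

from assemblage import CountTable, GroupDesign


@pytest.fixture
def small_table() -> CountTable:
    counts = np.array([
        [5, 0, 2, 1],
        [1, 3, 0, 4],
        [1, 1, 1, 1],
        [2, 0, 0, 7],
    ])
    return CountTable([f"o{i}" for i in range(4)],
                      [f"s{j}" for j in range(4)], counts)


@pytest.fixture
def two_group_design() -> GroupDesign:
    return GroupDesign({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})


def random_table(rng: np.random.Generator, n_taxa: int = 12,
                 n_samples: int = 6, lam: float = 3.0) -> CountTable:
    counts = rng.poisson(lam, size=(n_taxa, n_samples))
    counts[0] += 1  # keep every sample non-empty
    return CountTable([f"o{i}" for i in range(n_taxa)],
                      [f"s{j}" for j in range(n_samples)], counts)
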