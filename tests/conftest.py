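import numpy as np
import pytest
from hypothesis import settings

import phylocomm as pc

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


BALANCED = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def balanced_tree():
    """The 4-tip hand tree used throughout the worked examples."""
    return pc.read_newick(BALANCED)


def random_tree_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random rooted binary tree with uniform branch lengths, built by
    coalescent-style pairwise joining — independent of the package's own
    simulators."""
    parts = [f"t{i}" for i in range(n_tips)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        la, lb = rng.uniform(0.05, 2.0, size=2)
        parts.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return parts[0] + ";"


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
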