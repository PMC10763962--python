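import numpy as np
import pytest

import lineagedist as ld


@pytest.fixture(scope="session")
def template():
    return ld.make_template(ld.DEFAULT_TEMPLATE)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_lineage():
    # well-formed 7-cell tree rooted at C with alternating cycle times
    return ld.Lineage(
        "toy",
        {"C": 10.0, "Ca": 12.0, "Cp": 14.0, "Caa": 16.0, "Cap": 18.0, "Cpa": 20.0, "Cpp": 22.0},
    )


def random_tree_pair(rng, max_depth=4, split_prob=0.7):
    """Two random normalized trees sharing no structure beyond the root."""
    return (
        ld.random_sublineage(rng, max_depth=max_depth, split_prob=split_prob),
        ld.random_sublineage(rng, max_depth=max_depth, split_prob=split_prob),
    )
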