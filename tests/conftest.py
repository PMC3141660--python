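import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BUTTERFLY_AB_CD = "((a,b),(c,d));"
BUTTERFLY_AC_BD = "((a,c),(b,d));"
STAR_4 = "(a,b,c,d);"
CATERPILLAR_5 = "(((a,b),c),(d,e));"


@pytest.fixture
def rng():
    return np.random.default_rng(20110603)


def internal_node_with_leaf_neighbors(tree, labels):
    """The internal node whose leaf neighbours carry exactly ``labels``."""
    want = set(labels)
    for v in tree.internal_nodes:
        got = {tree.labels[u] for u in tree.adj[v] if u in tree.labels}
        if got == want:
            return v
    raise AssertionError(f"no internal node with leaf neighbours {want}")
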