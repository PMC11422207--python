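import numpy as np
import pandas as pd
import pytest
from io import StringIO

from skbio import TreeNode

from ecoassembly.containers import OtuTable


@pytest.fixture
def small_tree() -> TreeNode:
    """((A:1,B:1):1,C:2); -- 3 tips, total branch length 5."""
    return TreeNode.read(StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture
def toy_table() -> OtuTable:
    """3 samples x 4 taxa with simple hand-checkable counts."""
    counts = pd.DataFrame(
        [[5, 5, 5, 5], [10, 0, 0, 0], [0, 3, 3, 4]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C", "D"],
    )
    return OtuTable(counts)


@pytest.fixture
def random_table() -> OtuTable:
    """20 samples x 50 taxa multinomial table (fixed seed)."""
    rng = np.random.default_rng(42)
    p = rng.dirichlet(np.ones(50))
    counts = rng.multinomial(1000, p, size=20)
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"S{i}" for i in range(20)],
            columns=[f"T{j}" for j in range(50)],
        )
    )
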