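import numpy as np
import pandas as pd
import pytest

from cgrm.deg import DEGTable
from cgrm.io import ExpressionSeries


@pytest.fixture
def small_expr() -> ExpressionSeries:
    """3 genes x 4 time points, strictly positive."""
    values = np.array(
        [
            [1.0, 2.0, 4.0, 8.0],
            [5.0, 5.0, 5.0, 5.0],
            [8.0, 4.0, 2.0, 1.0],
        ]
    )
    return ExpressionSeries(["G1", "G2", "G3"], [0.0, 1.0, 2.0, 3.0], values)


def all_up_degs(gene_ids) -> DEGTable:
    """DEG table marking every gene up-regulated (for recovery drivers)."""
    return DEGTable(
        pd.DataFrame(
            {
                "gene_id": list(gene_ids),
                "log2_fold_change": 1.0,
                "p_value": 0.01,
                "direction": "up",
            }
        )
    )
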