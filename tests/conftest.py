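import numpy as np
import pytest

from orthoconcord.containers import DesignTable, ExprMatrix


@pytest.fixture
def design_3v3():
    """Minimal two-group design, three replicates each."""
    return DesignTable(
        [f"s{i}" for i in range(6)],
        ["mouse"] * 6,
        ["A", "A", "A", "B", "B", "B"],
        [1, 2, 3, 1, 2, 3],
    )


@pytest.fixture
def mouse_design_12():
    """Four-group mouse design: WT/KO at 6 and 24 months, N=3 per group."""
    groups = ["WT6"] * 3 + ["KO6"] * 3 + ["WT24"] * 3 + ["KO24"] * 3
    return DesignTable(
        [f"m{i}" for i in range(12)],
        ["mouse"] * 12,
        groups,
        [1, 2, 3] * 4,
    )


def make_matrix(values, feature_prefix="f", sample_ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(p)]
    return ExprMatrix([f"{feature_prefix}{i}" for i in range(n)], list(sample_ids), values)
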