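import numpy as np
import pandas as pd
import pytest

from persister_rx.io import ExpressionMatrix


@pytest.fixture
def tiny_counts():
    """3 genes x 4 cells with known nonzeros."""
    vals = np.array(
        [
            [5, 0, 1, 0],
            [0, 2, 0, 0],
            [1, 3, 0, 4],
        ]
    )
    return ExpressionMatrix(["A", "B", "C"], ["c1", "c2", "c3", "c4"], vals, layer="counts")


@pytest.fixture
def toy_survival():
    """6-subject two-group table used for hand-checked survival statistics."""
    return pd.DataFrame(
        {
            "sample": [f"s{i}" for i in range(6)],
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 0, 1, 1, 1],
            "group": ["high", "high", "high", "rest", "rest", "rest"],
        }
    )


def mtx_text(n_rows, n_cols, entries):
    """MatrixMarket coordinate text for {(i, j): v} with 1-based indices."""
    lines = [
        "%%MatrixMarket matrix coordinate integer general",
        f"{n_rows} {n_cols} {len(entries)}",
    ]
    for (i, j), v in sorted(entries.items()):
        lines.append(f"{i} {j} {v}")
    return "\n".join(lines) + "\n"
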