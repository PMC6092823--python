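import numpy as np
import pytest

from msavar import Alignment

AA = "ACDEFGHIKLMNPQRSTVWY"


def columns_to_alignment(columns, ids=None):
    """Build an Alignment from per-column strings (row i = i-th char of
    each column)."""
    n_seq = len(columns[0])
    rows = tuple("".join(col[i] for col in columns) for i in range(n_seq))
    ids = ids or tuple(f"s{i + 1}" for i in range(n_seq))
    return Alignment(ids=tuple(ids), rows=rows)


def random_alignment(rng, n_seq, n_col, gap_prob=0.0):
    mat = rng.choice(list(AA), size=(n_seq, n_col))
    if gap_prob > 0:
        mask = rng.random((n_seq, n_col)) < gap_prob
        mat[mask] = "-"
    return Alignment(
        ids=tuple(f"s{i + 1}" for i in range(n_seq)),
        rows=tuple("".join(r) for r in mat),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def worked_alignment():
    """The three-column fixture with columns AAAA, AAA-, AACC."""
    return columns_to_alignment(["AAAA", "AAA-", "AACC"])
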