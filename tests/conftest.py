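import numpy as np
import pandas as pd
import pytest

from menkit.table_io import FeatureTable


def make_table(counts, groups=None, months=None, subjects=None):
    counts = np.asarray(counts)
    n_asv, n_samp = counts.shape
    asv_ids = [f"ASV{i}" for i in range(n_asv)]
    sample_ids = [f"S{j}" for j in range(n_samp)]
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": groups or ["A"] * n_samp,
            "month": months or [1] * n_samp,
            "subject": subjects or sample_ids,
        }
    ).set_index("sample_id")
    return FeatureTable(counts, asv_ids, sample_ids, meta)


@pytest.fixture
def toy_table():
    return make_table([[5, 0, 3], [1, 2, 0], [0, 0, 7]])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
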