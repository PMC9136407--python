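import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from assocmap.schema import CATEGORICAL, CONTINUOUS, VariableSchema
from assocmap.tables import SampleTable


@pytest.fixture
def tiny_tsv(tmp_path):
    """Minimal well-formed merged table on disk."""
    p = tmp_path / "tiny.tsv"
    p.write_text("sid\tgroup\tfA\ns1\tcase\t0.4\ns2\tctrl\t0.6\n")
    return p


@pytest.fixture
def two_group_table():
    """12 samples, one binary group + one continuous covariate, 3 features.

    feat_c has a constant proportion in every sample, so it survives the
    abundance filter but is skipped as untestable.
    """
    rng = np.random.default_rng(7)
    n = 12
    index = pd.Index([f"s{i}" for i in range(n)], name="sid")
    metadata = pd.DataFrame(
        {
            "group": ["case"] * 6 + ["ctrl"] * 6,
            "cov": rng.normal(10, 2, n),
        },
        index=index,
    )
    a = rng.uniform(1, 3, n)
    b = rng.uniform(2, 5, n)
    features = pd.DataFrame({"feat_a": a, "feat_b": b}, index=index)
    features["feat_c"] = (a + b) / 3  # constant 0.25 proportion after TSS
    return SampleTable(metadata=metadata, features=features, sample_id_col="sid")


@pytest.fixture
def two_group_schema():
    return VariableSchema(
        sample_id_col="sid",
        fixed_vars={"group": CATEGORICAL, "cov": CONTINUOUS},
        level_order={"group": ["case", "ctrl"]},
        reference={"group": "ctrl"},
    )
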