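import numpy as np
import pandas as pd
import pytest

from edufacsseq.filtering import FeatureTable


def make_feature_table(counts: dict, fractions: dict, experiment: str = "exp1") -> FeatureTable:
    """Build a FeatureTable from {sample_id: {feature: count}} and
    {sample_id: fraction}."""
    counts_df = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(np.int64)
    meta = pd.DataFrame(
        {
            "fraction": pd.Series(fractions),
            "experiment": experiment,
            "treatment": "none",
            "replicate": "r1",
        }
    )
    return FeatureTable(counts_df, meta.loc[counts_df.index])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
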