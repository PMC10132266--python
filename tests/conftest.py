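import numpy as np
import pandas as pd
import pytest

from netomicspass import FeatureTable


def make_table(values, feature_ids=None, subject_ids=None, modality=None,
               scale_state="raw"):
    """Build a FeatureTable from a 2-D array (subjects × features)."""
    values = np.asarray(values, float)
    n, p = values.shape
    feature_ids = feature_ids or [f"f{i}" for i in range(p)]
    subject_ids = subject_ids or [f"s{i}" for i in range(n)]
    if modality is None:
        modality = {f: "protein" for f in feature_ids}
    return FeatureTable(
        pd.DataFrame(values, index=subject_ids, columns=feature_ids),
        pd.Series(modality),
        scale_state=scale_state,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_raw_table():
    """4 subjects × 3 features, one missing entry, mixed modalities."""
    return make_table(
        [[1.0, 2.0, 0.5], [2.0, 4.0, -0.5], [3.0, np.nan, 1.5], [4.0, 8.0, 2.5]],
        feature_ids=["p1", "p2", "echo1"],
        modality={"p1": "protein", "p2": "protein", "echo1": "imaging"},
    )
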