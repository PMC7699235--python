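import numpy as np
import pandas as pd
import pytest

from gutnet.io import METABOLITE, OTU, FeatureTable, MergedDataset, TraitTable


def make_table(values, kinds=None, feature_ids=None, sample_ids=None):
    """Build a FeatureTable from a 2D array with sensible default ids."""
    values = np.asarray(values, dtype=float)
    n_f, n_s = values.shape
    feature_ids = feature_ids or [f"f{i}" for i in range(n_f)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_s)]
    if kinds is None:
        kinds = [OTU] * (n_f // 2) + [METABOLITE] * (n_f - n_f // 2)
    data = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    return FeatureTable(data, pd.Series(kinds, index=feature_ids))


def make_traits(n_case, n_ctrl, sample_ids=None):
    sample_ids = sample_ids or [f"s{j}" for j in range(n_case + n_ctrl)]
    cond = pd.Series([1] * n_case + [0] * n_ctrl, index=sample_ids)
    treat = pd.Series([0.0] * n_case + [np.nan] * n_ctrl, index=sample_ids)
    return TraitTable(cond, treat)


def make_dataset(values, n_case, n_ctrl, **kw):
    table = make_table(values, **kw)
    traits = make_traits(n_case, n_ctrl, sample_ids=table.sample_ids)
    return MergedDataset(table, traits)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def fixture44_screened():
    """fixture_44 cohort with the default screening cascade applied once."""
    from gutnet import preprocess, simulate

    dataset = simulate.fixture_44(seed=0)
    z, report = preprocess.select_features(dataset, seed=0)
    return dataset, z, report
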