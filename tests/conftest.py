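import numpy as np
import pandas as pd
import pytest

from kcmnet.tables_io import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(values, feature_ids=None, sample_ids=None, omics="microbiome",
               units="percent_ra"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    feature_ids = feature_ids or [f"f{j}" for j in range(p)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    df = pd.DataFrame(values, index=sample_ids, columns=feature_ids)
    return FeatureTable(df, {f: omics for f in feature_ids},
                        {f: units for f in feature_ids})


@pytest.fixture
def random_table(rng):
    return make_table(rng.lognormal(0, 1, size=(12, 6)))


@pytest.fixture
def paired_design():
    """4 subjects x 2 sexes x 2 arms, sampled at T0 and Te."""
    rows = []
    i = 0
    for sex in ("F", "M"):
        for arm in ("A", "P"):
            for _ in range(4):
                i += 1
                sid = f"S{i:02d}"
                for tp in ("T0", "Te"):
                    rows.append((f"{sid}_{tp}", sid, sex, tp, arm))
    return pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "sex", "timepoint", "arm"]
    ).set_index("sample_id")
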