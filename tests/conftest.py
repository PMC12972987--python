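import numpy as np
import pandas as pd
import pytest

from mucosig import preprocess as pp
from mucosig.synthetic import DesignSpec, generate_cohort

ILEUM_ONLY = {"A": ("ileum",), "B": ("ileum",)}


@pytest.fixture(scope="session")
def two_group_cohort():
    """Moderate two-group, two-cohort study with a planted signature."""
    spec = DesignSpec(n_patients_per_group_per_cohort=12, groups=("HC", "pre_LTx"), seed=7)
    return spec, *generate_cohort(spec)


@pytest.fixture(scope="session")
def filtered_two_group(two_group_cohort):
    """Depth-filtered, NZV-filtered genus table + aligned metadata."""
    spec, counts, info, clinical, truth = two_group_cohort
    deep = pp.filter_depth(counts)
    info = pp.merge_segments(info.loc[deep.index])
    filt = pp.filter_near_zero_variance(deep)
    return filt, info, clinical, truth


def make_info(pairs):
    """SampleInfo from (sample_id, patient_id, cohort, group, segment) tuples."""
    df = pd.DataFrame(
        pairs, columns=["sample_id", "patient_id", "cohort", "group", "segment"]
    )
    return df.set_index("sample_id", drop=False)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
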