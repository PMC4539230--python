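import numpy as np
import pytest

from sexdisc.pipeline import table1_analysis
from sexdisc.synthetic_cohort import default_config, generate_cohort, null_config


@pytest.fixture(scope="session")
def preset_cohort():
    """One study-sized cohort from the shipped effect preset."""
    return generate_cohort(default_config(seed=11))


@pytest.fixture(scope="session")
def preset_measures(preset_cohort):
    return preset_cohort.measures_frame()


@pytest.fixture(scope="session")
def null_table1_pvalues():
    """Table-1 p values from 500 replicate no-effect cohorts (40/group).

    Returns (p, rows): p is a (500, 15) array, rows the matching
    (condition, group_a, group_b) labels.
    """
    ps = []
    rows = None
    for r in range(500):
        cohort = generate_cohort(null_config(seed=40_000 + r, n_per_scenario=40))
        t1 = table1_analysis(cohort)
        if rows is None:
            rows = list(t1[["condition", "group_a", "group_b"]].itertuples(index=False, name=None))
        ps.append(t1["p_two_sided"].to_numpy())
    return np.asarray(ps), rows
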