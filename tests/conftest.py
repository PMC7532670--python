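"""Shared fixtures: the default synthetic likelihood cohort and a fitted model.

The heavy end-to-end artifacts (300 training slides, 150 test slides, the
fitted PALHI/BoW/ensemble stack) are session-scoped so the aggregation,
signature, and acceptance tests share one fit.
"""

import numpy as np
import pytest

from epla.aggregation import bags_from_table, fit_epla
from epla.cohort_io import labels_series
from epla.synthetic import SyntheticCohortConfig, simulate_likelihood_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """450 slides at generator defaults, split 300 train / 150 test."""
    records, table = simulate_likelihood_cohort(
        SyntheticCohortConfig(n_slides=450, seed=1)
    )
    bags = bags_from_table(table)
    labels = labels_series(records)
    sids = [r.slide_id for r in records]
    return {
        "records": records,
        "table": table,
        "bags": bags,
        "labels": labels,
        "train_ids": sids[:300],
        "test_ids": sids[300:],
    }


@pytest.fixture(scope="session")
def fitted_epla(default_cohort):
    """EPLA stack fitted on the training split of the default cohort."""
    bags = {s: default_cohort["bags"][s] for s in default_cohort["train_ids"]}
    return fit_epla(bags, default_cohort["labels"], cv_folds=5, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
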