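import math
from pathlib import Path

import numpy as np
import pytest

from metabias import MetaSample, StudyRecord
from metabias.study_io import two_sided_p

DATA_DIR = Path(__file__).parent / "data"


def make_record(d, variance, study_id="s", alpha=0.05, n=(50, 50), subgroup=None):
    """Record with an explicitly set variance (for hand-built toy samples)."""
    se = math.sqrt(variance)
    p = two_sided_p(d, se)
    return StudyRecord(
        study_id=study_id,
        d=d,
        n_treat=n[0],
        n_ctrl=n[1],
        variance=variance,
        se=se,
        z=d / se,
        p_two_sided=p,
        is_significant=p < alpha,
        subgroup=subgroup,
    )


def toy_sample(ds, variances, label="toy", alpha=0.05):
    if np.isscalar(variances):
        variances = [variances] * len(ds)
    return MetaSample(
        studies=[
            make_record(d, v, study_id=f"s{i}") for i, (d, v) in enumerate(zip(ds, variances))
        ],
        label=label,
        alpha=alpha,
    )


def random_sample(rng, k=10, label="rand"):
    """A heterogeneous random sample for property checks."""
    n1 = rng.integers(10, 120, k)
    n2 = rng.integers(10, 120, k)
    d = rng.normal(0.3, 0.4, k)
    return MetaSample.from_summaries(
        [(f"r{i}", d[i], int(n1[i]), int(n2[i])) for i in range(k)], label=label
    )


@pytest.fixture(scope="session")
def homogeneous_fixture():
    """Frozen 12-study synthetic literature (no heterogeneity, no asymmetry)."""
    from metabias import read_study_table

    return read_study_table(DATA_DIR / "synthetic_literature_12.csv", label="hom12")


@pytest.fixture(scope="session")
def censored_fixture():
    """Frozen 15-study literature generated under significance censoring."""
    from metabias import read_study_table

    return read_study_table(DATA_DIR / "synthetic_censored_15.csv", label="cen15")
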