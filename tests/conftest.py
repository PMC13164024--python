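import numpy as np
import pandas as pd
import pytest

from burdencif.io_cohort import CompetingRisksDataset
from burdencif.synthetic_data import simulate_study_cohort


def make_dataset(time, event, cluster=None, ids=None):
    time = np.asarray(time, dtype=float)
    n = len(time)
    return CompetingRisksDataset(
        subject_id=np.asarray(ids) if ids is not None else np.arange(n).astype(str),
        time=time,
        event=np.asarray(event, dtype=int),
        cluster=np.asarray(cluster) if cluster is not None else np.arange(n),
    )


def simulate_competing(rng, n, beta1=0.0, x=None, p1=0.3, lam1=1.0, lam2=1.2,
                       censor=(0.3, 2.5)):
    """Minimal direct competing-risks draw used as an independent data source
    in tests that must not depend on the package's own generator."""
    x = rng.normal(size=n) if x is None else x
    e1 = np.exp(beta1 * x)
    p_c1 = 1.0 - (1.0 - p1) ** e1
    is1 = rng.uniform(size=n) < p_c1
    u = rng.uniform(size=n)
    inner = (1.0 - u * p_c1) ** (1.0 / e1)
    t1 = -np.log(1.0 - (1.0 - inner) / p1) / lam1
    t2 = rng.exponential(1.0 / lam2, size=n)
    latent = np.where(is1, t1, t2)
    cause = np.where(is1, 1, 2)
    c = rng.uniform(*censor, size=n)
    time = np.minimum(latent, c)
    event = np.where(latent <= c, cause, 0)
    return time, event, x


@pytest.fixture(scope="session")
def study_bundle():
    return simulate_study_cohort(seed=7)


@pytest.fixture(scope="session")
def study_dataset(study_bundle):
    from burdencif.io_cohort import build_dataset

    return build_dataset(study_bundle.subjects, "by_cause")
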