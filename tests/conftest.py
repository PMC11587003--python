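import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import twinefi as te

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_matrix(beta, probe_ids=None, subject_ids=None):
    beta = np.asarray(beta, dtype=float)
    n, m = beta.shape
    probe_ids = probe_ids or [f"cg{k:05d}" for k in range(n)]
    subject_ids = subject_ids or [f"S{k}" for k in range(m)]
    return te.MethylationMatrix(probe_ids=np.array(probe_ids, dtype=object),
                                subject_ids=list(subject_ids), beta=beta)


def make_cohort(ages, prefix="P"):
    pairs = [
        te.TwinPair(f"{prefix}{k}", f"{prefix}{k}a", f"{prefix}{k}b", float(age))
        for k, age in enumerate(ages)
    ]
    return te.TwinCohort(pairs)


def matrix_from_diffs(diffs_young, diffs_elderly, baseline=0.5):
    """Matrix + cohort whose within-pair differences at the single site
    'cg00000' are exactly the given young/elderly sets (ages 30 / 70)."""
    ages = [30.0] * len(diffs_young) + [70.0] * len(diffs_elderly)
    cohort = make_cohort(ages)
    row = []
    for d in list(diffs_young) + list(diffs_elderly):
        row.extend([baseline + d / 2.0, baseline - d / 2.0])
    matrix = make_matrix(np.array([row]), probe_ids=["cg00000"],
                         subject_ids=cohort.subject_ids)
    return matrix, cohort


@pytest.fixture
def toy_matrix_cohort():
    """Six pairs (3 young at 30y, 3 elderly at 70y), one clean site with
    young diffs {-0.1, 0, 0.1} and elderly diffs {-0.2, 0, 0.2}."""
    return matrix_from_diffs([-0.1, 0.0, 0.1], [-0.2, 0.0, 0.2])


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated cohort shared by read-only tests."""
    cfg = te.SimulationConfig(n_pairs=60, n_sites=600, seed=42)
    return te.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_analysis(small_sim):
    return te.analyze_cohort(small_sim.matrix, small_sim.cohort)
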