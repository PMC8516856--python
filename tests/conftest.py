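import numpy as np
import pytest

import meadev as md


@pytest.fixture(scope="session")
def default_cohort():
    """The default 60-dish synthetic cohort, QC'd, with features and truth.

    Built once per session; several end-to-end tests share it.
    """
    cfg = md.CohortConfig(seed=1)
    recordings, truth = md.simulate_cohort(cfg)
    kept, qc_log = md.apply_qc_cohort(recordings)
    table = md.feature_table(kept)
    trajectories = md.aggregate_trajectories(table)
    archetypes = truth.drop_duplicates("dish").set_index("dish")["archetype"]
    return {
        "config": cfg,
        "truth": truth,
        "qc_log": qc_log,
        "features": table,
        "trajectories": trajectories,
        "archetypes": archetypes,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_train(rng, rate_hz, duration_s):
    """Sorted homogeneous Poisson spike train."""
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))
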