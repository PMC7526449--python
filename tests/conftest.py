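import numpy as np
import pytest

from regact.base_scoring import base_activity, normalize_expression
from regact.synthetic_data import default_config, simulate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort with its normalized activity matrix."""
    cfg = default_config(
        seed=11,
        n_genes=300,
        n_regulators=30,
        targets_per_regulator=20,
        samples_per_subset=5,
    )
    em, sets, ct, truth = simulate_dataset(cfg)
    am = base_activity(normalize_expression(em), sets, n_perm=40, seed=7)
    return {"cfg": cfg, "expr": em, "sets": sets, "clinical": ct, "truth": truth, "activity": am}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
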