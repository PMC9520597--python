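import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "chemosig",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("chemosig")

from chemosig import SimulationConfig, simulate_cohort  # noqa: E402


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-gene, 120-sample planted cohort shared across read-only tests."""
    cfg = SimulationConfig(n_samples=120, n_genes=400, n_pro=4, n_con=4,
                           hazard_ratio=4.0, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture()
def clinical_two_arm():
    """Clinical table with a treated and an untreated arm, fixed draw."""
    rng = np.random.default_rng(5)
    n = 160
    treated = rng.random(n) < 0.5
    time = rng.exponential(np.where(treated, 900, 450))
    censor = rng.exponential(1500, size=n)
    return pd.DataFrame({
        "sample_id": [f"S{i:03d}" for i in range(n)],
        "time_days": np.minimum(time, censor),
        "event": time <= censor,
        "treatment": np.where(treated, "5-FU", "none"),
        "cancer_type": "STAD",
        "subtype": rng.choice(["diffuse", "intestinal", "not specified"], size=n),
    })
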