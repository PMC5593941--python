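import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metadeg.config import SimulationConfig
from metadeg.synthetic import simulate_all

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic cohort shared across read-only tests."""
    cfg = SimulationConfig(
        n_genes=400,
        group_sizes={"normal": 10, "confined": 16, "lymphnode": 12, "metastasis": 8},
        n_deg_up=25,
        n_deg_down=25,
        planted_module_size=10,
        network_n_nodes=200,
        network_n_edges=700,
        missing_rate=0.02,
        seed=11,
    )
    expr, ann, truth, net = simulate_all(cfg)
    return {"config": cfg, "expr": expr, "ann": ann, "truth": truth, "net": net}


@pytest.fixture()
def toy_expr():
    """5 genes × 6 samples, two groups, complete, hand-readable values."""
    rng = np.random.default_rng(7)
    values = rng.normal(8.0, 1.0, size=(5, 6)).round(2)
    expr = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(6)],
    )
    ann = pd.DataFrame(
        {
            "group": ["confined"] * 3 + ["lymphnode"] * 3,
            "pair_id": [pd.NA] * 6,
            "os_time": np.nan,
            "os_event": np.nan,
            "age": 60.0,
            "sex": "male",
            "stage": "I",
        },
        index=expr.columns,
    )
    return expr, ann
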