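import numpy as np
import pandas as pd
import pytest

from prognet.dataio import ExpressionMatrix, SurvivalData
from prognet.synthio import PlantedModule, SyntheticConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_expr():
    """5 probes x 4 samples, deterministic values."""
    data = pd.DataFrame(
        np.arange(20, dtype=float).reshape(5, 4) / 3.0 + 1.0,
        index=[f"P{i}" for i in range(5)],
        columns=[f"S{i}" for i in range(4)],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def exp_survival(rng):
    """200 samples, exponential times, ~25% censored."""
    n = 200
    t = rng.exponential(50.0, n)
    c = rng.exponential(150.0, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return SurvivalData(
        pd.DataFrame({"time": time, "event": event}, index=[f"S{i:04d}" for i in range(n)])
    )


def planted_config(seed: int, **overrides) -> SyntheticConfig:
    """Standard planted-signal config used across integration tests."""
    kwargs = dict(
        n_genes=200,
        n_samples=250,
        planted_modules=[
            PlantedModule(size=12, direction="poor", beta=0.8),
            PlantedModule(size=12, direction="good", beta=0.8),
        ],
        within_module_corr=0.6,
        background_edge_prob=0.01,
        module_edge_prob=0.9,
        censoring_rate=0.25,
        n_housekeeping=10,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture
def planted_cohort():
    cfg = planted_config(seed=7)
    truth, network, expr, surv = generate_cohort(cfg)
    return cfg, truth, network, expr, surv
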