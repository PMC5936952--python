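import warnings

import numpy as np
import pandas as pd
import pytest

from afloc import lattice_model as lm
from afloc.features import FEATURE_VECTOR_NAMES
from afloc.forest_models import ModelBundle, train_models

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def default_config() -> lm.ModelConfig:
    return lm.ModelConfig()


@pytest.fixture(scope="session")
def fibrillating_sim(default_config):
    """One initialized fibrillating tissue with a known circuit."""
    rng = np.random.default_rng(12)
    tissue = lm.build_tissue(default_config, rng)
    circuit = lm.insert_circuit(tissue, (100, 85))
    sim, t_ready = lm.initialize_af(tissue, circuit, rng=rng)
    return sim, circuit, t_ready


def synthetic_training_table(n_rows: int = 400, seed: int = 0) -> pd.DataFrame:
    """A fake labelled corpus whose targets depend on a few designated
    feature columns; cheap stand-in for simulated training data in
    model-API tests (synthetic, not produced by the simulator)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_rows, len(FEATURE_VECTOR_NAMES)))
    table = pd.DataFrame(X, columns=list(FEATURE_VECTOR_NAMES))
    dx = rng.integers(-30, 31, size=n_rows) * 5.0
    dy = rng.integers(-10, 11, size=n_rows) * 2.0
    # plant recoverable signal in two feature columns
    table["grad_x_intensity"] = dx / 50.0 + rng.normal(scale=0.01, size=n_rows)
    table["grad_y_intensity"] = dy / 50.0 + rng.normal(scale=0.01, size=n_rows)
    table["dx"] = dx
    table["dy"] = dy
    table["on_x_axis"] = np.abs(dx) <= 15
    table["on_y_axis"] = np.abs(dy) <= 4
    table["on_circuit"] = table["on_x_axis"] & table["on_y_axis"]
    table["probe_row"] = rng.integers(0, 200, size=n_rows)
    table["probe_col"] = rng.integers(3, 197, size=n_rows)
    return table


@pytest.fixture(scope="session")
def tiny_bundle() -> ModelBundle:
    """Bundle trained on the synthetic table; fast, deterministic."""
    table = synthetic_training_table()
    return train_models(
        table,
        hyperparams={"n_estimators": 20, "min_samples_leaf": 2},
        rng=0,
    )
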