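import numpy as np
import pandas as pd
import pytest

from tbarskinetics import (
    generate_study,
    load_secondary_fixture,
    published_study_spec,
)
from tbarskinetics.mlr import DesignMatrix


@pytest.fixture(scope="session")
def secondary_fixture():
    return load_secondary_fixture()


@pytest.fixture(scope="session")
def study_seed7():
    """Full synthetic study at the published Arrhenius ground truths, seed 7."""
    return generate_study(published_study_spec(seed=7))


@pytest.fixture
def multi_temp_csv(tmp_path):
    """Long-format CSV spanning two temperatures (regression-friendly)."""
    rows = []
    rng = np.random.default_rng(1)
    for sample in ("Control", "Clove", "Onion"):
        for temp, k in ((4, 0.1), (16, 0.25)):
            for rep in (1, 2):
                for day in (0, 1, 2, 3, 4, 5):
                    rows.append(
                        {
                            "sample": sample,
                            "temperature": temp,
                            "replicate": rep,
                            "day": day,
                            "value": 0.25 * np.exp(k * day) * rng.uniform(0.98, 1.02),
                        }
                    )
    path = tmp_path / "multi.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


@pytest.fixture
def small_csv(tmp_path):
    """Long-format CSV: 2 samples x 1 temperature x 3 replicates x 6 days."""
    rows = []
    rng = np.random.default_rng(0)
    for sample in ("Control", "Clove"):
        for rep in (1, 2, 3):
            for day in (0, 1, 2, 3, 4, 5):
                rows.append(
                    {
                        "sample": sample,
                        "temperature": 4,
                        "replicate": rep,
                        "day": day,
                        "value": 0.25 * np.exp(0.1 * day) * rng.uniform(0.98, 1.02),
                    }
                )
    path = tmp_path / "study.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def make_design(seed, n_groups=4, n_per_group=10, effects=None, sigma=0.1,
                beta0=4.4, beta_t=0.126, beta_T=0.044):
    """Design matrix drawn from the linear model itself (for inference tests)."""
    rng = np.random.default_rng(seed)
    labels = ["Control"] + [f"G{i}" for i in range(1, n_groups)]
    effects = effects or {}
    rows, y = [], []
    for g in labels:
        t = rng.uniform(0, 13, n_per_group)
        T = rng.uniform(4, 20, n_per_group)
        for ti, Ti in zip(t, T):
            row = {"intercept": 1.0, "time": ti, "temperature": Ti}
            for lab in labels[1:]:
                row[lab] = 1.0 if g == lab else 0.0
            rows.append(row)
            y.append(
                beta0 + beta_t * ti + beta_T * Ti + effects.get(g, 0.0)
                + (rng.normal(0, sigma) if sigma > 0 else 0.0)
            )
    cols = pd.DataFrame(rows, columns=["intercept", "time", "temperature"] + labels[1:])
    return DesignMatrix(response=np.asarray(y), columns=cols, reference_label="Control")
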