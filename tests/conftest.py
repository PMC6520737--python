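import numpy as np
import pandas as pd
import pytest

from ieinter import (
    ClinicalMatrix,
    ContinuousOutcome,
    Dataset,
    FeatureMatrix,
    SurvivalOutcome,
    SyntheticConfig,
    TrueModel,
    generate_continuous,
    generate_design,
    generate_survival,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_config():
    """Desk-scale synthetic study conditions: 30 features in three groups."""
    return SyntheticConfig(
        n=60,
        group_sizes={"Texture": 15, "Geometry": 10, "Holistic": 5},
        rho=0.3,
        seed=42,
    )


@pytest.fixture
def small_truth(small_config):
    K = small_config.K
    eta = np.zeros(K)
    gamma = np.zeros((4, K))
    eta[[1, 8, 20]] = [1.0, -0.8, 0.6]
    gamma[0, 1] = 0.9
    gamma[3, 8] = -0.7
    return TrueModel(tau=np.array([0.4, -0.2, 0.3, 0.0]), eta=eta, gamma=gamma)


@pytest.fixture
def continuous_dataset(small_config, small_truth):
    rng = np.random.default_rng(7)
    E, X = generate_design(small_config, rng=rng)
    y = generate_continuous(E, X, small_truth, sigma=0.5, seed=rng)
    return Dataset(E=E, X=X, outcome=y)


@pytest.fixture
def survival_dataset(small_config, small_truth):
    rng = np.random.default_rng(8)
    E, X = generate_design(small_config, rng=rng)
    out = generate_survival(E, X, small_truth, sigma=0.5, seed=rng)
    return Dataset(E=E, X=X, outcome=out)


@pytest.fixture
def uncensored_dataset(continuous_dataset):
    """Survival dataset with no censoring: time = exp(y), all events."""
    y = continuous_dataset.outcome.y
    return Dataset(
        E=continuous_dataset.E,
        X=continuous_dataset.X,
        outcome=SurvivalOutcome(np.exp(y), np.ones(len(y), dtype=int)),
        subject_ids=list(continuous_dataset.subject_ids),
    )


@pytest.fixture
def table_paths(tmp_path):
    """Three aligned delimited tables sharing 5 subject IDs."""
    ids = ["s1", "s2", "s3", "s4", "s5"]
    feats = pd.DataFrame(
        {"id": ids, "f1": [1.0, 2, 3, 4, 5], "f2": [0.5, 0.1, -0.3, 0.9, 0.2]}
    )
    clin = pd.DataFrame({"id": ids, "age": [60, 70, 55, 65, 72], "sex": [0, 1, 0, 1, 1]})
    outc = pd.DataFrame({"id": ids, "y": [1.2, 0.8, 1.5, 0.3, 0.9]})
    fp, cp, op = tmp_path / "f.csv", tmp_path / "c.csv", tmp_path / "o.csv"
    feats.to_csv(fp, index=False)
    clin.to_csv(cp, index=False)
    outc.to_csv(op, index=False)
    return fp, cp, op
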