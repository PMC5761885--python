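import dataclasses

import numpy as np
import pandas as pd
import pytest

from beatgrid.grid import experiment_table
from beatgrid.stimuli import EXP1_CONFIG, build_experiment_stimuli


@pytest.fixture(scope="session")
def exp1():
    """Enumerated Experiment-1 space and condition table (shared, ~1 s)."""
    return experiment_table(1)


@pytest.fixture(scope="session")
def exp2():
    return experiment_table(2)


@pytest.fixture(scope="session")
def exp1_trials(exp1):
    space, _ = exp1
    cfg = dataclasses.replace(EXP1_CONFIG, seed=20240101)
    return build_experiment_stimuli(space, space.intensity_masks, cfg)


def simulate_clmm_data(rng, n_groups, n_per, beta, theta, sigma,
                       X=None, n_cat=None):
    """Draw ordinal responses from the cumulative-logistic mixed law.

    Independent of the package's generator: direct inverse-CDF sampling on
    an explicit design matrix.
    """
    from scipy.special import expit

    theta = np.asarray(theta, dtype=float)
    n_cat = n_cat or theta.size + 1
    n = n_groups * n_per
    groups = np.repeat(np.arange(n_groups), n_per)
    if X is None:
        X = rng.normal(size=(n, len(beta)))
    b = rng.normal(scale=sigma, size=n_groups) if sigma > 0 else np.zeros(n_groups)
    eta = X @ np.asarray(beta) + b[groups]
    cum = expit(theta[None, :] - eta[:, None])
    y = (rng.random(n)[:, None] > cum).sum(axis=1)
    return y, X, groups


@pytest.fixture(scope="session")
def clmm_frame():
    """Small ratings-shaped frame drawn from the model the fitter assumes."""
    rng = np.random.default_rng(42)
    cells = [(0, "few"), (1, "few"), (1, "some"), (1, "many"), (2, "few"),
             (2, "some"), (2, "many"), (3, "few"), (3, "some"), (3, "many")]
    rows = []
    for pid in range(8):
        training = float(rng.uniform(0, 20))
        for _ in range(60):
            mb, cat = cells[rng.integers(len(cells))]
            rows.append(dict(participant_id=f"p{pid}",
                             missing_beats=mb, off_beat_category=cat,
                             accent_type=("temporal", "intensity")[rng.integers(2)],
                             training_years=training))
    df = pd.DataFrame(rows)
    theta = np.linspace(-1.5, 2.5, 9)
    eta = 0.5 * df["missing_beats"].to_numpy() + rng.normal(
        scale=0.8, size=df["participant_id"].nunique()
    )[pd.factorize(df["participant_id"])[0]]
    from scipy.special import expit
    cum = expit(theta[None, :] - eta[:, None])
    df["rating"] = (rng.random(len(df))[:, None] > cum).sum(axis=1) + 1
    return df
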