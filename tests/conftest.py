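"""Shared fixtures: small synthetic scenarios generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from soundlasso.datasets import GeneratorConfig, Predictor, generate_survey
from soundlasso.preprocess import prepare_design


def continuous_roster(k: int) -> tuple[Predictor, ...]:
    return tuple(Predictor(f"x{i}", "continuous") for i in range(1, k + 1))


def make_survey(seed: int = 0, n_clusters: int = 200, beta=None, tau00=0.2,
                sigma2=0.6, roster=None, **kw):
    cfg = GeneratorConfig(
        n_clusters=n_clusters,
        roster=roster if roster is not None else continuous_roster(3),
        beta=beta if beta is not None else {"x1": 0.5, "x2": -0.3},
        intercept=2.8,
        tau00=tau00,
        sigma2=sigma2,
        seed=seed,
        **kw,
    )
    return generate_survey(cfg)


@pytest.fixture
def small_design():
    """200-cluster design with two true effects and one null predictor."""
    ds = make_survey(seed=1)
    return prepare_design(ds.data, "annoyance", ["x1", "x2", "x3"])


@pytest.fixture
def factor_design():
    """Design with a 3-level factor plus continuous predictors."""
    roster = continuous_roster(2) + (
        Predictor("f", "categorical", levels=("a", "b", "c"),
                  prevalences=(0.5, 0.3, 0.2)),
    )
    ds = make_survey(seed=2, beta={"x1": 0.4, "f[b]": 0.3, "f[c]": -0.5},
                     roster=roster)
    return prepare_design(ds.data, "annoyance", ["x1", "x2", "f"], factors=["f"])


def balanced_frame(n_clusters: int, per_cluster: int, tau00: float,
                   sigma2: float, seed: int) -> pd.DataFrame:
    """Balanced intercept-only two-level data for closed-form oracles."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(tau00), n_clusters)
    e = rng.normal(0, np.sqrt(sigma2), (n_clusters, per_cluster))
    y = 3.0 + u[:, None] + e
    return pd.DataFrame({
        "cluster_id": np.repeat(np.arange(n_clusters), per_cluster),
        "y": y.ravel(),
    })
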