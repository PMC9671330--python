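"""Shared fixtures: tiny geometric cohorts and a mid-size synthetic study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from t2dcf.schema import Cohort, CohortSchema, FeatureSpec, LABEL_HIGH, LABEL_LOW
from t2dcf.simulate import default_t2dm_config, generate_cohort
from t2dcf.schema import split_stratified
from t2dcf.svdd import SVDDHyperparams, reduce_fnr, train_tc_svdd


def schema_2d(role: str = "controllable") -> CohortSchema:
    return CohortSchema(
        (
            FeatureSpec("f1", "au", "numeric", role, -100, 100),
            FeatureSpec("f2", "au", "numeric", role, -100, 100),
        )
    )


def cohort_2d(X_high: np.ndarray, X_low: np.ndarray) -> Cohort:
    """Wrap two 2-D point clouds as a labeled cohort."""
    X = np.vstack([X_high, X_low])
    df = pd.DataFrame(X, columns=["f1", "f2"])
    df.insert(0, "id", [f"r{i}" for i in range(len(df))])
    df["label"] = [LABEL_HIGH] * len(X_high) + [LABEL_LOW] * len(X_low)
    return Cohort(df, schema_2d())


@pytest.fixture(scope="session")
def separated_blobs():
    """Two well-separated Gaussian blobs (n=40 each), RBF-trainable."""
    rng = np.random.default_rng(7)
    Xh = rng.normal([0.0, 0.0], 0.3, size=(40, 2))
    Xl = rng.normal([8.0, 8.0], 0.3, size=(40, 2))
    cohort = cohort_2d(Xh, Xl)
    model = train_tc_svdd(cohort, SVDDHyperparams(sigma=0.8))
    return cohort, model


@pytest.fixture(scope="session")
def study():
    """Default synthetic study: n=1000/class, seed 42, 70/30 split,
    canonical and FNR-reduced models.  Shared session-wide because
    training dominates suite runtime."""
    cohort, _ = generate_cohort(default_t2dm_config(n_per_class=1000, seed=42))
    train, test = split_stratified(cohort, 0.7, seed=42)
    model = train_tc_svdd(train)
    reduced = reduce_fnr(model, train, tau=0.08, shrink_step=0.01,
                         coverage_floor=0.35)
    return {"cohort": cohort, "train": train, "test": test,
            "model": model, "reduced": reduced}
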