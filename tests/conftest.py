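import numpy as np
import pandas as pd
import pytest

from asps import (
    BIOMARKERS,
    LongitudinalProfile,
    PopulationPrior,
    TrainingSet,
)


@pytest.fixture
def prior():
    return PopulationPrior(mu0=0.0, tau2=1.0, sigma2_w=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_profile(values_by_biomarker=None, athlete_id="A1", T=6, rng=None,
                 **kwargs) -> LongitudinalProfile:
    """Build a profile; unspecified biomarkers get lognormal noise."""
    rng = rng or np.random.default_rng(0)
    data = {}
    for b in BIOMARKERS:
        if values_by_biomarker and b in values_by_biomarker:
            data[b] = np.asarray(values_by_biomarker[b], dtype=float)
            T = len(data[b])
        else:
            data[b] = np.exp(0.1 * rng.standard_normal(T))
    return LongitudinalProfile(athlete_id=athlete_id,
                               values=pd.DataFrame(data, columns=list(BIOMARKERS)),
                               **kwargs)


def make_training_set(n=60, n_features=6, seed=0, lab_frac=0.0,
                      beta=None) -> TrainingSet:
    """Random features with a known logistic signal."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, n_features))
    names = [f"f{i:02d}" for i in range(n_features)]
    if beta is None:
        beta = np.zeros(n_features)
        beta[: min(2, n_features)] = 1.0
    eta = X @ beta
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    # ensure both classes
    if y.sum() == 0:
        y[0] = 1
    if y.sum() == n:
        y[0] = 0
    n_lab = int(round(lab_frac * n))
    source = np.array(["laboratory"] * n_lab
                      + ["doping_control"] * (n - n_lab), dtype=object)
    weights = np.where(source == "laboratory", 20.0, 1.0)
    ids = [f"A{i:03d}" for i in range(n)]
    return TrainingSet(features=pd.DataFrame(X, columns=names, index=ids),
                       labels=y, weights=weights, source=source)
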