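"""Bayesian adaptive longitudinal model and sequence probabilities.

Each biomarker is modelled on the log scale with a normal-normal
conjugate hierarchy: an athlete-level mean drawn from a population
distribution and independent within-athlete noise around it.  The
sequence probability of a new measurement is the posterior-predictive
CDF evaluated at that measurement, computed *before* the measurement is
absorbed (prequential scoring), so the first observation of a series is
scored under the pure population prior.

Values near 0 mean the measurement is much lower than the athlete's
expected range; values near 1 mean much higher.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .exceptions import (
    EmptyInputError,
    EstimationError,
    InvalidMeasurementError,
    InvalidPriorError,
)
from .profiles import BIOMARKERS, LongitudinalProfile, canonical_biomarker

#: Clamp applied to sequence probabilities before downstream logit-like use.
Z_CLAMP = 1e-12

#: Floor for estimated variance components.
VARIANCE_FLOOR = 1e-6


@dataclass(frozen=True)
class PopulationPrior:
    """Hyperparameters of the log-scale hierarchy for one biomarker.

    mu0
        Population mean of the log-ratio.
    tau2
        Between-athlete variance of the athlete-level log mean.
    sigma2_w
        Within-athlete variance of log measurements around that mean.
    """

    mu0: float
    tau2: float
    sigma2_w: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu0) and math.isfinite(self.tau2)
                and math.isfinite(self.sigma2_w)):
            raise InvalidPriorError("prior parameters must be finite")
        if self.tau2 <= 0 or self.sigma2_w <= 0:
            raise InvalidPriorError(
                f"variances must be positive (tau2={self.tau2}, "
                f"sigma2_w={self.sigma2_w})"
            )


@dataclass(frozen=True)
class PredictiveState:
    """Running posterior for one athlete x biomarker.

    ``m`` and ``v`` are the posterior mean and variance of the athlete's
    log-scale mean; the one-step predictive distribution for the next
    log measurement is Normal(m, v + sigma2_w).
    """

    n_obs: int
    m: float
    v: float
    prior: PopulationPrior

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise InvalidPriorError("posterior variance must be positive")
        if self.n_obs < 0:
            raise ValueError("n_obs must be non-negative")

    @property
    def predictive_variance(self) -> float:
        return self.v + self.prior.sigma2_w


@dataclass(frozen=True)
class SequenceProbability:
    """A prequential CDF value for one occasion, clamped inside (0, 1)."""

    z: float
    occasion: int

    def __post_init__(self) -> None:
        if not 0.0 < self.z < 1.0:
            raise ValueError(f"z must lie in (0,1), got {self.z}")


def init_state(prior: PopulationPrior) -> PredictiveState:
    """Fresh state: zero observations, posterior equals the prior."""
    return PredictiveState(n_obs=0, m=prior.mu0, v=prior.tau2, prior=prior)


def _check_measurement(y: float) -> float:
    y = float(y)
    if not math.isfinite(y) or y <= 0:
        raise InvalidMeasurementError(f"measurement must be positive, got {y}")
    return y


def predictive_cdf(state: PredictiveState, y: float,
                   occasion: int = 0) -> SequenceProbability:
    """Score a measurement against the current predictive distribution.

    Returns Phi((log y - m) / sqrt(v + sigma2_w)), clamped to
    ``[Z_CLAMP, 1 - Z_CLAMP]`` so downstream logits stay finite.
    """
    y = _check_measurement(y)
    sd = math.sqrt(state.predictive_variance)
    z = stats.norm.cdf((math.log(y) - state.m) / sd)
    z = min(max(z, Z_CLAMP), 1.0 - Z_CLAMP)
    return SequenceProbability(z=z, occasion=occasion)


def update_state(state: PredictiveState, y: float) -> PredictiveState:
    """Absorb a measurement via the conjugate normal update on log scale."""
    y = _check_measurement(y)
    precision = 1.0 / state.v + 1.0 / state.prior.sigma2_w
    v_new = 1.0 / precision
    m_new = v_new * (state.m / state.v + math.log(y) / state.prior.sigma2_w)
    return replace(state, n_obs=state.n_obs + 1, m=m_new, v=v_new)


def sequence_probabilities(series, prior: PopulationPrior
                           ) -> list[SequenceProbability]:
    """Prequential sequence probabilities for an ordered series.

    Each value is scored with :func:`predictive_cdf` before being passed
    to :func:`update_state`, so z_t depends only on observations before t.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size == 0:
        raise EmptyInputError("series must be a non-empty 1-D sequence")
    state = init_state(prior)
    out: list[SequenceProbability] = []
    for t, y in enumerate(series):
        out.append(predictive_cdf(state, y, occasion=t))
        state = update_state(state, y)
    return out


def sequence_probability_values(series, prior: PopulationPrior) -> np.ndarray:
    """Like :func:`sequence_probabilities` but returning a plain array."""
    return np.array([sp.z for sp in sequence_probabilities(series, prior)])


def estimate_prior(profiles, key: str) -> PopulationPrior:
    """Method-of-moments hyperparameter estimate for one biomarker.

    mu0 is the grand mean of per-athlete log means; sigma2_w the pooled
    within-athlete variance of log values; tau2 the variance of the
    per-athlete log means minus the sampling contribution
    sigma2_w / harmonic-mean(n).  Both variance components are floored
    at ``VARIANCE_FLOOR``.
    """
    key = canonical_biomarker(key)
    log_series = []
    for p in profiles:
        s = np.log(p.series(key))
        if s.size >= 2:
            log_series.append(s)
    if len(log_series) < 2:
        raise EstimationError(
            "prior estimation needs >= 2 athletes with >= 2 observations"
        )
    means = np.array([s.mean() for s in log_series])
    ns = np.array([s.size for s in log_series], dtype=float)
    pooled_num = sum((s.size - 1) * s.var(ddof=1) for s in log_series)
    pooled_den = float(np.sum(ns - 1))
    sigma2_w = max(pooled_num / pooled_den, VARIANCE_FLOOR)
    harmonic_n = len(ns) / np.sum(1.0 / ns)
    tau2 = max(means.var(ddof=1) - sigma2_w / harmonic_n, VARIANCE_FLOOR)
    return PopulationPrior(mu0=float(means.mean()), tau2=float(tau2),
                           sigma2_w=float(sigma2_w))


def estimate_priors(profiles) -> dict[str, PopulationPrior]:
    """Estimate one :class:`PopulationPrior` per panel biomarker."""
    return {b: estimate_prior(profiles, b) for b in BIOMARKERS}


def transform_profile(profile: LongitudinalProfile,
                      priors: dict[str, PopulationPrior]
                      ) -> LongitudinalProfile:
    """Replace a profile's raw ratios with their sequence probabilities."""
    cols = {
        b: sequence_probability_values(profile.series(b), priors[b])
        for b in BIOMARKERS
    }
    values = profile.values.copy()
    for b in BIOMARKERS:
        values[b] = cols[b]
    return LongitudinalProfile(
        athlete_id=profile.athlete_id, values=values, label=profile.label,
        weight=profile.weight, source=profile.source, regime=profile.regime,
        kind="abp_sp", meta=dict(profile.meta),
    )


def transform_profiles(profiles, priors) -> list[LongitudinalProfile]:
    return [transform_profile(p, priors) for p in profiles]
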