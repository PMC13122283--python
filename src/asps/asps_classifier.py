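"""Weighted logistic-regression risk score (the ASPS) and its evaluation.

Training data mix two sources: laboratory athletes (known dopers, loss
weight 20 by default) and doping-control athletes (ADRV label, weight 1).
The model is fitted by Newton iterations on the weighted Bernoulli
log-likelihood of standardised features, with a tiny switchable ridge on
the slopes to guard against separation.  Cross-validation folds are
built from doping-control athletes only, stratified so every fold holds
the same number of positives (up to integer remainder); laboratory
athletes join every training split and are never scored.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .exceptions import (
    DegenerateLabelsError,
    EmptyInputError,
    PlanError,
    SchemaError,
    UndefinedAUCError,
)
from .trajectory_features import FEATURE_NAMES

logger = logging.getLogger(__name__)

DEFAULT_LAB_WEIGHT = 20.0
DEFAULT_RIDGE = 1e-8

LABORATORY = "laboratory"
DOPING_CONTROL = "doping_control"


@dataclass
class TrainingSet:
    """Feature matrix plus labels, loss weights and source tags."""

    features: pd.DataFrame          # index: athlete_id, columns: features
    labels: np.ndarray              # 0/1 per athlete
    weights: np.ndarray             # positive loss weights
    source: np.ndarray              # LABORATORY / DOPING_CONTROL

    def __post_init__(self) -> None:
        n = len(self.features)
        self.labels = np.asarray(self.labels, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        self.source = np.asarray(self.source, dtype=object)
        if not (len(self.labels) == len(self.weights) == len(self.source) == n):
            raise ValueError("features/labels/weights/source length mismatch")
        if n and not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame,
                           lab_weight: float = DEFAULT_LAB_WEIGHT
                           ) -> "TrainingSet":
        """Build from :func:`compute_feature_table` output.

        Weights default to ``lab_weight`` for laboratory athletes and 1
        for doping-control athletes unless a weight column overrides.
        """
        feats = table[[c for c in table.columns
                       if c not in ("label", "weight", "source")]]
        source = table.get("source",
                           pd.Series(DOPING_CONTROL, index=table.index))
        weights = np.where(np.asarray(source) == LABORATORY, lab_weight, 1.0)
        return cls(features=feats,
                   labels=table["label"].to_numpy(),
                   weights=weights,
                   source=np.asarray(source))

    def subset(self, mask: np.ndarray) -> "TrainingSet":
        return TrainingSet(features=self.features.loc[mask],
                           labels=self.labels[np.asarray(mask)],
                           weights=self.weights[np.asarray(mask)],
                           source=self.source[np.asarray(mask)])

    @property
    def athlete_ids(self) -> np.ndarray:
        return self.features.index.to_numpy()


@dataclass
class LogisticModel:
    """Fitted risk model: intercept, named coefficients, standardisation.

    ``standardisation`` maps feature name -> (centre, scale) learned on
    the training data; predictions standardise first.  The transformed
    output probability is the ASPS.
    """

    intercept: float
    coefficients: dict[str, float]
    standardisation: dict[str, tuple[float, float]]
    measurement_kind: str = "original"
    converged: bool = True
    n_iter: int = 0
    std_errors: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    schema_version: int = 1

    @property
    def feature_names(self) -> list[str]:
        return list(self.coefficients)

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        """Standardised feature matrix restricted to model features."""
        missing = [n for n in self.coefficients if n not in features.columns]
        if missing:
            raise SchemaError(f"features missing model columns: {missing}")
        X = features[self.feature_names].to_numpy(dtype=float)
        centre = np.array([self.standardisation[n][0] for n in self.feature_names])
        scale = np.array([self.standardisation[n][1] for n in self.feature_names])
        return (X - centre) / scale

    def linear_predictor(self, features: pd.DataFrame) -> np.ndarray:
        beta = np.array([self.coefficients[n] for n in self.feature_names])
        return self.intercept + self.transform(features) @ beta

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(features))

    # -- flat key-value serialisation ------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "measurement_kind": self.measurement_kind,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "standardisation": {k: list(v)
                                for k, v in self.standardisation.items()},
            "converged": self.converged,
            "n_iter": self.n_iter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticModel":
        return cls(
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            standardisation={k: (float(v[0]), float(v[1]))
                             for k, v in d["standardisation"].items()},
            measurement_kind=d.get("measurement_kind", "original"),
            converged=bool(d.get("converged", True)),
            n_iter=int(d.get("n_iter", 0)),
            schema_version=int(d.get("schema_version", 1)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "LogisticModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class CVPlan:
    """Fold assignment over doping-control athletes only."""

    K: int
    assignment: dict  # athlete_id -> fold index

    def fold_ids(self, k: int) -> list:
        return [a for a, f in self.assignment.items() if f == k]


def standardise(train: TrainingSet, feature_names=None
                ) -> tuple[dict[str, tuple[float, float]], pd.DataFrame]:
    """Centre/scale each feature to training mean 0, sd 1 (n-1 scaling).

    Zero-variance features are dropped with a logged warning and do not
    appear in the returned transform or matrix.
    """
    if len(train.features) == 0:
        raise EmptyInputError("empty training set")
    names = list(feature_names) if feature_names is not None \
        else list(train.features.columns)
    transform: dict[str, tuple[float, float]] = {}
    kept: dict[str, np.ndarray] = {}
    dropped = []
    for name in names:
        col = train.features[name].to_numpy(dtype=float)
        centre = float(col.mean())
        scale = float(col.std(ddof=1)) if col.size > 1 else 0.0
        if scale <= 0 or not np.isfinite(scale):
            dropped.append(name)
            continue
        transform[name] = (centre, scale)
        kept[name] = (col - centre) / scale
    if dropped:
        logger.warning("dropped %d zero-variance feature(s): %s",
                       len(dropped), dropped)
    return transform, pd.DataFrame(kept, index=train.features.index)


def _newton_fit(X: np.ndarray, y: np.ndarray, w: np.ndarray, ridge: float,
                tol: float = 1e-8, max_iter: int = 100):
    """Newton optimisation of the weighted penalised Bernoulli loss.

    ``X`` includes the leading intercept column, which is not penalised.
    Returns (beta, hessian_at_optimum, converged, n_iter).
    """
    n, p = X.shape
    pen = np.full(p, ridge)
    pen[0] = 0.0
    beta = np.zeros(p)

    def loss(b):
        eta = X @ b
        return float(np.sum(w * (np.logaddexp(0.0, eta) - y * eta))
                     + 0.5 * np.sum(pen * b * b))

    current = loss(beta)
    converged = False
    it = 0
    H = np.eye(p)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (w * (mu - y)) + pen * beta
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        W = w * mu * (1.0 - mu)
        H = (X.T * W) @ X + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        for _ in range(50):
            candidate = beta - t * step
            new = loss(candidate)
            if new <= current + 1e-12:
                break
            t *= 0.5
        beta, current = candidate, new
    # Hessian at the final point, for Wald diagnostics
    mu = expit(X @ beta)
    W = w * mu * (1.0 - mu)
    H = (X.T * W) @ X + np.diag(pen)
    return beta, H, converged, it


def fit_weighted_logistic(train: TrainingSet, feature_names=None,
                          ridge: float = DEFAULT_RIDGE,
                          measurement_kind: str = "original",
                          tol: float = 1e-8,
                          max_iter: int = 100) -> LogisticModel:
    """Fit the weighted logistic model on standardised features.

    Maximises the weighted Bernoulli log-likelihood (minus a tiny ridge
    on the slopes) by damped Newton steps; deterministic given input
    order.  Non-convergence raises a warning, not an error.
    """
    classes = set(np.unique(train.labels))
    if classes != {0, 1}:
        raise DegenerateLabelsError(f"need both classes, got labels {classes}")
    transform, Xs = standardise(train, feature_names)
    names = list(Xs.columns)
    X = np.column_stack([np.ones(len(Xs)), Xs.to_numpy(dtype=float)])
    beta, H, converged, n_iter = _newton_fit(
        X, train.labels.astype(float), train.weights, ridge,
        tol=tol, max_iter=max_iter)
    if not converged:
        grad_note = f"after {n_iter} iterations"
        warnings.warn(f"logistic fit did not reach tolerance {grad_note}",
                      RuntimeWarning, stacklevel=2)
        logger.warning("logistic fit not converged %s", grad_note)
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    return LogisticModel(
        intercept=float(beta[0]),
        coefficients={n: float(b) for n, b in zip(names, beta[1:])},
        standardisation=transform,
        measurement_kind=measurement_kind,
        converged=converged,
        n_iter=n_iter,
        std_errors={n: float(s) for n, s in zip(["intercept"] + names, se)},
        p_values={n: float(p) for n, p in zip(["intercept"] + names, pvals)},
    )


def predict_asps(model: LogisticModel, features) -> np.ndarray | float:
    """ASPS = logistic(intercept + sum of coefficient x standardised feature).

    Accepts a DataFrame (returns an array) or a Series/dict for a single
    athlete (returns a float).
    """
    if isinstance(features, dict):
        features = pd.Series(features)
    if isinstance(features, pd.Series):
        return float(model.predict(features.to_frame().T)[0])
    return model.predict(features)


def select_variables(train: TrainingSet, target_size: int = 21,
                     ridge: float = DEFAULT_RIDGE,
                     measurement_kind: str = "original",
                     alpha: float = 0.05) -> LogisticModel:
    """Backward elimination on Wald p-values.

    Starting from the full model, repeatedly refit and drop the
    coefficient with the largest p-value until ``target_size`` regressors
    remain or every p-value is below ``alpha``.  Ties are broken by
    dropping the lexicographically last name.  Deterministic.
    """
    model = fit_weighted_logistic(train, ridge=ridge,
                                  measurement_kind=measurement_kind)
    names = model.feature_names
    if target_size >= len(names):
        warnings.warn("target_size >= available features; nothing to select",
                      RuntimeWarning, stacklevel=2)
        return model
    while len(names) > target_size:
        pvals = {n: model.p_values[n] for n in names}
        worst_p = max(pvals.values())
        if worst_p < alpha:
            break
        tied = sorted(n for n, p in pvals.items() if p >= worst_p - 1e-12)
        drop = tied[-1]
        names = [n for n in names if n != drop]
        model = fit_weighted_logistic(train, feature_names=names, ridge=ridge,
                                      measurement_kind=measurement_kind)
    return model


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with midrank tie handling.

    P(score_pos > score_neg) + 0.5 P(score_pos = score_neg).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    rank_sum = float(np.sum(ranks[labels == 1]))
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def make_cv_plan(train: TrainingSet, K: int = 5, seed: int = 0) -> CVPlan:
    """Stratified fold plan: shuffle by seed, deal round-robin.

    Positives and negatives among doping-control athletes are shuffled
    separately and dealt to folds in turn, so fold positive counts differ
    by at most one.  Laboratory athletes get no fold.
    """
    if K < 2:
        raise PlanError("K must be >= 2")
    dc = train.source == DOPING_CONTROL
    ids = train.athlete_ids
    pos = ids[dc & (train.labels == 1)]
    neg = ids[dc & (train.labels == 0)]
    if len(pos) < K:
        raise PlanError(f"need >= {K} positive doping-control athletes, "
                        f"got {len(pos)}")
    rng = np.random.default_rng(seed)
    assignment: dict = {}
    for group in (pos, neg):
        shuffled = rng.permutation(np.asarray(group))
        for i, athlete in enumerate(shuffled):
            assignment[athlete] = i % K
    return CVPlan(K=K, assignment=assignment)


def cross_validated_scores(train: TrainingSet, plan: CVPlan,
                           fit_fn=None) -> pd.Series:
    """Out-of-fold ASPS for every doping-control athlete.

    ``fit_fn`` is the pluggable scorer contract: any callable mapping a
    :class:`TrainingSet` to an object with ``predict(features) ->
    scores``; defaults to the weighted logistic fit.  Each fold's model
    trains on the remaining folds plus all laboratory athletes.
    """
    if fit_fn is None:
        fit_fn = fit_weighted_logistic
    ids = train.athlete_ids
    dc_ids = set(ids[train.source == DOPING_CONTROL])
    planned = set(plan.assignment)
    if planned != dc_ids:
        raise PlanError("plan athletes do not match training set's "
                        "doping-control athletes")
    scores = pd.Series(np.nan, index=train.features.index, dtype=float)
    for k in range(plan.K):
        test_mask = np.array([plan.assignment.get(a) == k for a in ids])
        model = fit_fn(train.subset(~test_mask))
        test_features = train.features.loc[test_mask]
        scores.loc[test_mask] = np.asarray(model.predict(test_features))
    scores = scores.loc[[a in dc_ids for a in ids]]
    assert not scores.isna().any()
    return scores


def cv_auc(train: TrainingSet, plan: CVPlan, fit_fn=None) -> float:
    """AUC of out-of-fold scores over doping-control athletes."""
    scores = cross_validated_scores(train, plan, fit_fn=fit_fn)
    mask = np.array([a in set(scores.index) for a in train.athlete_ids])
    labels = pd.Series(train.labels, index=train.features.index).loc[scores.index]
    return auc(scores.to_numpy(), labels.to_numpy())


def max_score_per_athlete(scores: pd.Series, athlete_ids) -> pd.Series:
    """Collapse per-occasion scores to one per athlete by the maximum."""
    scores = pd.Series(np.asarray(scores, dtype=float),
                       index=np.asarray(athlete_ids))
    if scores.empty:
        raise EmptyInputError("no occasion scores supplied")
    return scores.groupby(level=0).max()
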