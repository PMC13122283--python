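"""Per-biomarker decomposition of the risk score and threshold calibration.

The logistic linear predictor splits into additive source contributions
(LCs): one per biomarker for its mean/range/difference-range features,
and a single covariance source collecting every pairwise-covariance
feature.  A source is flagged when its LC strictly exceeds the flag
threshold (default 0.8); adding the threshold to the linear predictor
multiplies the doping odds by exp(threshold).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import SchemaError, UndefinedAUCError
from .asps_classifier import LogisticModel
from .profiles import BIOMARKERS
from .trajectory_features import FEATURE_NAMES

logger = logging.getLogger(__name__)

DEFAULT_FLAG_THRESHOLD = 0.8

#: Source tags: the four per-biomarker sources plus the covariance source.
SOURCES: tuple[str, ...] = BIOMARKERS + ("cov",)

_FEATURE_SET = frozenset(FEATURE_NAMES)


def source_of_feature(name: str) -> str:
    """Map a feature name to its LC source tag.

    Squared features follow their base feature; every covariance feature
    (levels or differences) maps to the ``cov`` source.
    """
    if name not in _FEATURE_SET:
        raise SchemaError(f"unknown feature name: {name!r}")
    base = name[:-3] if name.endswith("_sq") else name
    if base.startswith("cov_"):
        return "cov"
    for prefix in ("mean_", "range_d1_", "range_d2_", "range_"):
        if base.startswith(prefix):
            return base[len(prefix):]
    raise SchemaError(f"feature {name!r} matches no source rule")


@dataclass(frozen=True)
class SourceLC:
    """Signed per-source contributions to the linear predictor."""

    lc_te: float
    lc_aetio: float
    lc_adiol_ratio: float
    lc_adiol_e: float
    lc_at: float
    lc_cov: float
    asps: float

    _FIELD_BY_SOURCE = {
        "te": "lc_te",
        "a_etio": "lc_aetio",
        "adiol_ratio": "lc_adiol_ratio",
        "adiol_e": "lc_adiol_e",
        "a_t": "lc_at",
        "cov": "lc_cov",
    }

    def contribution(self, source: str) -> float:
        return getattr(self, self._FIELD_BY_SOURCE[source])

    def as_dict(self) -> dict[str, float]:
        return {s: self.contribution(s) for s in SOURCES}

    @property
    def total(self) -> float:
        return float(sum(self.as_dict().values()))


@dataclass(frozen=True)
class FlagSet:
    """Binary per-source flags at a given LC threshold."""

    flags: dict
    threshold: float

    @property
    def odds_multiplier(self) -> float:
        """Odds multiplier implied by a flagged LC increment."""
        return math.exp(self.threshold)

    @property
    def n_flagged(self) -> int:
        return int(sum(self.flags.values()))


@dataclass(frozen=True)
class ThresholdRow:
    """One calibrated operating point of the score."""

    threshold: float
    fpr: float
    tpr: float
    n_flagged: int
    pct_flagged: float
    target_fpr: float
    note: str = ""


def decompose_lc(model: LogisticModel, features) -> SourceLC:
    """Split logit(ASPS) - intercept into per-source sums.

    Each source LC is the sum over its features of coefficient times
    standardised feature value; the intercept belongs to no source.
    """
    if isinstance(features, dict):
        features = pd.Series(features)
    if isinstance(features, pd.Series):
        features = features.to_frame().T
    Xs = model.transform(features)
    if len(Xs) != 1:
        raise ValueError("decompose_lc expects a single athlete's features")
    beta = np.array([model.coefficients[n] for n in model.feature_names])
    terms = Xs[0] * beta
    sums = dict.fromkeys(SOURCES, 0.0)
    for name, term in zip(model.feature_names, terms):
        sums[source_of_feature(name)] += float(term)
    eta = model.intercept + float(terms.sum())
    return SourceLC(
        lc_te=sums["te"], lc_aetio=sums["a_etio"],
        lc_adiol_ratio=sums["adiol_ratio"], lc_adiol_e=sums["adiol_e"],
        lc_at=sums["a_t"], lc_cov=sums["cov"],
        asps=float(1.0 / (1.0 + np.exp(-eta))),
    )


def flag_sources(lc: SourceLC,
                 threshold: float = DEFAULT_FLAG_THRESHOLD) -> FlagSet:
    """Flag each source whose LC strictly exceeds the threshold."""
    flags = {s: int(lc.contribution(s) > threshold) for s in SOURCES}
    return FlagSet(flags=flags, threshold=threshold)


def attribution_table(model: LogisticModel, features: pd.DataFrame,
                      threshold: float = DEFAULT_FLAG_THRESHOLD
                      ) -> pd.DataFrame:
    """Per-athlete LCs, flags and ASPS for a whole feature table."""
    rows = []
    for athlete_id, row in features.iterrows():
        lc = decompose_lc(model, row[list(model.feature_names)])
        flags = flag_sources(lc, threshold)
        rec = {"athlete_id": athlete_id}
        rec.update({f"lc_{s}": lc.contribution(s) for s in SOURCES})
        rec.update({f"flag_{s}": flags.flags[s] for s in SOURCES})
        rec["asps"] = lc.asps
        rows.append(rec)
    return pd.DataFrame(rows).set_index("athlete_id")


def threshold_sweep(scores, labels) -> pd.DataFrame:
    """FPR/TPR at every candidate threshold (strict ``score > t`` rule).

    Rows are sorted by decreasing threshold; FPR and TPR are then
    non-decreasing.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    neg = scores[labels == 0]
    pos = scores[labels == 1]
    if neg.size == 0 or pos.size == 0:
        raise UndefinedAUCError("threshold sweep needs both classes")
    candidates = np.unique(scores)[::-1]
    rows = []
    for t in candidates:
        rows.append({
            "threshold": float(t),
            "fpr": float(np.mean(neg > t)),
            "tpr": float(np.mean(pos > t)),
            "n_flagged": int(np.sum(scores > t)),
        })
    df = pd.DataFrame(rows)
    df["pct_flagged"] = 100.0 * df["n_flagged"] / scores.size
    return df


def calibrate_thresholds(scores, labels,
                         fpr_targets=(0.05, 0.10, 0.20)
                         ) -> list[ThresholdRow]:
    """For each FPR target, the best operating point below the target.

    Among thresholds with empirical FPR <= target, TPR is maximised;
    within TPR ties the largest (most conservative) threshold is kept.
    Reports achieved FPR, TPR and flagged counts over all athletes.
    """
    sweep = threshold_sweep(scores, labels)
    n_neg = int(np.sum(np.asarray(labels, dtype=int) == 0))
    out = []
    for target in fpr_targets:
        if not 0.0 < target < 1.0:
            raise ValueError(f"fpr target must be in (0,1), got {target}")
        note = ""
        if 1.0 / n_neg > target:
            note = ("target below 1/n_negatives; only FPR 0 is attainable")
            logger.warning("fpr target %.3g unattainable with %d negatives",
                           target, n_neg)
        admissible = sweep[sweep["fpr"] <= target]
        best_tpr = admissible["tpr"].max()
        tied = admissible[admissible["tpr"] == best_tpr]
        row = tied.loc[tied["threshold"].idxmax()]
        out.append(ThresholdRow(
            threshold=float(row["threshold"]), fpr=float(row["fpr"]),
            tpr=float(row["tpr"]), n_flagged=int(row["n_flagged"]),
            pct_flagged=float(row["pct_flagged"]),
            target_fpr=float(target), note=note,
        ))
    return out


def thresholds_frame(rows: list[ThresholdRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
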