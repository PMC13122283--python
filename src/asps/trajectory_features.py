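"""Whole-trajectory summary features.

For a trajectory of T occasions x 5 biomarkers the base feature set is:

* 5 per-biomarker sample means                      ``mean_<b>``
* 5 per-biomarker ranges (max - min)                ``range_<b>``
* 5 ranges of first differences                     ``range_d1_<b>``
* 5 ranges of second differences                    ``range_d2_<b>``
* 10 pairwise sample covariances of levels          ``cov_<a>_<b>``
* 10 pairwise sample covariances of first diffs     ``cov_d1_<a>_<b>``

followed by the square of each base feature (suffix ``_sq``), giving 80
named features in a fixed order.  Covariance pairs are enumerated in
lexicographic order of the canonical biomarker identifiers; sample
covariance uses the n-1 denominator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    InsufficientLengthError,
    InsufficientObservationsError,
    SchemaError,
)
from .profiles import BIOMARKERS

#: Minimum occasions per trajectory (athletes with fewer are excluded).
MIN_OCCASIONS = 4

# Pair enumeration order for covariance features.
_SORTED_BIOMARKERS = tuple(sorted(BIOMARKERS))
COV_PAIRS: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations(_SORTED_BIOMARKERS, 2)
)


def _base_feature_names() -> list[str]:
    names = [f"mean_{b}" for b in BIOMARKERS]
    names += [f"range_{b}" for b in BIOMARKERS]
    names += [f"range_d1_{b}" for b in BIOMARKERS]
    names += [f"range_d2_{b}" for b in BIOMARKERS]
    names += [f"cov_{a}_{b}" for a, b in COV_PAIRS]
    names += [f"cov_d1_{a}_{b}" for a, b in COV_PAIRS]
    return names


#: The 40 base feature names in fixed order.
BASE_FEATURE_NAMES: tuple[str, ...] = tuple(_base_feature_names())

#: All 80 feature names: the 40 base features then their squares.
FEATURE_NAMES: tuple[str, ...] = BASE_FEATURE_NAMES + tuple(
    f"{n}_sq" for n in BASE_FEATURE_NAMES
)


@dataclass
class TrajectoryMatrix:
    """T x 5 grid of finite values for one athlete, tagged by kind."""

    values: pd.DataFrame
    athlete_id: str = ""
    measurement_kind: str = "original"

    def __post_init__(self) -> None:
        try:
            self.values = self.values[list(BIOMARKERS)]
        except KeyError as exc:
            raise SchemaError("trajectory columns must be the five panel "
                              f"biomarkers {BIOMARKERS}") from exc
        # complete-case by occasion: drop rows with any missing cell so
        # all series stay aligned for the covariance features
        self.values = self.values.dropna(how="any").reset_index(drop=True)
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("trajectory contains non-finite values")

    @classmethod
    def from_profile(cls, profile) -> "TrajectoryMatrix":
        return cls(values=profile.values.copy(),
                   athlete_id=profile.athlete_id,
                   measurement_kind=profile.kind)


def first_differences(series) -> np.ndarray:
    """Consecutive differences x[j+1] - x[j]; length shrinks by one."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InsufficientLengthError("need at least 2 values to difference")
    return np.diff(x)


def feature_range(series) -> float:
    """max - min of a series; 0 for a singleton."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise InsufficientLengthError("range needs a non-empty series")
    return float(x.max() - x.min())


def pairwise_covariance(a, b) -> float:
    """Sample covariance with the n-1 denominator."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InsufficientLengthError("covariance needs equal-length 1-D series")
    if a.size < 2:
        raise InsufficientLengthError("covariance needs at least 2 points")
    return float(np.cov(a, b, ddof=1)[0, 1])


def compute_feature_vector(traj: TrajectoryMatrix) -> pd.Series:
    """All 80 named features for one trajectory, in schema order."""
    T = len(traj.values)
    if T < MIN_OCCASIONS:
        raise InsufficientObservationsError(
            f"trajectory has {T} complete occasions; need >= {MIN_OCCASIONS}"
        )
    cols = {b: traj.values[b].to_numpy(dtype=float) for b in BIOMARKERS}
    d1 = {b: np.diff(cols[b]) for b in BIOMARKERS}
    d2 = {b: np.diff(d1[b]) for b in BIOMARKERS}

    out: dict[str, float] = {}
    for b in BIOMARKERS:
        out[f"mean_{b}"] = float(cols[b].mean())
    for b in BIOMARKERS:
        out[f"range_{b}"] = feature_range(cols[b])
    for b in BIOMARKERS:
        out[f"range_d1_{b}"] = feature_range(d1[b])
    for b in BIOMARKERS:
        out[f"range_d2_{b}"] = feature_range(d2[b])
    for a, b in COV_PAIRS:
        out[f"cov_{a}_{b}"] = pairwise_covariance(cols[a], cols[b])
    for a, b in COV_PAIRS:
        out[f"cov_d1_{a}_{b}"] = pairwise_covariance(d1[a], d1[b])
    for name in BASE_FEATURE_NAMES:
        out[f"{name}_sq"] = out[name] ** 2
    return pd.Series(out, index=list(FEATURE_NAMES), dtype=float)


def compute_feature_table(profiles) -> pd.DataFrame:
    """One row per athlete: 80 features plus label/weight/source columns.

    Athletes whose trajectories are shorter than ``MIN_OCCASIONS`` raise;
    callers are expected to have filtered them at ingest.
    """
    rows = []
    meta = []
    for p in profiles:
        vec = compute_feature_vector(TrajectoryMatrix.from_profile(p))
        rows.append(vec)
        meta.append((p.athlete_id, p.label, p.weight, p.source))
    table = pd.DataFrame(rows).reset_index(drop=True)
    ids, labels, weights, sources = zip(*meta)
    table.insert(0, "athlete_id", ids)
    table["label"] = labels
    table["weight"] = weights
    table["source"] = sources
    return table.set_index("athlete_id")
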