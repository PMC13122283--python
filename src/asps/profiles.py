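"""Biomarker naming and the per-athlete longitudinal profile container.

The panel tracks five urinary steroid ratios.  Column names in every
tabular interface use ASCII-safe canonical identifiers; human-readable
display names are kept for reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidMeasurementError, SchemaError

#: Canonical biomarker identifiers, in fixed panel order.
BIOMARKERS: tuple[str, ...] = ("te", "a_etio", "adiol_ratio", "adiol_e", "a_t")

#: Canonical identifier -> display name.
DISPLAY_NAMES: dict[str, str] = {
    "te": "T/E",
    "a_etio": "A/Etio",
    "adiol_ratio": "5a-ADiol/5b-ADiol",
    "adiol_e": "5a-ADiol/E",
    "a_t": "A/T",
}

# Accepted aliases (lower-cased, Greek letters normalised) -> canonical id.
_ALIASES: dict[str, str] = {
    "te": "te",
    "t/e": "te",
    "t_e": "te",
    "a_etio": "a_etio",
    "a/etio": "a_etio",
    "adiol_ratio": "adiol_ratio",
    "5a-adiol/5b-adiol": "adiol_ratio",
    "5a_adiol/5b_adiol": "adiol_ratio",
    "5a-adiol_5b-adiol": "adiol_ratio",
    "adiol_e": "adiol_e",
    "5a-adiol/e": "adiol_e",
    "5a_adiol/e": "adiol_e",
    "a_t": "a_t",
    "a/t": "a_t",
}


def canonical_biomarker(name: str) -> str:
    """Map a biomarker name or alias to its canonical identifier.

    Raises
    ------
    SchemaError
        If the name is not one of the five panel ratios.
    """
    key = str(name).strip().lower().replace("α", "a").replace("β", "b")
    key = key.replace("‐", "-").replace("‑", "-").replace("–", "-")
    if key in _ALIASES:
        return _ALIASES[key]
    raise SchemaError(f"unknown biomarker name: {name!r}")


@dataclass
class LongitudinalProfile:
    """One athlete's time-ordered panel of the five ratios.

    ``values`` is a (T occasions x 5 biomarkers) frame whose columns are
    the canonical identifiers in panel order and whose index is the
    0-based occasion number.  ``kind`` records whether the cells are raw
    ratios (``original``) or sequence probabilities (``abp_sp``).
    """

    athlete_id: str
    values: pd.DataFrame
    label: int = 0
    weight: float = 1.0
    source: str = "doping_control"
    regime: str | None = None
    kind: str = "original"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = tuple(self.values.columns)
        if cols != BIOMARKERS:
            try:
                self.values = self.values[list(BIOMARKERS)]
            except KeyError as exc:
                raise SchemaError(
                    f"profile columns {cols} do not match panel {BIOMARKERS}"
                ) from exc
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise InvalidMeasurementError(
                f"athlete {self.athlete_id}: non-finite measurement"
            )
        if np.any(arr <= 0):
            raise InvalidMeasurementError(
                f"athlete {self.athlete_id}: non-positive measurement"
            )
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label}")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        self.values = self.values.reset_index(drop=True)

    @property
    def n_occasions(self) -> int:
        return len(self.values)

    def series(self, biomarker: str) -> np.ndarray:
        """Time-ordered values of one biomarker as a float array."""
        return self.values[canonical_biomarker(biomarker)].to_numpy(dtype=float)
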