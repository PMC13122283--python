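"""Synthetic longitudinal steroid-ratio cohorts.

Generates clean and doped athlete trajectories with the structure the
scoring pipeline assumes: log-scale athlete-level random intercepts,
within-athlete Gaussian noise, additive route/dose-specific log-scale
doping effects during administration, and exponential washout decay
afterwards.  Doped trajectories include pre-dose baseline and post-dose
washout occasions.  Athlete-level variation of the T/E and 5a-ADiol/E
responses is drawn with a configurable correlation (default 0.72).

The four published administration regimes carry measured log-scale
effects; the three weekly-injection dose regimes carry order-of-
magnitude placeholder effects (no numeric estimates are published for
them), dose-ordered so higher doses give stronger responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError, EstimationError
from .profiles import BIOMARKERS, LongitudinalProfile

_SD_FLOOR = 1e-12


@dataclass(frozen=True)
class RegimeEffect:
    """One administration regime's additive log-scale biomarker effects."""

    name: str
    effects: dict  # biomarker id -> additive log-scale effect while dosed
    onset: int = 3
    duration: int = 5
    washout_half_life: float = 3.0

    def __post_init__(self) -> None:
        if self.washout_half_life <= 0:
            raise ConfigError("washout half-life must be positive")
        if set(self.effects) != set(BIOMARKERS):
            raise ConfigError(
                f"regime {self.name}: effects must cover {BIOMARKERS}")
        if not all(math.isfinite(v) for v in self.effects.values()):
            raise ConfigError(f"regime {self.name}: non-finite effect")

    def dose_profile(self, occasions: int) -> np.ndarray:
        """Multiplier on the effect at each occasion: 0 before onset, 1
        while dosing, exponential decay with the configured half-life
        afterwards."""
        t = np.arange(occasions)
        end = self.onset + self.duration
        d = np.zeros(occasions)
        dosing = (t >= self.onset) & (t < end)
        d[dosing] = 1.0
        post = t >= end
        d[post] = 0.5 ** ((t[post] - end + 1) / self.washout_half_life)
        return d


def _regime(name, te, adiol_e, adiol_ratio, a_etio, a_t, **kw) -> RegimeEffect:
    return RegimeEffect(name=name, effects={
        "te": te, "adiol_e": adiol_e, "adiol_ratio": adiol_ratio,
        "a_etio": a_etio, "a_t": a_t}, **kw)


def default_regimes() -> dict[str, RegimeEffect]:
    """The seven administration regimes with their default log effects."""
    return {r.name: r for r in (
        # measured effects (log-scale change from baseline)
        _regime("transdermal", 0.41, 0.48, 0.16, -0.05, -0.11),
        _regime("placebo", 0.32, 0.31, 0.10, -0.02, -0.14),
        _regime("intramuscular_1", 2.53, 1.93, -0.07, -0.02, -0.33),
        _regime("intramuscular_2", 2.67, 2.10, -0.08, 0.11, -0.29),
        # dose-ordered placeholders for the weekly self-injections
        _regime("injection_50", 0.80, 0.50, 0.05, 0.00, -0.05),
        _regime("injection_75", 1.20, 0.80, 0.08, 0.00, -0.10),
        _regime("injection_100", 1.60, 1.20, 0.12, 0.02, -0.15),
    )}


def _default_log_means() -> dict[str, float]:
    # order-of-magnitude placeholders for typical ratio levels
    return {"te": 0.0, "a_etio": 0.2, "adiol_ratio": 0.0,
            "adiol_e": -0.5, "a_t": 1.0}


def _const(value: float) -> dict[str, float]:
    return {b: value for b in BIOMARKERS}


@dataclass
class SimulationConfig:
    """Cohort layout and generating parameters (all log-scale)."""

    n_clean: int = 300
    n_doped: int = 40          # doping-control athletes with an ADRV label
    n_lab: int = 20            # laboratory athletes (known dopers, weight 20)
    occasions: int = 12
    log_means: dict = field(default_factory=_default_log_means)
    between_sd: dict = field(default_factory=lambda: _const(0.35))
    within_sd: dict = field(default_factory=lambda: _const(0.25))
    effect_corr: float = math.sqrt(0.52)   # T/E vs 5a-ADiol/E responses
    effect_sd: float = 0.2
    regimes: dict = field(default_factory=default_regimes)
    lab_weight: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_clean, self.n_doped, self.n_lab) < 0:
            raise ConfigError("athlete counts must be >= 0")
        if self.occasions < 1:
            raise ConfigError("occasions must be >= 1")
        if not -1.0 <= self.effect_corr <= 1.0:
            raise ConfigError("effect correlation must lie in [-1, 1]")
        if self.effect_sd < 0:
            raise ConfigError("effect_sd must be >= 0")
        for d in (self.between_sd, self.within_sd):
            if any(v < 0 for v in d.values()):
                raise ConfigError("SDs must be non-negative")

    def scaled_effects(self, te: float | None = None) -> "SimulationConfig":
        """Copy with every regime's T/E effect overridden (dose sweeps)."""
        regimes = {}
        for name, r in self.regimes.items():
            eff = dict(r.effects)
            if te is not None:
                eff["te"] = te
            regimes[name] = replace(r, effects=eff)
        return replace(self, regimes=regimes)


@dataclass
class SimulatedCohort:
    """Profiles plus the generating truth, for recovery tests."""

    profiles: list
    config: SimulationConfig

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"athlete_id": p.athlete_id, "label": p.label,
             "source": p.source, "regime": p.regime or ""}
            for p in self.profiles
        ]).set_index("athlete_id")

    def to_frame(self) -> pd.DataFrame:
        """Wide longitudinal table: one row per athlete-occasion."""
        rows = []
        for p in self.profiles:
            for t in range(p.n_occasions):
                rec = {"athlete_id": p.athlete_id, "occasion": t,
                       "label": p.label, "source": p.source,
                       "regime": p.regime or ""}
                for b in BIOMARKERS:
                    rec[b] = p.values.at[t, b]
                rows.append(rec)
        return pd.DataFrame(rows)


def _athlete_effects(config: SimulationConfig, regime: RegimeEffect,
                     rng: np.random.Generator) -> dict[str, float]:
    """Per-athlete realised effects: base + correlated Gaussian spread."""
    rho = config.effect_corr
    z = rng.standard_normal(len(BIOMARKERS))
    # index 0 = te, 3 = adiol_e in panel order; correlate those two draws
    eps = dict(zip(BIOMARKERS, z))
    eps["adiol_e"] = rho * eps["te"] + math.sqrt(1 - rho ** 2) * eps["adiol_e"]
    return {b: regime.effects[b] + config.effect_sd * eps[b]
            for b in BIOMARKERS}


def simulate_athlete(config: SimulationConfig,
                     regime: RegimeEffect | None,
                     rng: np.random.Generator,
                     athlete_id: str = "A0",
                     source: str = "doping_control") -> LongitudinalProfile:
    """One athlete's trajectory; doped iff ``regime`` is given."""
    T = config.occasions
    data = {}
    effects = _athlete_effects(config, regime, rng) if regime else None
    dose = regime.dose_profile(T) if regime else np.zeros(T)
    for b in BIOMARKERS:
        intercept = (config.log_means[b]
                     + max(config.between_sd[b], _SD_FLOOR)
                     * rng.standard_normal())
        noise = max(config.within_sd[b], _SD_FLOOR) * rng.standard_normal(T)
        logy = intercept + noise
        if effects is not None:
            logy = logy + effects[b] * dose
        data[b] = np.exp(logy)
    doped = regime is not None
    return LongitudinalProfile(
        athlete_id=athlete_id,
        values=pd.DataFrame(data, columns=list(BIOMARKERS)),
        label=int(doped),
        weight=config.lab_weight if source == "laboratory" else 1.0,
        source=source,
        regime=regime.name if regime else None,
        meta={"effects": effects} if effects else {},
    )


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Full cohort: clean + doped doping-control athletes + laboratory
    athletes, with doped regimes assigned uniformly at random."""
    rng = np.random.default_rng(config.seed)
    regime_names = sorted(config.regimes)
    profiles = []
    for i in range(config.n_clean):
        profiles.append(simulate_athlete(config, None, rng,
                                         athlete_id=f"C{i:04d}"))
    for i in range(config.n_doped):
        r = config.regimes[regime_names[rng.integers(len(regime_names))]]
        profiles.append(simulate_athlete(config, r, rng,
                                         athlete_id=f"D{i:04d}"))
    for i in range(config.n_lab):
        r = config.regimes[regime_names[rng.integers(len(regime_names))]]
        profiles.append(simulate_athlete(config, r, rng,
                                         athlete_id=f"L{i:04d}",
                                         source="laboratory"))
    return SimulatedCohort(profiles=profiles, config=config)


def recover_effects(cohort: SimulatedCohort) -> pd.DataFrame:
    """Moment recovery of per-regime log effects from a cohort.

    For each doped athlete the change from baseline is the mean dosed-
    occasion log value minus the mean pre-onset log value; the regime
    estimate averages over its athletes, with a normal-approximation SE.
    """
    doped = [p for p in cohort.profiles if p.regime is not None]
    if not doped:
        raise EstimationError("cohort has no doped athletes")
    rows = []
    for name, regime in cohort.config.regimes.items():
        athletes = [p for p in doped if p.regime == name]
        if not athletes:
            continue
        dose = regime.dose_profile(cohort.config.occasions)
        dosed = np.flatnonzero(dose == 1.0)
        baseline = np.arange(regime.onset)
        for b in BIOMARKERS:
            deltas = np.array([
                np.log(p.series(b))[dosed].mean()
                - np.log(p.series(b))[baseline].mean()
                for p in athletes
            ])
            se = (deltas.std(ddof=1) / math.sqrt(len(deltas))
                  if len(deltas) > 1 else float("nan"))
            rows.append({"regime": name, "biomarker": b,
                         "estimate": float(deltas.mean()), "se": float(se),
                         "n_athletes": len(athletes),
                         "true_effect": regime.effects[b]})
    return pd.DataFrame(rows)
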