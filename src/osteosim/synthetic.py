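"""Synthetic stand-ins for model inputs that were used but never printed.

The published analysis drew on three data sources that cannot be reproduced
from the printed tables: the simulated patient population (only its summary
statistics are given), the 2004 French all-cause female life table, and the
post-fracture excess-mortality adjustments.  This module generates explicit,
clearly-flagged synthetic versions of each, plus small DRG cost tables that
exercise the weighted-average hospital-costing method on the printed
aggregates.

Everything here is seeded and writes/reads plain CSV so a run is fully
reproducible from its manifest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.stats import truncnorm

from .params import ModelParameters


class PopulationSpec(BaseModel):
    """Baseline cohort description: truncated-normal age, Bernoulli prior fracture.

    Defaults match the published cohort summary: mean age 70.5 y, SD 9.7 y,
    59.7% with a prior fracture.  Ages are truncated to [50, 100] because the
    fracture-risk table is undefined below 50.
    """

    mean_age: float = 70.5
    sd_age: float = Field(gt=0, default=9.7)
    age_min: float = 50.0
    age_max: float = 100.0
    prior_fracture_prevalence: float = Field(ge=0.0, le=1.0, default=0.597)

    @model_validator(mode="after")
    def _bounds(self) -> "PopulationSpec":
        if not (self.age_min < self.mean_age < self.age_max):
            raise ValueError("mean_age must lie inside the truncation bounds")
        return self


def generate_population(spec: PopulationSpec, n: int, seed: int) -> pd.DataFrame:
    """Draw a baseline cohort: DataFrame(id, age, prior_fracture).

    Ages are drawn from a normal truncated to ``[age_min, age_max]``;
    prior-fracture flags are independent Bernoulli draws.  Identical
    (spec, n, seed) gives a byte-identical frame.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    a = (spec.age_min - spec.mean_age) / spec.sd_age
    b = (spec.age_max - spec.mean_age) / spec.sd_age
    ages = truncnorm.rvs(a, b, loc=spec.mean_age, scale=spec.sd_age, size=n, random_state=rng)
    prior = rng.uniform(size=n) < spec.prior_fracture_prevalence
    return pd.DataFrame({"id": np.arange(n), "age": ages, "prior_fracture": prior})


# Default Gompertz anchors: q(70) = 0.012 with mortality doubling every 8
# years.  These are synthetic stand-ins for the unprinted 2004 national
# female rates, not estimates of them.
DEFAULT_GOMPERTZ_SHAPE = math.log(2.0) / 8.0
DEFAULT_GOMPERTZ_SCALE = 0.012 * math.exp(-DEFAULT_GOMPERTZ_SHAPE * 70.0)


@dataclass
class LifeTable:
    """Age → annual all-cause death probability, integer ages 50..110.

    The terminal age is forced to q = 1 so no simulated woman outlives the
    table.  ``synthetic`` flags that the values are generated stand-ins.
    """

    ages: np.ndarray
    q: np.ndarray
    synthetic: bool = True

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.q = np.asarray(self.q, dtype=float)
        if self.ages.shape != self.q.shape:
            raise ValueError("ages and q must have the same length")
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("death probabilities must be in [0, 1]")
        if self.q[-1] != 1.0:
            raise ValueError("terminal-age death probability must be 1")

    def annual_death_probability(self, age):
        """q at integer age; ages outside the range clamp to the end rows."""
        idx = np.clip(np.floor(np.asarray(age, dtype=float)).astype(int) - self.ages[0],
                      0, len(self.ages) - 1)
        out = self.q[idx]
        return float(out) if np.isscalar(age) else out

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "q": self.q}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(ages=df["age"].to_numpy(), q=df["q"].to_numpy())


def synthetic_life_table(
    scale: float = DEFAULT_GOMPERTZ_SCALE,
    shape: float = DEFAULT_GOMPERTZ_SHAPE,
    age_min: int = 50,
    age_max: int = 110,
) -> LifeTable:
    """Gompertz life table q(age) = min(1, scale·exp(shape·age)), q(age_max)=1."""
    if scale <= 0 or shape <= 0:
        raise ValueError("Gompertz scale and shape must be positive")
    ages = np.arange(age_min, age_max + 1)
    q = np.minimum(1.0, scale * np.exp(shape * ages))
    q[-1] = 1.0
    return LifeTable(ages=ages, q=q)


class ExcessMortality(BaseModel):
    """Post-fracture excess-mortality hazard multipliers (synthetic stand-ins).

    The published model adjusted mortality after hip and clinically diagnosed
    vertebral fractures using external data it did not print; defaults here
    (2.5 post-hip, 2.0 post-clinical-vertebral, 1-year window) are explicit
    synthetic assumptions and fully configurable.
    """

    hip: float = Field(ge=1.0, default=2.5)
    clinical_vertebral: float = Field(ge=1.0, default=2.0)
    window_years: float = Field(gt=0, default=1.0)
    synthetic: bool = True


class DRGRow(BaseModel):
    """One disease-related group: stay count and unit cost per stay (€)."""

    drg_id: str
    count: int = Field(ge=0)
    unit_cost: float = Field(ge=0.0)


class DRGCostTable(BaseModel):
    """Hospital stays grouped by DRG, for weighted-average unit costing."""

    rows: list[DRGRow]

    @model_validator(mode="after")
    def _some_stays(self) -> "DRGCostTable":
        if not any(r.count > 0 for r in self.rows):
            raise ValueError("DRG table needs at least one row with count > 0")
        return self

    @property
    def total_stays(self) -> int:
        return sum(r.count for r in self.rows)

    @property
    def total_cost(self) -> float:
        return float(sum(r.count * r.unit_cost for r in self.rows))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.model_dump() for r in self.rows])

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DRGCostTable":
        df = pd.read_csv(path)
        return cls(rows=[DRGRow(**row) for row in df.to_dict("records")])


# Synthetic DRG fixtures.  The vertebra preset decomposes the printed national
# aggregate exactly (26,490 stays, €93,325,278) into three plausible DRG rows;
# hip and wrist reproduce the printed stay counts and per-stay weighted
# averages (their printed aggregates are inconsistent with those averages and
# are not reproduced).  The toy preset is a 2-row table for unit tests.
_DRG_PRESETS: dict[str, list[tuple[str, int, float]]] = {
    "vertebra": [
        ("V-DRG-01", 12000, 2701.0),
        ("V-DRG-02", 11304, 2000.0),
        ("V-DRG-03", 3186, 12023.0),
    ],
    "hip": [
        ("H-DRG-01", 26688, 8000.0),
        ("H-DRG-02", 26688, 6616.0),
    ],
    "wrist": [
        ("W-DRG-01", 5197, 2000.0),
        ("W-DRG-02", 5197, 1688.0),
    ],
    "toy": [
        ("T-DRG-01", 1, 100.0),
        ("T-DRG-02", 3, 200.0),
    ],
}


def fixture_drg_table(preset: str) -> DRGCostTable:
    """A synthetic DRG cost table for one of the presets vertebra|hip|wrist|toy."""
    try:
        rows = _DRG_PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown DRG preset {preset!r}; choose from {sorted(_DRG_PRESETS)}")
    return DRGCostTable(rows=[DRGRow(drg_id=d, count=n, unit_cost=c) for d, n, c in rows])


def write_manifest(
    path: str | Path,
    seed: int,
    params: ModelParameters | None = None,
    **extra,
) -> None:
    """Record a run manifest (seed, parameter hash, extras) as JSON."""
    import hashlib

    payload: dict = {"seed": seed, **extra}
    if params is not None:
        blob = params.model_dump_json().encode()
        payload["params_sha256"] = hashlib.sha256(blob).hexdigest()
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
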