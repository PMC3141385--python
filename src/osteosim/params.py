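"""Validated model parameters for the bisphosphonate persistence cost model.

Every clinical and economic input of the model lives here as a pydantic
structure: age-band absolute fracture risks, relative risks by health state,
treatment risk multipliers while protected, the persistence and
residual-protection coefficients, costs, and simulation settings.  The default
bundle reproduces the published French base case (euros 2010, generic
alendronate pricing, 5% annual discounting, 10-year horizon).

Percent-scale inputs are converted to probabilities exactly once, at
construction or file import; everything downstream works on probabilities.
"""

from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class Site(str, Enum):
    """Fracture site (the three best-documented osteoporotic sites)."""

    VERTEBRA = "vertebra"
    HIP = "hip"
    WRIST = "wrist"


SITES: tuple[Site, Site, Site] = (Site.VERTEBRA, Site.HIP, Site.WRIST)


class HealthState(str, Enum):
    """Mutually exclusive Markov health states (plus absorbing death)."""

    PMO = "pmo"
    POST_VERTEBRAL = "post_vertebral"
    POST_HIP = "post_hip"
    POST_WRIST = "post_wrist"
    DEAD = "dead"


#: Living states in engine index order.
LIVING_STATES = (
    HealthState.PMO,
    HealthState.POST_VERTEBRAL,
    HealthState.POST_HIP,
    HealthState.POST_WRIST,
)


class Alternative(str, Enum):
    """The three persistence alternatives compared by the analysis."""

    NO_TREATMENT = "no_treatment"
    REAL_WORLD = "real_world"
    IDEAL = "ideal"


class AgeBandRisk(BaseModel):
    """Annual absolute fracture probabilities for one age band.

    ``age_hi`` is ``None`` for the open-ended oldest band.  Values are
    probabilities per year (a printed 5.56 %/year is stored as 0.0556).
    """

    age_lo: float = Field(ge=0)
    age_hi: Optional[float] = None
    vertebra: float = Field(ge=0.0, le=1.0)
    hip: float = Field(ge=0.0, le=1.0)
    wrist: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _ordered(self) -> "AgeBandRisk":
        if self.age_hi is not None and self.age_hi <= self.age_lo:
            raise ValueError(f"age_hi {self.age_hi} must exceed age_lo {self.age_lo}")
        return self

    def risk(self, site: Site) -> float:
        return float(getattr(self, Site(site).value))


class FractureRiskTable(BaseModel):
    """Piecewise-constant age-specific annual absolute fracture risks.

    Bands must be contiguous starting at 50 years and end with one open-ended
    band; ages beyond the last closed band use the open-ended band.
    """

    bands: list[AgeBandRisk]

    @model_validator(mode="after")
    def _contiguous(self) -> "FractureRiskTable":
        if not self.bands:
            raise ValueError("risk table needs at least one band")
        if self.bands[0].age_lo != 50:
            raise ValueError("first age band must start at 50")
        for prev, cur in zip(self.bands, self.bands[1:]):
            if prev.age_hi is None:
                raise ValueError("only the last band may be open-ended")
            if cur.age_lo != prev.age_hi:
                raise ValueError(
                    f"bands must be contiguous: {prev.age_hi} then {cur.age_lo}"
                )
        if self.bands[-1].age_hi is not None:
            raise ValueError("last band must be open-ended")
        return self

    @property
    def min_age(self) -> float:
        return self.bands[0].age_lo

    def band_index(self, age: float) -> int:
        if age < self.min_age:
            raise ValueError(f"age {age} below risk-table support ({self.min_age})")
        for i, band in enumerate(self.bands):
            if band.age_hi is None or age < band.age_hi:
                return i
        return len(self.bands) - 1

    def lookup(self, age: float, site: Site) -> float:
        return self.bands[self.band_index(age)].risk(site)


def lookup_absolute_risk(table: FractureRiskTable, age: float, site: Site) -> float:
    """Annual absolute fracture probability for (age, site); piecewise constant."""
    return table.lookup(age, site)


class RelativeRiskSet(BaseModel):
    """Relative risks by history/state and treatment risk multipliers.

    ``prior_fracture`` applies in the entry state when the woman had any
    fracture before baseline; ``post_state`` replaces (not multiplies) it after
    an on-model fracture.  ``treatment`` holds the risk multipliers applied
    while the woman is under effective drug protection (values < 1 are
    protective).  ``None`` marks cells the source evidence does not cover; the
    resolution policy (nearest printed value) is explicit in the accessors and
    can be overridden by filling the cells in a parameter file.
    """

    prior_fracture: dict[Site, float]
    post_state: dict[HealthState, dict[Site, Optional[float]]]
    treatment: dict[HealthState, dict[Site, Optional[float]]]

    @field_validator("prior_fracture")
    @classmethod
    def _positive(cls, v: dict[Site, float]) -> dict[Site, float]:
        for site, rr in v.items():
            if not rr > 0:
                raise ValueError(f"prior_fracture[{site}] must be > 0, got {rr}")
        return v

    @field_validator("post_state")
    @classmethod
    def _post_positive(cls, v):
        for state, row in v.items():
            for site, rr in row.items():
                if rr is not None and not rr > 0:
                    raise ValueError(f"post_state[{state}][{site}] must be > 0")
        return v

    @field_validator("treatment")
    @classmethod
    def _protective(cls, v):
        for state, row in v.items():
            for site, m in row.items():
                if m is not None and not (0 < m <= 1):
                    raise ValueError(
                        f"treatment[{state}][{site}] must be in (0, 1], got {m}"
                    )
        return v

    def state_rr(self, state: HealthState, site: Site, prior: bool) -> float:
        """Resolved fracture RR for a living state; NA falls back to the
        baseline any-prior-fracture RR for that site."""
        state, site = HealthState(state), Site(site)
        if state == HealthState.PMO:
            return self.prior_fracture[site] if prior else 1.0
        rr = self.post_state[state][site]
        return self.prior_fracture[site] if rr is None else rr

    def treatment_multiplier(self, state: HealthState, site: Site) -> float:
        """Resolved protective risk multiplier; NA falls back to the baseline
        (entry-state) multiplier for that site."""
        state, site = HealthState(state), Site(site)
        m = self.treatment[state][site]
        return self.treatment[HealthState.PMO][site] if m is None else m


class PersistenceParams(BaseModel):
    """Fitted logarithmic persistence curve P(T) = 1 - b·ln(T) with a floor.

    ``b`` is the fitted log coefficient (0.196 for weekly regimens), the curve
    is clamped to 1 for T ≤ ``min_duration_months`` and to ``floor`` from
    ``floor_onset_months`` (60) onwards.
    """

    b: float = Field(gt=0, lt=1)
    floor: float = Field(ge=0.0, le=1.0)
    floor_onset_months: float = Field(gt=0)
    min_duration_months: float = Field(gt=0, default=1.0)


class ResidualEffectParams(BaseModel):
    """Residual protection y(T) = scale·exp(rate·T) months, with y(0) = 0."""

    scale_months: float = Field(gt=0)
    rate_per_month: float = Field(gt=0)


class CostParams(BaseModel):
    """Economic inputs: fracture management costs, drug prices, discounting."""

    management_cost: dict[Site, float]
    drug_price_per_12_weeks: float = Field(ge=0)
    branded_price_per_12_weeks: float = Field(ge=0)
    weeks_per_year: float = Field(gt=0, default=52.0)
    discount_rate: float = Field(ge=0.0, lt=1.0)
    symptomatic_vertebral_fraction: float = Field(ge=0.0, le=1.0)
    national_population: int = Field(gt=0)
    horizon_years: int = Field(gt=0)

    @field_validator("management_cost")
    @classmethod
    def _nonneg(cls, v):
        for site, c in v.items():
            if c < 0:
                raise ValueError(f"management_cost[{site}] must be >= 0")
        return v


class SimulationSettings(BaseModel):
    """Run-level knobs: cohort size, annual cycles, seed, alternative."""

    n_patients: int = Field(ge=1)
    n_cycles: int = Field(ge=1, default=10)
    seed: int = 0
    alternative: Alternative = Alternative.NO_TREATMENT


class ModelParameters(BaseModel):
    """Complete validated parameter bundle for one model configuration."""

    risk_table: FractureRiskTable
    relative_risks: RelativeRiskSet
    persistence: PersistenceParams
    residual: ResidualEffectParams
    costs: CostParams


# Published base-case inputs.  Absolute risks are the printed %/year figures
# divided by 100; NA cells are None and resolved by RelativeRiskSet accessors.
_DEFAULT = {
    "risk_table": {
        "bands": [
            {"age_lo": 50, "age_hi": 55, "vertebra": 0.0310, "hip": 0.0000, "wrist": 0.0299},
            {"age_lo": 55, "age_hi": 60, "vertebra": 0.0359, "hip": 0.0006, "wrist": 0.0320},
            {"age_lo": 60, "age_hi": 65, "vertebra": 0.0415, "hip": 0.0020, "wrist": 0.0318},
            {"age_lo": 65, "age_hi": 70, "vertebra": 0.0481, "hip": 0.0034, "wrist": 0.0206},
            {"age_lo": 70, "age_hi": 75, "vertebra": 0.0556, "hip": 0.0065, "wrist": 0.0197},
            {"age_lo": 75, "age_hi": 80, "vertebra": 0.0644, "hip": 0.0104, "wrist": 0.0117},
            {"age_lo": 80, "age_hi": 85, "vertebra": 0.0745, "hip": 0.0162, "wrist": 0.0092},
            {"age_lo": 85, "age_hi": None, "vertebra": 0.0862, "hip": 0.0352, "wrist": 0.0092},
        ]
    },
    "relative_risks": {
        "prior_fracture": {"vertebra": 2.0, "hip": 2.0, "wrist": 1.9},
        "post_state": {
            "post_vertebral": {"vertebra": 4.4, "hip": 2.3, "wrist": 1.4},
            "post_hip": {"vertebra": 2.5, "hip": 2.3, "wrist": None},
            "post_wrist": {"vertebra": 1.7, "hip": 1.9, "wrist": 3.3},
        },
        "treatment": {
            "pmo": {"vertebra": 0.526, "hip": 0.672, "wrist": 0.833},
            "post_vertebral": {"vertebra": 0.575, "hip": 0.620, "wrist": None},
            "post_hip": {"vertebra": None, "hip": 0.620, "wrist": None},
            "post_wrist": {"vertebra": 0.575, "hip": 0.620, "wrist": 0.566},
        },
    },
    "persistence": {
        "b": 0.196,
        "floor": 0.20,
        "floor_onset_months": 60.0,
        "min_duration_months": 1.0,
    },
    "residual": {"scale_months": 13.5, "rate_per_month": 0.048},
    "costs": {
        "management_cost": {"hip": 11419.0, "wrist": 3305.0, "vertebra": 5872.0},
        "drug_price_per_12_weeks": 52.23,
        "branded_price_per_12_weeks": 87.46,
        "weeks_per_year": 52.0,
        "discount_rate": 0.05,
        "symptomatic_vertebral_fraction": 0.23,
        "national_population": 1_130_000,
        "horizon_years": 10,
    },
}


def default_parameters() -> ModelParameters:
    """The published base case: generic pricing, 5% discounting, 10 years."""
    return ModelParameters.model_validate(_DEFAULT)


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter bundle to JSON or YAML (chosen by file suffix)."""
    path = Path(path)
    payload = params.model_dump(mode="json")
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def load_parameters(path: str | Path) -> ModelParameters:
    """Load and validate a parameter bundle from JSON or YAML."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return ModelParameters.model_validate(payload)


def risk_table_from_csv(path: str | Path, percent: bool = True) -> FractureRiskTable:
    """Import a risk table from CSV (columns age_lo, age_hi, vertebra, hip, wrist).

    With ``percent=True`` (the printed convention) values are %/year and are
    divided by 100 once here.  An empty/missing ``age_hi`` marks the open band.
    """
    df = pd.read_csv(path)
    scale = 0.01 if percent else 1.0
    bands = []
    for _, row in df.iterrows():
        hi = row["age_hi"]
        bands.append(
            AgeBandRisk(
                age_lo=float(row["age_lo"]),
                age_hi=None if pd.isna(hi) else float(hi),
                vertebra=float(row["vertebra"]) * scale,
                hip=float(row["hip"]) * scale,
                wrist=float(row["wrist"]) * scale,
            )
        )
    return FractureRiskTable(bands=bands)


def risk_table_to_csv(table: FractureRiskTable, path: str | Path, percent: bool = True) -> None:
    scale = 100.0 if percent else 1.0
    rows = [
        {
            "age_lo": b.age_lo,
            "age_hi": b.age_hi,
            "vertebra": b.vertebra * scale,
            "hip": b.hip * scale,
            "wrist": b.wrist * scale,
        }
        for b in table.bands
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
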