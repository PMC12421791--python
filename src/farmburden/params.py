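"""Model parameters for the human-capital fatality costing.

Everything the costing engine consumes is collected here so that a single
YAML/JSON file fully determines a run: the retirement (FTE) trajectory, the
friction fraction, the discount rate, household-production window and value,
fixed direct-cost components, the compensation payout for work-related
deaths, the workers'-compensation coverage fraction, plus the three lookup
schedules (life table, occupation earnings, CPI).

Magnitudes the source material does not publish — the earnings schedule,
fixed direct costs, the compensation payout and the annual value of
household production — ship as clearly-labelled PLACEHOLDER defaults in
plausible Australian ranges; every one of them flows from configuration and
none is hard-coded in the costing logic.
"""

from __future__ import annotations

import bisect
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq


class ConfigurationError(ValueError):
    """A parameter set is incomplete or inconsistent for the requested case."""


# --------------------------------------------------------------------------
# Lookup schedules
# --------------------------------------------------------------------------

class LifeTable(BaseModel):
    """Remaining life expectancy (years) by integer age and sex.

    ``expectancy[sex]`` is a list indexed by age 0..max_age.  Values must be
    positive and non-increasing in age within each sex.
    """

    expectancy: dict[str, list[float]]

    @model_validator(mode="after")
    def _check(self) -> "LifeTable":
        for sex, ex in self.expectancy.items():
            arr = np.asarray(ex)
            if not (arr > 0).all():
                raise ValueError(f"life table for {sex!r} has non-positive entries")
            if (np.diff(arr) > 1e-12).any():
                raise ValueError(f"life table for {sex!r} is not non-increasing in age")
        return self

    def remaining_years(self, age: int, sex: str) -> float:
        try:
            ex = self.expectancy[sex]
        except KeyError:
            raise ConfigurationError(f"life table does not cover sex {sex!r}") from None
        if not 0 <= age < len(ex):
            raise ConfigurationError(
                f"life table for {sex!r} does not cover age {age} (max {len(ex) - 1})"
            )
        return ex[age]


def synthetic_life_table(
    e0_male: float = 77.8,
    e0_female: float = 82.8,
    max_age: int = 109,
    gompertz_b: float = 0.095,
) -> LifeTable:
    """Synthetic stand-in for official period life tables.

    The real life tables are licensed statistical outputs that are not
    redistributed with this package.  This generator produces a smooth
    Gompertz-mortality life table (force of mortality ``A·exp(B·age)``)
    with ``A`` calibrated so life expectancy at birth matches the published
    male/female values; remaining expectancies at working ages land within
    roughly a year of the official 2002–04 Australian figures, which is
    ample for a placeholder schedule.
    """
    ages = np.linspace(0.0, 120.0, 1201)

    def expectancies(a: float) -> np.ndarray:
        # survival S(x) = exp(-A/B (e^{Bx} - 1)); e(x) = ∫_x S/S(x)
        cum_haz = (a / gompertz_b) * (np.exp(gompertz_b * ages) - 1.0)
        surv = np.exp(-cum_haz)
        tail = cumulative_trapezoid(surv[::-1], dx=0.1, initial=0.0)[::-1]
        # survival underflows at extreme ages during calibration; floor it
        return tail / np.maximum(surv, 1e-290)

    table: dict[str, list[float]] = {}
    for sex, e0 in (("male", e0_male), ("female", e0_female)):
        a = brentq(lambda A: expectancies(A)[0] - e0, 1e-6, 1e-2)
        ex = expectancies(a)
        table[sex] = [float(ex[i * 10]) for i in range(max_age + 1)]
    return LifeTable(expectancy=table)


class EarningsSchedule(BaseModel):
    """Annual gross earnings (AUD) by occupation classification code.

    Codes are matched on the longest prefix, so a 1-digit major-group entry
    covers all 6-digit codes beneath it.  ``default_earnings`` is applied to
    unmatched codes or cases with no recorded occupation; set it to ``None``
    to make an unmatched occupation a hard configuration error.
    """

    earnings: dict[str, float]
    default_earnings: float | None = 65_000.0

    @field_validator("earnings")
    @classmethod
    def _positive(cls, v: dict[str, float]) -> dict[str, float]:
        for code, val in v.items():
            if val <= 0:
                raise ValueError(f"earnings for {code!r} must be > 0, got {val}")
        return v

    def annual_earnings(self, occupation_code: str | None) -> float:
        if occupation_code:
            for length in range(len(occupation_code), 0, -1):
                hit = self.earnings.get(occupation_code[:length])
                if hit is not None:
                    return hit
        if self.default_earnings is None:
            raise ConfigurationError(
                f"occupation code {occupation_code!r} is unmatched and no "
                "default_earnings is configured"
            )
        return self.default_earnings


class CPISeries(BaseModel):
    """Consumer price index by calendar year, used to express nominal
    amounts in base-year (default 2023) dollars."""

    index: dict[int, float]
    base_year: int = 2023

    @model_validator(mode="after")
    def _check(self) -> "CPISeries":
        for year, val in self.index.items():
            if val <= 0:
                raise ValueError(f"CPI index for {year} must be > 0, got {val}")
        if self.base_year not in self.index:
            raise ValueError(f"CPI series is missing its base year {self.base_year}")
        return self

    def value(self, year: int) -> float:
        try:
            return self.index[year]
        except KeyError:
            raise ConfigurationError(f"CPI series has no entry for year {year}") from None


# --------------------------------------------------------------------------
# Cost parameters
# --------------------------------------------------------------------------

class CostParameters(BaseModel):
    """Every constant of the human-capital fatality costing model."""

    friction_fraction: float = Field(0.25, ge=0.0, le=1.0)
    discount_rate: float = Field(0.03, ge=0.0)

    #: Labour-force entry age: no earnings accrue below it.
    entry_age: int = 16
    #: FTE anchor points (age, fte). Working ages up to the first anchor get
    #: its value; beyond the last anchor the last value applies.
    fte_anchors: list[tuple[int, float]] = [(71, 0.9), (75, 0.5), (76, 0.0)]
    fte_interpolation: Literal["linear", "step"] = "linear"

    hp_start_age: int = 16
    hp_end_age_male: int = 76
    hp_end_age_female: int = 82
    #: PLACEHOLDER: annual value of unpaid household production, AUD.
    hp_annual_value: float = Field(25_000.0, ge=0.0)

    #: PLACEHOLDER magnitudes for the fixed direct-cost components, AUD.
    fixed_costs: dict[str, float] = {
        "funeral": 10_000.0,
        "coronial": 5_000.0,
        "investigation_whs_police": 25_000.0,
        "emergency_response": 10_000.0,
    }
    #: PLACEHOLDER: lump-sum compensation payout, applied iff work-related.
    compensation_payout: float = Field(600_000.0, ge=0.0)

    coverage_fraction: float = Field(0.58, gt=0.0, le=1.0)
    #: Multiplicative uplift applied to claim costs for workforce not covered
    #: by workers' compensation (the published convention).
    under_coverage_factor: float = Field(0.4, ge=0.0)

    base_year: int = 2023

    @field_validator("fixed_costs")
    @classmethod
    def _nonneg(cls, v: dict[str, float]) -> dict[str, float]:
        for name, val in v.items():
            if val < 0:
                raise ValueError(f"fixed cost {name!r} must be >= 0, got {val}")
        return v

    @model_validator(mode="after")
    def _check_anchors(self) -> "CostParameters":
        ages = [a for a, _ in self.fte_anchors]
        ftes = [f for _, f in self.fte_anchors]
        if ages != sorted(ages) or len(set(ages)) != len(ages):
            raise ValueError("fte_anchors must have strictly increasing ages")
        if any(not 0.0 <= f <= 1.0 for f in ftes):
            raise ValueError("fte values must lie in [0, 1]")
        if any(b > a for a, b in zip(ftes, ftes[1:])):
            raise ValueError("fte_anchors must be non-increasing")
        return self

    def fte_at(self, age: float) -> float:
        """FTE worked at ``age`` under the configured retirement trajectory."""
        if age < 0:
            raise ValueError(f"age must be non-negative, got {age}")
        if age < self.entry_age:
            return 0.0
        ages = [a for a, _ in self.fte_anchors]
        ftes = [f for _, f in self.fte_anchors]
        if age <= ages[0]:
            return ftes[0]
        if age >= ages[-1]:
            return ftes[-1]
        i = bisect.bisect_right(ages, age)
        if self.fte_interpolation == "step":
            return ftes[i - 1]
        a0, a1 = ages[i - 1], ages[i]
        f0, f1 = ftes[i - 1], ftes[i]
        return f0 + (f1 - f0) * (age - a0) / (a1 - a0)

    def hp_end_age(self, sex: str) -> int:
        if sex == "male":
            return self.hp_end_age_male
        if sex == "female":
            return self.hp_end_age_female
        raise ConfigurationError(f"household production window undefined for sex {sex!r}")


class ParameterSet(BaseModel):
    """Bundle of cost parameters plus the three lookup schedules."""

    cost: CostParameters = CostParameters()
    life_table: LifeTable = None  # type: ignore[assignment]
    earnings: EarningsSchedule = None  # type: ignore[assignment]
    cpi: CPISeries = None  # type: ignore[assignment]

    @model_validator(mode="before")
    @classmethod
    def _fill_defaults(cls, data):
        if isinstance(data, dict):
            data.setdefault("life_table", synthetic_life_table())
            data.setdefault("earnings", default_earnings_schedule())
            data.setdefault("cpi", default_cpi_series())
        return data


#: PLACEHOLDER occupation earnings (nominal AUD/year, mid-period levels),
#: keyed by standard occupation major/minor-group prefixes.
def default_earnings_schedule() -> EarningsSchedule:
    return EarningsSchedule(
        earnings={
            "1211": 85_000.0,   # crop farmers / farm managers
            "1212": 82_000.0,   # livestock farmers
            "121": 80_000.0,    # farmers and farm managers, other
            "3": 70_000.0,      # technicians and trades
            "7": 62_000.0,      # machinery operators and drivers
            "8414": 52_000.0,   # farm, forestry and garden labourers
            "84": 54_000.0,     # labourers, other
        },
        default_earnings=65_000.0,
    )


#: Approximate Australian all-groups CPI, calendar-year averages
#: (index reference period 2011-12 = 100).
def default_cpi_series() -> CPISeries:
    return CPISeries(
        index={
            2013: 102.8,
            2014: 105.4,
            2015: 106.9,
            2016: 108.3,
            2017: 110.4,
            2018: 112.6,
            2019: 114.4,
            2020: 115.4,
            2021: 118.2,
            2022: 126.1,
            2023: 133.0,
        },
        base_year=2023,
    )


def default_parameter_set() -> ParameterSet:
    return ParameterSet()


# --------------------------------------------------------------------------
# YAML round-trip
# --------------------------------------------------------------------------

def load_parameter_set(path: str | Path) -> ParameterSet:
    """Load a :class:`ParameterSet` from a YAML (or JSON) file.

    Missing top-level sections fall back to the packaged defaults.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"parameter file {path} must contain a mapping")
    # YAML mapping keys arrive as strings; CPI years must be ints
    if "cpi" in raw and isinstance(raw["cpi"], dict) and "index" in raw["cpi"]:
        raw["cpi"]["index"] = {int(k): v for k, v in raw["cpi"]["index"].items()}
    return ParameterSet.model_validate(raw)


def dump_parameter_set(params: ParameterSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params.model_dump(mode="json"), fh, sort_keys=True)
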