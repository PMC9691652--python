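"""Model inputs: costs, utilities, transition structure, analysis settings.

All monetary quantities are 2021 Chinese Yuan (CNY) unless stated otherwise.
Utilities for the live NYHA states are stored on a *monthly* scale (annual
utility / 12), matching the one-month cycle length; one-time disutilities
(procedure, complications, HF hospitalization) are stored as positive
magnitudes and subtracted where they apply.

Source-cost arithmetic is reproduced here rather than hard-coded: the monthly
OMT cost and the HF-hospitalization cost are weighted means of published
per-patient costs in USD, converted at the source-era exchange rate and
inflated along a healthcare CPI chain to 2021 CNY.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

NYHA_STATES: tuple[str, ...] = ("nyha1", "nyha2", "nyha3", "nyha4")
STATES: tuple[str, ...] = NYHA_STATES + ("dead",)
ARMS: tuple[str, ...] = ("mitraclip", "omt")

#: z-quantile spanned by a 95% confidence interval (high - low = 2 * 1.96 sd)
_CI_WIDTH_Z = 2.0 * 1.959963984540054


class ParameterError(ValueError):
    """Invalid model input or derivation request."""


# ---------------------------------------------------------------------------
# cost-derivation arithmetic
# ---------------------------------------------------------------------------

def weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted arithmetic mean sum(v*w)/sum(w).

    Used to pool per-patient costs reported by sub-cohorts of different sizes.
    """
    if len(values) == 0 or len(values) != len(weights):
        raise ParameterError("values and weights must be equal-length and non-empty")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ParameterError("weights must be nonnegative")
    total = float(w.sum())
    if total == 0:
        raise ParameterError("weights must not all be zero")
    return float(np.dot(np.asarray(values, dtype=float), w) / total)


def inflate_cpi(amount: float, factors: Sequence[float]) -> float:
    """Inflate ``amount`` along a chain of annual CPI multipliers."""
    if amount < 0:
        raise ParameterError("amount must be nonnegative")
    if any(f <= 0 for f in factors):
        raise ParameterError("CPI factors must be positive")
    return float(amount * math.prod(factors))


def convert_currency(amount: float, rate: float) -> float:
    """Convert CNY to USD at ``rate`` CNY per USD."""
    if rate <= 0:
        raise ParameterError("exchange rate must be positive")
    return amount / rate


def monthly_from_annual(annual: float) -> float:
    """Annual quantity to per-cycle (monthly) quantity: exact division by 12."""
    return annual / 12.0


# ---------------------------------------------------------------------------
# uncertainty distributions
# ---------------------------------------------------------------------------

class DistributionSpec(BaseModel):
    """A parameter's base value with its 95%-interval bounds and PSA family.

    ``gamma`` is used for nonnegative costs, ``beta`` for probabilities and
    utilities in [0, 1]; ``fixed`` parameters keep their bounds for one-way
    sensitivity analysis but are not perturbed probabilistically. Shape
    parameters are moment-matched from the symmetric-CI standard error
    sd = (high - low) / (2 * 1.96).
    """

    family: Literal["gamma", "beta", "fixed"]
    base: float
    low: float
    high: float

    @model_validator(mode="after")
    def _check(self) -> "DistributionSpec":
        if not (self.low <= self.base <= self.high):
            raise ValueError(f"bounds must bracket base: {self.low} <= {self.base} <= {self.high}")
        if self.family == "gamma" and self.low < 0:
            raise ValueError("gamma distribution requires nonnegative bounds")
        if self.family == "beta":
            if not (0.0 < self.base < 1.0):
                raise ValueError(f"beta distribution requires base in (0,1), got {self.base}")
            if not (0.0 <= self.low and self.high <= 1.0):
                raise ValueError("beta distribution requires bounds in [0,1]")
            v = self.sd**2
            if v > 0 and v >= self.base * (1.0 - self.base):
                raise ValueError("beta variance must be below base*(1-base)")
        return self

    @property
    def sd(self) -> float:
        """Standard error implied by reading [low, high] as a symmetric 95% CI."""
        return (self.high - self.low) / _CI_WIDTH_Z

    @property
    def gamma_shape(self) -> float:
        return self.base**2 / self.sd**2

    @property
    def gamma_rate(self) -> float:
        return self.base / self.sd**2

    @property
    def beta_ab(self) -> tuple[float, float]:
        m, v = self.base, self.sd**2
        common = m * (1.0 - m) / v - 1.0
        return m * common, (1.0 - m) * common

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        """Draw from the fitted distribution (point mass for fixed/zero-width)."""
        if self.family == "fixed" or self.high == self.low:
            return np.full(size, self.base) if size is not None else self.base
        if self.family == "gamma":
            return rng.gamma(self.gamma_shape, 1.0 / self.gamma_rate, size=size)
        a, b = self.beta_ab
        return rng.beta(a, b, size=size)


def derive_distribution(
    name: str, family: str, base: float, low: float, high: float
) -> DistributionSpec:
    """Build a validated :class:`DistributionSpec` for parameter ``name``.

    Degenerate bounds (low == high) yield a point mass regardless of family.
    """
    if low == high:
        family = "fixed"
    try:
        return DistributionSpec(family=family, base=base, low=low, high=high)
    except ValueError as exc:
        raise ParameterError(f"invalid distribution for {name!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# parameter groups
# ---------------------------------------------------------------------------

class CostParameters(BaseModel):
    """One-time MitraClip-related costs plus recurring costs, in 2021 CNY.

    The eight one-time components are charged once in the intervention arm's
    30-day stage; ``omt_monthly`` accrues for every live month in both arms
    and ``hf_hospitalization`` per hospitalization event.
    """

    device: float = Field(ge=0)
    procedure: float = Field(ge=0)
    diagnosis: float = Field(ge=0)
    medicine: float = Field(ge=0)
    complications: float = Field(ge=0)
    ward: float = Field(ge=0)
    nursing: float = Field(ge=0)
    others: float = Field(ge=0)
    omt_monthly: float = Field(ge=0)
    hf_hospitalization: float = Field(ge=0)

    @property
    def one_time_components(self) -> tuple[float, ...]:
        return (
            self.device,
            self.procedure,
            self.diagnosis,
            self.medicine,
            self.complications,
            self.ward,
            self.nursing,
            self.others,
        )

    @property
    def one_time_total(self) -> float:
        """Sum of the eight one-time MitraClip components."""
        return float(sum(self.one_time_components))

    @model_validator(mode="after")
    def _device_not_whole(self) -> "CostParameters":
        if not math.isfinite(self.one_time_total):
            raise ValueError("one-time cost components must be finite")
        if self.one_time_total <= self.device:
            raise ValueError("one-time total must exceed the device cost alone")
        return self


# 1/12 + small tolerance: monthly utility cannot exceed perfect health
_MONTHLY_UTILITY_CAP = 1.0 / 12.0 + 1e-9


class UtilityParameters(BaseModel):
    """Monthly utilities per NYHA state and one-time disutility magnitudes."""

    nyha1: float
    nyha2: float
    nyha3: float
    nyha4: float
    disutility_complications: float = Field(ge=0)
    disutility_procedure: float = Field(ge=0)
    disutility_hf_hospitalization: float = Field(ge=0)
    dead: float = 0.0

    @field_validator("nyha1", "nyha2", "nyha3", "nyha4")
    @classmethod
    def _monthly_range(cls, v: float) -> float:
        if not (0.0 <= v <= _MONTHLY_UTILITY_CAP):
            raise ValueError(f"monthly utility {v} outside [0, 1/12]")
        return v

    @field_validator("dead")
    @classmethod
    def _dead_zero(cls, v: float) -> float:
        if v != 0.0:
            raise ValueError("dead-state utility is fixed at 0")
        return v

    @model_validator(mode="after")
    def _severity_ordering(self) -> "UtilityParameters":
        u = [self.nyha1, self.nyha2, self.nyha3, self.nyha4]
        if any(a < b - 1e-12 for a, b in zip(u, u[1:])):
            raise ValueError("utilities must be non-increasing in NYHA severity")
        return self

    def monthly_vector(self) -> np.ndarray:
        """Utilities for the live states, state order NYHA I..IV."""
        return np.array([self.nyha1, self.nyha2, self.nyha3, self.nyha4])


class TransitionSpec(BaseModel):
    """Per-arm monthly transition rows and HF-hospitalization probabilities.

    ``matrices[arm][from_state]`` holds the five probabilities of moving to
    (NYHA I, II, III, IV, dead) within one month; the dead row is implicit
    (absorbing). ``hospitalization[arm][state]`` is the monthly probability
    of an HF hospitalization while occupying that state, independent of the
    NYHA transition.
    """

    matrices: dict[str, dict[str, list[float]]]
    hospitalization: dict[str, dict[str, float]]

    @model_validator(mode="after")
    def _validate(self) -> "TransitionSpec":
        for arm in ARMS:
            if arm not in self.matrices:
                raise ValueError(f"missing transition matrix for arm {arm!r}")
            for state in NYHA_STATES:
                row = self.matrices[arm].get(state)
                if row is None or len(row) != len(STATES):
                    raise ValueError(f"transitions.{arm}.{state}: need {len(STATES)} probabilities")
                if any(p < 0 or p > 1 for p in row):
                    raise ValueError(f"transitions.{arm}.{state}: probability outside [0,1]")
                if abs(math.fsum(row) - 1.0) > 1e-12:
                    raise ValueError(
                        f"transitions.{arm}.{state}: row sums to {math.fsum(row)!r}, not 1"
                    )
            if arm not in self.hospitalization:
                raise ValueError(f"missing hospitalization probabilities for arm {arm!r}")
            for state in NYHA_STATES:
                h = self.hospitalization[arm].get(state)
                if h is None or not (0.0 <= h <= 1.0):
                    raise ValueError(f"hospitalization.{arm}.{state}: probability outside [0,1]")
        return self

    def matrix(self, arm: str) -> np.ndarray:
        """Full 5x5 row-stochastic matrix with the absorbing dead row."""
        if arm not in self.matrices:
            raise ParameterError(f"unknown arm {arm!r}")
        rows = [self.matrices[arm][s] for s in NYHA_STATES]
        rows.append([0.0, 0.0, 0.0, 0.0, 1.0])
        return np.array(rows, dtype=float)

    def hosp_vector(self, arm: str) -> np.ndarray:
        if arm not in self.hospitalization:
            raise ParameterError(f"unknown arm {arm!r}")
        return np.array([self.hospitalization[arm][s] for s in NYHA_STATES], dtype=float)


class EconomicSettings(BaseModel):
    """Discounting, willingness-to-pay, and currency/inflation constants.

    Two exchange rates play distinct roles: ``source_exchange_rate`` (6.75
    CNY/USD) converts the source-era USD cost data into CNY inside the cost
    derivations, while ``reporting_exchange_rate`` (6.45 CNY/USD, the 2021
    average) converts 2021-CNY results into USD for reporting.
    """

    annual_discount_rate: float = Field(ge=0.0, le=0.5)
    per_capita_gdp: float = Field(gt=0)
    wtp_threshold: float | None = None
    reporting_exchange_rate: float = Field(default=6.45, gt=0)
    source_exchange_rate: float = Field(default=6.75, gt=0)
    cpi_factors: list[float] = Field(default_factory=list)

    @field_validator("cpi_factors")
    @classmethod
    def _positive_factors(cls, v: list[float]) -> list[float]:
        if any(f <= 0 for f in v):
            raise ValueError("CPI factors must be positive")
        return v

    @property
    def wtp(self) -> float:
        """WTP threshold; defaults to 3x per-capita GDP when not set explicitly."""
        return self.wtp_threshold if self.wtp_threshold is not None else 3.0 * self.per_capita_gdp


class DecisionTreeSettings(BaseModel):
    """30-day stage outputs handed to the Markov model.

    The post-30-day NYHA distributions are not published; the shipped defaults
    are calibrated so the model reproduces the reported lifetime outcomes.
    """

    initial_nyha_distribution: dict[str, list[float]]
    thirty_day_mortality: dict[str, float] = Field(
        default_factory=lambda: {a: 0.0 for a in ARMS}
    )

    @model_validator(mode="after")
    def _validate(self) -> "DecisionTreeSettings":
        for arm in ARMS:
            dist = self.initial_nyha_distribution.get(arm)
            if dist is None or len(dist) != len(NYHA_STATES):
                raise ValueError(f"initial_nyha_distribution.{arm}: need {len(NYHA_STATES)} shares")
            if any(p < 0 or p > 1 for p in dist):
                raise ValueError(f"initial_nyha_distribution.{arm}: share outside [0,1]")
            if abs(math.fsum(dist) - 1.0) > 1e-9:
                raise ValueError(f"initial_nyha_distribution.{arm}: shares sum to {math.fsum(dist)!r}")
            m = self.thirty_day_mortality.get(arm, 0.0)
            if not (0.0 <= m <= 1.0):
                raise ValueError(f"thirty_day_mortality.{arm}: probability outside [0,1]")
        return self

    def distribution(self, arm: str) -> np.ndarray:
        if arm not in self.initial_nyha_distribution:
            raise ParameterError(f"unknown arm {arm!r}")
        return np.array(self.initial_nyha_distribution[arm], dtype=float)


class ModelSettings(BaseModel):
    """Cohort ages, cycle length, horizon and half-cycle flag."""

    entry_age: float = 72.0
    terminal_age: float = 100.0
    cycle_length_months: int = 1
    half_cycle_correction: bool = True

    @model_validator(mode="after")
    def _ages(self) -> "ModelSettings":
        if self.terminal_age <= self.entry_age:
            raise ValueError("terminal_age must exceed entry_age")
        if self.cycle_length_months < 1:
            raise ValueError("cycle length must be at least one month")
        return self

    @property
    def n_cycles(self) -> int:
        """Number of monthly cycles to the terminal age (336 for 72 -> 100)."""
        return round((self.terminal_age - self.entry_age) * 12 / self.cycle_length_months)


class ParameterSet(BaseModel):
    """Complete validated bundle of model inputs."""

    costs: CostParameters
    utilities: UtilityParameters
    transitions: TransitionSpec
    econ: EconomicSettings
    decision_tree: DecisionTreeSettings
    model: ModelSettings = Field(default_factory=ModelSettings)
    uncertainty: dict[str, DistributionSpec] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _uncertainty_names_resolve(self) -> "ParameterSet":
        for name in self.uncertainty:
            try:
                get_path(self, name)
            except (AttributeError, KeyError) as exc:
                raise ValueError(f"uncertainty entry {name!r} names no model parameter") from exc
        return self


# ---------------------------------------------------------------------------
# dotted-path access (used by sensitivity analyses and calibration)
# ---------------------------------------------------------------------------

def get_path(params: ParameterSet, path: str) -> float:
    """Fetch a scalar parameter by dotted path, e.g. ``"costs.device"``."""
    obj: object = params
    for part in path.split("."):
        if isinstance(obj, Mapping):
            obj = obj[part]
        else:
            obj = getattr(obj, part)
    return obj  # type: ignore[return-value]


def set_path(params: ParameterSet, path: str, value: float) -> ParameterSet:
    """Return a deep copy of ``params`` with the parameter at ``path`` replaced."""
    new = params.model_copy(deep=True)
    parts = path.split(".")
    obj: object = new
    for part in parts[:-1]:
        obj = obj[part] if isinstance(obj, Mapping) else getattr(obj, part)
    if isinstance(obj, Mapping):
        obj[parts[-1]] = value  # type: ignore[index]
    else:
        setattr(obj, parts[-1], value)
    return new


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------

def load_parameters(source: str | Path | Mapping) -> ParameterSet:
    """Load and validate a configuration document (YAML/JSON path or mapping)."""
    if isinstance(source, Mapping):
        doc = source
    else:
        text = Path(source).read_text()
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ParameterError("configuration document must be a mapping")
    try:
        return ParameterSet.model_validate(doc)
    except Exception as exc:  # pydantic ValidationError carries field locations
        raise ParameterError(f"invalid configuration: {exc}") from exc


def to_document(params: ParameterSet) -> dict:
    """Plain-dict form of a parameter set, round-trippable via load_parameters."""
    return params.model_dump(mode="json")


def write_parameters(params: ParameterSet, path: str | Path) -> Path:
    """Serialize a parameter set to YAML."""
    path = Path(path)
    path.write_text(yaml.safe_dump(to_document(params), sort_keys=False))
    return path


def default_parameters() -> ParameterSet:
    """The shipped base-case configuration (calibrated defaults)."""
    text = resources.files("teer_cea").joinpath("data/base_case.yaml").read_text()
    return load_parameters(yaml.safe_load(text))
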