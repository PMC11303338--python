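"""Parameter schema, validation and (de)serialisation.

Two parameter blocks drive the whole pipeline:

* :class:`DemographicParameters` -- rates and structural constants of the
  flock demography (the inputs of the stationary solver).
* :class:`PriceAndCostParameters` -- live weights, unit prices, manure and
  feed coefficients, currency conversion and variable-cost shares.

Parameters live in a small YAML dialect with explicit units in the key
names so a file is self-documenting.  ``load`` after ``write`` is the
identity on valid parameter sets (full float precision is written).

Range rules are deliberately *not* enforced at construction time: models
only check types, so that :func:`validate_parameters` can act as a total
reporting operation over arbitrary values.  :func:`load_parameters`
rejects files whose values violate any range rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator

import yaml
from pydantic import BaseModel, ConfigDict

logger = logging.getLogger(__name__)

#: animal classes and sexes used throughout the package
CLASSES = ("lamb", "subadult", "adult")
SEXES = ("f", "m")
#: keys of the per-class-and-sex weight/price tables
CLASS_SEX_KEYS = ("lamb", "subadult_f", "subadult_m", "adult_f", "adult_m")

BASELINE_RESOURCE = "baseline_mcl_sheep.yaml"


class ParameterError(ValueError):
    """Raised when a parameter file is missing, malformed or out of range."""


class DemographicParameters(BaseModel):
    """Demographic rates and structural constants of the flock."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_breeding_females: float
    male_breeder_ratio: float
    parturition_rate: float
    prolificacy: float
    sex_ratio_at_birth: float = 0.5
    lamb_mortality: float
    subadult_mortality_f: float
    subadult_mortality_m: float
    adult_mortality_f: float
    adult_mortality_m: float
    subadult_offtake_f: float
    subadult_offtake_m: float
    lamb_class_duration: float = 0.5
    subadult_class_duration: float = 0.5

    def replace(self, **kwargs) -> "DemographicParameters":
        """Return a copy with the given fields replaced."""
        return self.model_copy(update=kwargs)


class PriceAndCostParameters(BaseModel):
    """Live weights, prices and cost/conversion coefficients.

    ``live_weight`` and ``price`` are keyed by ``lamb``, ``subadult_f``,
    ``subadult_m``, ``adult_f`` and ``adult_m``.  Manure output is
    modelled per kg of standing live weight per year (the convention that
    reproduces the published manure revenues, which scale with flock
    biomass rather than head count).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    live_weight: dict[str, float]
    price: dict[str, float]
    manure_output_kg_per_kg_liveweight_year: float
    manure_price_birr_per_kg: float
    feed_dm_fraction: float = 0.026
    exchange_rate: float = 43.0
    variable_cost_shares: tuple[float, ...] = (0.15, 0.25)

    def replace(self, **kwargs) -> "PriceAndCostParameters":
        return self.model_copy(update=kwargs)


class ScenarioSpec(BaseModel):
    """Grid and scenario settings for the YSM analysis."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    ysm_grid: tuple[float, ...] = (0.30, 0.25, 0.20, 0.15, 0.10, 0.05, 0.0)
    baseline_ysm: float = 0.20
    fertility_scenarios: tuple[float, ...] = (0.59, 1.00)
    growth_mode: str = "zero-growth"
    constant_growth_rate: float = 0.102
    population_size: float = 24_700_000.0

    def replace(self, **kwargs) -> "ScenarioSpec":
        return self.model_copy(update=kwargs)


@dataclass(frozen=True)
class Violation:
    """One violated parameter rule."""

    field: str
    value: object
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}={self.value!r} violates: {self.rule}"


def _check(name: str, value: float, lo: float | None, hi: float | None,
           lo_open: bool = False, hi_open: bool = False) -> Iterator[Violation]:
    if not isinstance(value, (int, float)) or not math.isfinite(value):
        yield Violation(name, value, "must be a finite number")
        return
    if lo is not None and (value <= lo if lo_open else value < lo):
        op = ">" if lo_open else ">="
        yield Violation(name, value, f"must be {op} {lo}")
    if hi is not None and (value >= hi if hi_open else value > hi):
        op = "<" if hi_open else "<="
        yield Violation(name, value, f"must be {op} {hi}")


def validate_parameters(
    d: DemographicParameters, p: PriceAndCostParameters
) -> list[Violation]:
    """Check every range invariant; return a (possibly empty) violation list.

    Total: never raises, whatever the parameter values.
    """
    out: list[Violation] = []
    out += _check("n_breeding_females", d.n_breeding_females, 0, None, lo_open=True)
    out += _check("male_breeder_ratio", d.male_breeder_ratio, 0, None)
    out += _check("parturition_rate", d.parturition_rate, 0, None)
    out += _check("prolificacy", d.prolificacy, 0, None)
    out += _check("sex_ratio_at_birth", d.sex_ratio_at_birth, 0, 1,
                  lo_open=True, hi_open=True)
    for name in ("lamb_mortality", "subadult_mortality_f", "subadult_mortality_m",
                 "adult_mortality_f", "adult_mortality_m",
                 "subadult_offtake_f", "subadult_offtake_m"):
        out += _check(name, getattr(d, name), 0, 1)
    for name in ("lamb_class_duration", "subadult_class_duration"):
        out += _check(name, getattr(d, name), 0, None, lo_open=True)

    for key in CLASS_SEX_KEYS:
        if key not in p.live_weight:
            out.append(Violation(f"live_weight.{key}", None, "missing class"))
        else:
            out += _check(f"live_weight.{key}", p.live_weight[key], 0, None)
        if key not in p.price:
            out.append(Violation(f"price.{key}", None, "missing class"))
        else:
            out += _check(f"price.{key}", p.price[key], 0, None)
    out += _check("manure_output_kg_per_kg_liveweight_year",
                  p.manure_output_kg_per_kg_liveweight_year, 0, None)
    out += _check("manure_price_birr_per_kg", p.manure_price_birr_per_kg, 0, None)
    out += _check("feed_dm_fraction", p.feed_dm_fraction, 0, 0.2,
                  lo_open=True, hi_open=True)
    out += _check("exchange_rate", p.exchange_rate, 0, None, lo_open=True)
    for i, v in enumerate(p.variable_cost_shares):
        out += _check(f"variable_cost_shares[{i}]", v, 0, 1, hi_open=True)
    return out


# --------------------------------------------------------------------------
# serialisation
# --------------------------------------------------------------------------

_DEMOGRAPHY_KEY_MAP = {
    "n_breeding_females_head": "n_breeding_females",
    "male_breeders_per_female": "male_breeder_ratio",
    "parturition_rate_per_female_year": "parturition_rate",
    "prolificacy_lambs_per_parturition": "prolificacy",
    "sex_ratio_proportion_female_at_birth": "sex_ratio_at_birth",
    "lamb_mortality_risk": "lamb_mortality",
    "subadult_mortality_risk_female": "subadult_mortality_f",
    "subadult_mortality_risk_male": "subadult_mortality_m",
    "adult_mortality_risk_female": "adult_mortality_f",
    "adult_mortality_risk_male": "adult_mortality_m",
    "subadult_offtake_rate_female": "subadult_offtake_f",
    "subadult_offtake_rate_male": "subadult_offtake_m",
    "lamb_class_duration_years": "lamb_class_duration",
    "subadult_class_duration_years": "subadult_class_duration",
}
_DEMOGRAPHY_KEY_MAP_INV = {v: k for k, v in _DEMOGRAPHY_KEY_MAP.items()}

_PRICE_KEY_MAP = {
    "live_weight_kg": "live_weight",
    "price_birr_per_head": "price",
    "manure_output_kg_per_kg_liveweight_year":
        "manure_output_kg_per_kg_liveweight_year",
    "manure_price_birr_per_kg": "manure_price_birr_per_kg",
    "feed_dm_fraction_of_liveweight_per_day": "feed_dm_fraction",
    "exchange_rate_birr_per_usd": "exchange_rate",
    "variable_cost_shares_of_revenue": "variable_cost_shares",
}
_PRICE_KEY_MAP_INV = {v: k for k, v in _PRICE_KEY_MAP.items()}


def _map_keys(section: dict, key_map: dict[str, str], section_name: str) -> dict:
    out = {}
    for key, value in section.items():
        if key not in key_map:
            raise ParameterError(
                f"unknown key {section_name}.{key!r} in parameter file"
            )
        out[key_map[key]] = value
    return out


def _parse(raw: dict) -> tuple[DemographicParameters, PriceAndCostParameters]:
    if not isinstance(raw, dict):
        raise ParameterError("parameter file must contain a mapping")
    unknown = set(raw) - {"demography", "prices"}
    if unknown:
        raise ParameterError(f"unknown top-level section(s): {sorted(unknown)}")
    for section in ("demography", "prices"):
        if section not in raw:
            raise ParameterError(f"missing section {section!r}")
    try:
        d = DemographicParameters(
            **_map_keys(raw["demography"], _DEMOGRAPHY_KEY_MAP, "demography"))
        p = PriceAndCostParameters(
            **_map_keys(raw["prices"], _PRICE_KEY_MAP, "prices"))
    except ParameterError:
        raise
    except Exception as exc:  # pydantic type errors
        raise ParameterError(f"schema violation: {exc}") from exc
    violations = validate_parameters(d, p)
    if violations:
        raise ParameterError(
            "out-of-range parameter(s): " + "; ".join(map(str, violations)))
    return d, p


def load_parameters(
    path: str | Path,
) -> tuple[DemographicParameters, PriceAndCostParameters]:
    """Read and fully validate a parameter file.

    Raises :class:`ParameterError` if the file is missing, has unknown or
    missing keys, or contains out-of-range values (the offending field is
    named in the message).
    """
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"parameter file not found: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ParameterError(f"cannot parse {path}: {exc}") from exc
    return _parse(raw)


def write_parameters(
    path: str | Path,
    d: DemographicParameters,
    p: PriceAndCostParameters,
) -> None:
    """Write a parameter set in the documented dialect (bit-exact round-trip)."""
    raw = {
        "demography": {
            _DEMOGRAPHY_KEY_MAP_INV[k]: getattr(d, k)
            for k in DemographicParameters.model_fields
        },
        "prices": {
            _PRICE_KEY_MAP_INV["live_weight"]: dict(p.live_weight),
            _PRICE_KEY_MAP_INV["price"]: dict(p.price),
            "manure_output_kg_per_kg_liveweight_year":
                p.manure_output_kg_per_kg_liveweight_year,
            "manure_price_birr_per_kg": p.manure_price_birr_per_kg,
            _PRICE_KEY_MAP_INV["feed_dm_fraction"]: p.feed_dm_fraction,
            _PRICE_KEY_MAP_INV["exchange_rate"]: p.exchange_rate,
            _PRICE_KEY_MAP_INV["variable_cost_shares"]:
                list(p.variable_cost_shares),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False, default_flow_style=False)


# Text anchors used to sanity-check the packaged baseline fixture.
_BASELINE_ANCHORS = {
    "parturition_rate": 0.59,
    "lamb_mortality": 0.20,
    "feed_dm_fraction": 0.026,
    "exchange_rate": 43.0,
    "lamb_price_birr": 28.5 * 43.0,
}


def load_baseline_parameters() -> tuple[DemographicParameters, PriceAndCostParameters]:
    """Load the packaged baseline fixture (MCL sheep, most-likely values).

    Anchor values that are fixed in the published record (parturition rate
    0.59, lamb mortality 0.20, feed fraction 0.026, exchange rate 43,
    lamb value USD 28.5) are cross-checked and a warning is logged on any
    mismatch.
    """
    with resources.as_file(
        resources.files("flockvalue.data").joinpath(BASELINE_RESOURCE)
    ) as fp:
        d, p = load_parameters(fp)
    checks = {
        "parturition_rate": d.parturition_rate,
        "lamb_mortality": d.lamb_mortality,
        "feed_dm_fraction": p.feed_dm_fraction,
        "exchange_rate": p.exchange_rate,
        "lamb_price_birr": p.price["lamb"],
    }
    for name, expected in _BASELINE_ANCHORS.items():
        actual = checks[name]
        if abs(actual - expected) > 1e-9 * max(1.0, abs(expected)):
            logger.warning(
                "baseline fixture %s=%r differs from documented value %r",
                name, actual, expected)
    return d, p


def parameter_table(
    d: DemographicParameters, p: PriceAndCostParameters
) -> "pandas.DataFrame":  # noqa: F821 - imported lazily
    """Flat one-row-per-parameter table, e.g. for CSV export in reports."""
    import pandas as pd

    rows = []
    for field in DemographicParameters.model_fields:
        rows.append(("demography", _DEMOGRAPHY_KEY_MAP_INV[field],
                     getattr(d, field)))
    for key in CLASS_SEX_KEYS:
        rows.append(("prices", f"live_weight_kg.{key}", p.live_weight[key]))
    for key in CLASS_SEX_KEYS:
        rows.append(("prices", f"price_birr_per_head.{key}", p.price[key]))
    rows.append(("prices", "manure_output_kg_per_kg_liveweight_year",
                 p.manure_output_kg_per_kg_liveweight_year))
    rows.append(("prices", "manure_price_birr_per_kg", p.manure_price_birr_per_kg))
    rows.append(("prices", "feed_dm_fraction_of_liveweight_per_day",
                 p.feed_dm_fraction))
    rows.append(("prices", "exchange_rate_birr_per_usd", p.exchange_rate))
    for i, v in enumerate(p.variable_cost_shares):
        rows.append(("prices", f"variable_cost_shares_of_revenue[{i}]", v))
    return pd.DataFrame(rows, columns=["section", "parameter", "value"])
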