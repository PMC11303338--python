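"""Monetary and efficiency metrics of a solved flock.

All accounting is in Birr internally; conversion to USD happens once per
statement via the exchange rate (``usd = birr / exchange_rate`` exactly).
Skins income is deliberately excluded.  Feed requirement and manure
output both scale with standing flock biomass: daily dry-matter intake is
a fixed fraction of live weight, and manure output is modelled per kg of
standing live weight per year (the convention under which the published
manure revenues, which grow with flock biomass rather than head count,
are reproduced).
"""

from __future__ import annotations

from dataclasses import dataclass

from .herd import AnnualFlows, FlockState
from .params import DemographicParameters, PriceAndCostParameters

__all__ = [
    "RevenueStatement",
    "ProductivityMetrics",
    "offtake_value",
    "manure_value",
    "feed_dm",
    "revenue_statement",
    "productivity_metrics",
]

DAYS_PER_YEAR = 365.0


class MissingPriceError(KeyError):
    """A class with non-zero offtake has no price."""


def _price_key(cls: str, sex: str) -> str:
    return cls if cls == "lamb" else f"{cls}_{sex}"


@dataclass(frozen=True)
class RevenueStatement:
    """Annual revenue components of the flock (Birr)."""

    live_birr: dict[tuple[str, str], float]
    manure_birr: float
    inventory_birr: float  # change in inventory value; zero in zero-growth mode
    feed_dm_kg: float
    exchange_rate: float

    @property
    def live_total_birr(self) -> float:
        return sum(self.live_birr.values())

    @property
    def total_birr(self) -> float:
        return self.live_total_birr + self.manure_birr + self.inventory_birr

    # USD views ------------------------------------------------------------
    @property
    def live_total_usd(self) -> float:
        return self.live_total_birr / self.exchange_rate

    @property
    def manure_usd(self) -> float:
        return self.manure_birr / self.exchange_rate

    @property
    def inventory_usd(self) -> float:
        return self.inventory_birr / self.exchange_rate

    @property
    def total_usd(self) -> float:
        return self.total_birr / self.exchange_rate


@dataclass(frozen=True)
class ProductivityMetrics:
    """Revenue ratios (USD) and gross margins per variable-cost share."""

    per_head: float
    per_breeding_female: float
    per_100kg_feed_dm: float
    gross_margin_per_head: dict[float, float]


def offtake_value(
    flows: AnnualFlows, p: PriceAndCostParameters
) -> dict[tuple[str, str], float]:
    """Live-animal offtake value by class x sex (Birr/yr).

    Only sold animals are valued; deaths carry no value.  Raises
    :class:`MissingPriceError` for a class with offtake but no price.
    """
    out = {}
    for (cls, sex), head in flows.offtake.items():
        key = _price_key(cls, sex)
        if key not in p.price:
            if head > 0:
                raise MissingPriceError(
                    f"no price for class {key!r} with offtake {head:g}")
            out[(cls, sex)] = 0.0
            continue
        out[(cls, sex)] = head * p.price[key]
    return out


def manure_value(state: FlockState, p: PriceAndCostParameters) -> float:
    """Annual manure revenue (Birr/yr), proportional to standing biomass."""
    return (state.biomass_kg(p.live_weight)
            * p.manure_output_kg_per_kg_liveweight_year
            * p.manure_price_birr_per_kg)


def feed_dm(state: FlockState, p: PriceAndCostParameters) -> float:
    """Annual feed dry-matter requirement (kg DM/yr) of the standing flock."""
    return state.biomass_kg(p.live_weight) * p.feed_dm_fraction * DAYS_PER_YEAR


def revenue_statement(
    state: FlockState,
    flows: AnnualFlows,
    increment: dict[tuple[str, str], float] | None,
    p: PriceAndCostParameters,
) -> RevenueStatement:
    """Assemble the annual revenue statement of a solved flock.

    ``increment`` is the net stock change (head/yr, constant-growth mode);
    it is valued at class prices.  Pass ``None`` (or all-zero) for the
    zero-growth mode.
    """
    live = offtake_value(flows, p)
    inventory = 0.0
    if increment:
        for (cls, sex), head in increment.items():
            inventory += head * p.price[_price_key(cls, sex)]
    return RevenueStatement(
        live_birr=live,
        manure_birr=manure_value(state, p),
        inventory_birr=inventory,
        feed_dm_kg=feed_dm(state, p),
        exchange_rate=p.exchange_rate,
    )


def productivity_metrics(
    statement: RevenueStatement,
    state: FlockState,
    d: DemographicParameters,
    p: PriceAndCostParameters,
) -> ProductivityMetrics:
    """Per-head / per-ewe / per-feed revenue and gross margins (USD)."""
    total_usd = statement.total_usd
    head = state.total
    per_head = total_usd / head if head > 0 else 0.0
    per_bf = (total_usd / d.n_breeding_females
              if d.n_breeding_females > 0 else 0.0)
    per_feed = (total_usd / (statement.feed_dm_kg / 100.0)
                if statement.feed_dm_kg > 0 else 0.0)
    margins = {v: per_head * (1.0 - v) for v in p.variable_cost_shares}
    return ProductivityMetrics(
        per_head=per_head,
        per_breeding_female=per_bf,
        per_100kg_feed_dm=per_feed,
        gross_margin_per_head=margins,
    )
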