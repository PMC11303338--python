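"""Young-stock-mortality (YSM) analysis pipeline.

Sweeps lamb mortality over a grid, derives the gross and net cost of YSM,
per-step marginal returns, the fertility sensitivity comparison,
population-level extrapolations and the multi-scenario report table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import econ, herd
from .params import (DemographicParameters, PriceAndCostParameters,
                     ScenarioSpec)

__all__ = [
    "ScenarioResult",
    "YsmSweepResult",
    "CostOfYsmEstimate",
    "evaluate_scenario",
    "sweep_ysm",
    "cost_of_ysm",
    "revenue_slope",
    "marginal_returns",
    "fertility_scenario",
    "population_extrapolation",
    "table1_report",
]


@dataclass(frozen=True)
class ScenarioResult:
    """One fully evaluated scenario (one YSM grid value)."""

    lamb_mortality: float
    state: herd.FlockState
    flows: herd.AnnualFlows
    statement: econ.RevenueStatement
    metrics: econ.ProductivityMetrics

    @property
    def offtake_rate(self) -> float:
        return self.flows.total_offtake / self.state.total


@dataclass(frozen=True)
class YsmSweepResult:
    """Sweep of lamb mortality; one record per grid value, grid-ordered."""

    records: list[ScenarioResult]
    growth_mode: str
    growth_rate: float
    parturition_rate: float

    @property
    def grid(self) -> list[float]:
        return [r.lamb_mortality for r in self.records]

    def at(self, ysm: float) -> ScenarioResult:
        for rec in self.records:
            if abs(rec.lamb_mortality - ysm) < 1e-12:
                return rec
        raise KeyError(f"YSM value {ysm!r} is not on the sweep grid")

    def per_head(self) -> np.ndarray:
        return np.array([r.metrics.per_head for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-grid-value summary."""
        rows = []
        for r in self.records:
            rows.append({
                "lamb_mortality": r.lamb_mortality,
                "total_stock": r.state.total,
                "total_births": r.flows.total_births,
                "total_deaths": r.flows.total_deaths,
                "total_offtake": r.flows.total_offtake,
                "offtake_rate": r.offtake_rate,
                "revenue_usd": r.statement.total_usd,
                "live_revenue_usd": r.statement.live_total_usd,
                "manure_usd": r.statement.manure_usd,
                "inventory_usd": r.statement.inventory_usd,
                "per_head_usd": r.metrics.per_head,
                "per_breeding_female_usd": r.metrics.per_breeding_female,
                "per_100kg_feed_dm_usd": r.metrics.per_100kg_feed_dm,
            })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CostOfYsmEstimate:
    """Gross/net cost of a YSM level relative to a lower comparison level."""

    baseline_ysm: float
    target_ysm: float
    gross_cost_per_head: float
    net_cost_per_head: dict[float, float]
    additional_surviving_lambs: float
    cost_per_surviving_lamb: float
    flock_live_revenue_difference: float


def evaluate_scenario(
    d: DemographicParameters,
    p: PriceAndCostParameters,
    growth_mode: str = "zero-growth",
    growth_rate: float = 0.0,
    convention: str = "risk",
) -> ScenarioResult:
    """Solve one flock and attach its revenue statement and metrics."""
    if growth_mode == "constant-growth":
        state, flows, increment = herd.constant_growth_state(
            d, growth_rate, convention)
    elif growth_mode == "zero-growth":
        state, flows = herd.stationary_state(d, convention)
        increment = None
    else:
        raise ValueError(f"unknown growth mode: {growth_mode!r}")
    statement = econ.revenue_statement(state, flows, increment, p)
    metrics = econ.productivity_metrics(statement, state, d, p)
    return ScenarioResult(d.lamb_mortality, state, flows, statement, metrics)


def sweep_ysm(
    d: DemographicParameters,
    p: PriceAndCostParameters,
    spec: ScenarioSpec,
    convention: str = "risk",
) -> YsmSweepResult:
    """Evaluate the flock at every YSM grid value (only lamb_mortality varies)."""
    records = []
    rate = (spec.constant_growth_rate
            if spec.growth_mode == "constant-growth" else 0.0)
    for m in spec.ysm_grid:
        try:
            records.append(evaluate_scenario(
                d.replace(lamb_mortality=m), p,
                growth_mode=spec.growth_mode, growth_rate=rate,
                convention=convention))
        except herd.InfeasibleParameterError as exc:
            raise herd.InfeasibleParameterError(exc.sex, exc.required_offtake) \
                from ValueError(f"infeasible at YSM grid value {m}")
    return YsmSweepResult(
        records=records, growth_mode=spec.growth_mode, growth_rate=rate,
        parturition_rate=d.parturition_rate)


def cost_of_ysm(
    sweep: YsmSweepResult,
    baseline_ysm: float,
    target_ysm: float,
    shares: tuple[float, ...] = (0.15, 0.25),
) -> CostOfYsmEstimate:
    """Cost of running the flock at ``baseline_ysm`` instead of ``target_ysm``.

    Gross cost is the per-head revenue difference; net cost deducts each
    variable-cost share.  The per-surviving-lamb figure divides the
    flock-level *live-animal* revenue difference (manure excluded) by the
    difference in annual lamb deaths.
    """
    base = sweep.at(baseline_ysm)
    target = sweep.at(target_ysm)
    gross = target.metrics.per_head - base.metrics.per_head
    net = {v: gross * (1.0 - v) for v in shares}
    extra_lambs = (base.flows.deaths_by_class("lamb")
                   - target.flows.deaths_by_class("lamb"))
    live_diff = target.statement.live_total_usd - base.statement.live_total_usd
    per_lamb = live_diff / extra_lambs if extra_lambs > 0 else 0.0
    return CostOfYsmEstimate(
        baseline_ysm=baseline_ysm,
        target_ysm=target_ysm,
        gross_cost_per_head=gross,
        net_cost_per_head=net,
        additional_surviving_lambs=extra_lambs,
        cost_per_surviving_lamb=per_lamb,
        flock_live_revenue_difference=live_diff,
    )


def revenue_slope(sweep: YsmSweepResult) -> float:
    """Per-head revenue gain (USD) per one-percentage-point YSM reduction.

    Least-squares slope of per-head revenue on YSM in percentage points,
    sign-flipped so a beneficial reduction reports positive.
    """
    if len(sweep.records) < 2:
        raise ValueError("need at least two grid points to estimate a slope")
    x = np.array(sweep.grid) * 100.0
    if np.ptp(x) == 0:
        raise ValueError("degenerate grid: all YSM values identical")
    y = sweep.per_head()
    slope = np.polyfit(x, y, 1)[0]
    return -slope


def marginal_returns(sweep: YsmSweepResult) -> pd.DataFrame:
    """Per-step revenue increments along the grid (absolute USD and %).

    Steps run from the higher-YSM to the lower-YSM point of each
    consecutive pair; the relative increment is expressed on the
    higher-YSM per-head revenue.
    """
    if len(sweep.records) < 2:
        raise ValueError("need at least two grid points")
    recs = sorted(sweep.records, key=lambda r: r.lamb_mortality, reverse=True)
    rows = []
    for high, low in zip(recs[:-1], recs[1:]):
        gain = low.metrics.per_head - high.metrics.per_head
        rows.append({
            "ysm_from": high.lamb_mortality,
            "ysm_to": low.lamb_mortality,
            "gain_usd_per_head": gain,
            "gain_pct": 100.0 * gain / high.metrics.per_head,
        })
    return pd.DataFrame(rows)


def fertility_scenario(
    d: DemographicParameters,
    p: PriceAndCostParameters,
    spec: ScenarioSpec,
    convention: str = "risk",
) -> dict:
    """Run the YSM sweep for each parturition-rate scenario and compare.

    Returns the sweeps plus a summary of baseline-YSM revenues and of the
    absolute and relative gains from eliminating the baseline YSM.
    """
    target = min(spec.ysm_grid)
    sweeps: dict[float, YsmSweepResult] = {}
    summary = []
    for rate in spec.fertility_scenarios:
        sweep = sweep_ysm(d.replace(parturition_rate=rate), p, spec, convention)
        sweeps[rate] = sweep
        base = sweep.at(spec.baseline_ysm)
        cost = cost_of_ysm(sweep, spec.baseline_ysm, target)
        summary.append({
            "parturition_rate": rate,
            "per_head_usd": base.metrics.per_head,
            "per_breeding_female_usd": base.metrics.per_breeding_female,
            "per_100kg_feed_dm_usd": base.metrics.per_100kg_feed_dm,
            "offtake_rate": base.offtake_rate,
            "gain_usd_per_head": cost.gross_cost_per_head,
            "relative_gain_pct":
                100.0 * cost.gross_cost_per_head / base.metrics.per_head,
            "relative_feed_gain_pct":
                100.0 * (sweep.at(target).metrics.per_100kg_feed_dm
                         / base.metrics.per_100kg_feed_dm - 1.0),
        })
    frame = pd.DataFrame(summary)
    gains = frame["gain_usd_per_head"]
    comparison = {
        "absolute_gain_difference": float(gains.max() - gains.min()),
        "summary": frame,
    }
    return {"sweeps": sweeps, "comparison": comparison}


def population_extrapolation(
    per_head_gain: float, population: float, flock_size: float
) -> dict[str, float]:
    """Scale a per-head revenue gain to population and single-flock level."""
    if per_head_gain < 0 or population <= 0 or flock_size <= 0:
        if per_head_gain == 0:
            return {"national_gain_usd": 0.0,
                    "per_flock_annual_usd": 0.0,
                    "per_flock_monthly_usd": 0.0}
        raise ValueError("inputs must be positive")
    annual = per_head_gain * flock_size
    return {
        "national_gain_usd": per_head_gain * population,
        "per_flock_annual_usd": annual,
        "per_flock_monthly_usd": annual / 12.0,
    }


# --------------------------------------------------------------------------
# report table
# --------------------------------------------------------------------------

def _col(result: ScenarioResult) -> dict[str, tuple[float, float | None]]:
    """One report column: row -> (count/value, within-block share %)."""
    st, fl, stmt, met = (result.state, result.flows, result.statement,
                         result.metrics)
    inv_total = st.total
    rows: dict[str, tuple[float, float | None]] = {}

    def share(x: float, total: float) -> float:
        return 100.0 * x / total if total > 0 else 0.0

    rows["Inventory / Adult/breeding females"] = (
        st.breeding_females, share(st.breeding_females, inv_total))
    rows["Inventory / Adult/breeding males"] = (
        st.stock[("adult", "m")], share(st.stock[("adult", "m")], inv_total))
    rows["Inventory / Other females"] = (
        st.other_females, share(st.other_females, inv_total))
    rows["Inventory / Other males"] = (
        st.other_males, share(st.other_males, inv_total))
    rows["Inventory / Total"] = (inv_total, None)

    d_ad = fl.deaths_by_class("adult")
    d_sa = fl.deaths_by_class("subadult")
    d_la = fl.deaths_by_class("lamb")
    d_tot = fl.total_deaths
    rows["Deaths / Adults/breeders"] = (d_ad, share(d_ad, d_tot))
    rows["Deaths / Sub-adults"] = (d_sa, share(d_sa, d_tot))
    rows["Deaths / Lambs"] = (d_la, share(d_la, d_tot))
    rows["Deaths / Total"] = (d_tot, None)

    o_tot = fl.total_offtake
    for label, key in [
        ("Adult/breeding females", ("adult", "f")),
        ("Adult/breeding males", ("adult", "m")),
        ("Sub-adult females", ("subadult", "f")),
        ("Sub-adult males", ("subadult", "m")),
        ("Lambs", ("lamb", "f")),
    ]:
        if label == "Lambs":
            head = fl.offtake_by_class("lamb")
        else:
            head = fl.offtake[key]
        rows[f"Live animal offtake / {label}"] = (head, share(head, o_tot))
    rows["Live animal offtake / Total"] = (o_tot, None)

    v_tot = stmt.total_usd
    rows["Offtake value (USD) / Live animals"] = (
        stmt.live_total_usd, share(stmt.live_total_usd, v_tot))
    rows["Offtake value (USD) / Manure"] = (
        stmt.manure_usd, share(stmt.manure_usd, v_tot))
    if stmt.inventory_birr:
        rows["Offtake value (USD) / Inventory change"] = (
            stmt.inventory_usd, share(stmt.inventory_usd, v_tot))
    rows["Offtake value (USD) / Total"] = (v_tot, None)
    rows["Offtake value (USD) / Per head"] = (met.per_head, None)
    rows["Offtake value (USD) / Per breeding female"] = (
        met.per_breeding_female, None)
    rows["Offtake value (USD) / Per 100 kg feed DM"] = (
        met.per_100kg_feed_dm, None)
    return rows


def table1_report(results: list[ScenarioResult]) -> pd.DataFrame:
    """Multi-scenario report in the Inventory / Deaths / Offtake / Value
    layout, one (Nr, %) column pair per scenario, rounded to 1 decimal."""
    if not results:
        raise ValueError("need at least one scenario column")
    data = {}
    for res in results:
        label = f"{100 * res.lamb_mortality:g}% lamb mortality"
        col = _col(res)
        data[(label, "Nr")] = {k: round(v, 1) for k, (v, _) in col.items()}
        data[(label, "%")] = {
            k: (round(s, 1) if s is not None else None)
            for k, (_, s) in col.items()}
    frame = pd.DataFrame(data)
    frame.index.name = "row"
    return frame
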