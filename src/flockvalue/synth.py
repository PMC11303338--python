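"""Randomized, feasibility-checked parameter sets for testing and demos.

Draws emulate the structure of the baseline parameter file: per-class and
per-sex mortality risks, offtake rates, live weights and prices, plus the
manure and feed coefficients.  A single integer seed drives one
pseudo-random stream; fields are drawn in a fixed order so the same seed
reproduces the same parameter set on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import herd
from .params import (DemographicParameters, PriceAndCostParameters,
                     load_baseline_parameters, validate_parameters,
                     write_parameters)

__all__ = [
    "ParameterRanges",
    "generate_parameters",
    "feasibility_filter",
    "make_fixtures",
]


@dataclass(frozen=True)
class ParameterRanges:
    """Inclusive lower/upper bounds for every randomized field.

    Defaults keep parturition in the 0.5-1.5 range plausible for systems
    with 7-10 month lambing intervals, class mortality risks below 0.4,
    and log-uniform positive prices wide enough to cover the large
    male/female price spreads seen in field data.
    """

    n_breeding_females: tuple[float, float] = (50.0, 500.0)
    male_breeder_ratio: tuple[float, float] = (0.02, 0.2)
    parturition_rate: tuple[float, float] = (0.5, 1.5)
    prolificacy: tuple[float, float] = (1.0, 1.5)
    sex_ratio_at_birth: tuple[float, float] = (0.45, 0.55)
    lamb_mortality: tuple[float, float] = (0.0, 0.4)
    subadult_mortality: tuple[float, float] = (0.0, 0.4)
    adult_mortality: tuple[float, float] = (0.01, 0.2)
    subadult_offtake: tuple[float, float] = (0.0, 0.6)
    live_weight_kg: tuple[float, float] = (8.0, 45.0)
    price_birr: tuple[float, float] = (500.0, 8000.0)  # log-uniform
    manure_output: tuple[float, float] = (2.0, 15.0)
    manure_price: tuple[float, float] = (0.05, 1.0)  # log-uniform
    feed_dm_fraction: tuple[float, float] = (0.02, 0.035)

    def validate(self) -> None:
        for name, (lo, hi) in self.__dict__.items():
            if lo > hi:
                raise ValueError(f"range {name}: lower {lo} > upper {hi}")


# fixed draw order; shuffling it would silently change every seeded fixture
_DEMO_DRAWS = (
    ("n_breeding_females", "n_breeding_females", "uniform"),
    ("male_breeder_ratio", "male_breeder_ratio", "uniform"),
    ("parturition_rate", "parturition_rate", "uniform"),
    ("prolificacy", "prolificacy", "uniform"),
    ("sex_ratio_at_birth", "sex_ratio_at_birth", "uniform"),
    ("lamb_mortality", "lamb_mortality", "uniform"),
    ("subadult_mortality_f", "subadult_mortality", "uniform"),
    ("subadult_mortality_m", "subadult_mortality", "uniform"),
    ("adult_mortality_f", "adult_mortality", "uniform"),
    ("adult_mortality_m", "adult_mortality", "uniform"),
    ("subadult_offtake_f", "subadult_offtake", "uniform"),
    ("subadult_offtake_m", "subadult_offtake", "uniform"),
)
_CLASS_KEYS = ("lamb", "subadult_f", "subadult_m", "adult_f", "adult_m")


def _draw(rng: np.random.Generator, bounds: tuple[float, float],
          how: str) -> float:
    lo, hi = bounds
    if lo == hi:
        return float(lo)
    if how == "log":
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return float(rng.uniform(lo, hi))


def generate_parameters(
    seed: int, ranges: ParameterRanges | None = None
) -> tuple[DemographicParameters, PriceAndCostParameters]:
    """Draw one parameter set; deterministic in ``seed``, always valid."""
    ranges = ranges or ParameterRanges()
    ranges.validate()
    rng = np.random.default_rng(seed)
    demo = {name: _draw(rng, getattr(ranges, src), how)
            for name, src, how in _DEMO_DRAWS}
    d = DemographicParameters(**demo)
    live_weight = {k: _draw(rng, ranges.live_weight_kg, "uniform")
                   for k in _CLASS_KEYS}
    price = {k: _draw(rng, ranges.price_birr, "log") for k in _CLASS_KEYS}
    p = PriceAndCostParameters(
        live_weight=live_weight,
        price=price,
        manure_output_kg_per_kg_liveweight_year=_draw(
            rng, ranges.manure_output, "uniform"),
        manure_price_birr_per_kg=_draw(rng, ranges.manure_price, "log"),
        feed_dm_fraction=_draw(rng, ranges.feed_dm_fraction, "uniform"),
    )
    violations = validate_parameters(d, p)
    if violations:  # pragma: no cover - bounds are within field invariants
        raise AssertionError(f"generator produced invalid set: {violations}")
    return d, p


def feasibility_filter(d: DemographicParameters) -> tuple[bool, str]:
    """True iff a stationary solution exists; reason names the failing sex."""
    try:
        herd.solve_stationary_offtake(d)
    except herd.InfeasibleParameterError as exc:
        sex = "female" if exc.sex == "f" else "male"
        return False, (f"adult {sex} recruitment cannot cover losses "
                       f"(required offtake {exc.required_offtake:.4g})")
    return True, "feasible"


def _near_infeasible(d: DemographicParameters) -> DemographicParameters:
    """Bisect parturition_rate down to the feasibility boundary.

    Returns a variant whose solved adult offtake is tiny (< 1 head/yr for
    the limiting sex) but still non-negative.
    """
    lo, hi = 0.0, d.parturition_rate
    if not feasibility_filter(d.replace(parturition_rate=hi))[0]:
        raise ValueError("baseline itself infeasible; cannot bracket")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if feasibility_filter(d.replace(parturition_rate=mid))[0]:
            hi = mid
        else:
            lo = mid
    return d.replace(parturition_rate=hi)


def make_fixtures(out_dir: str | Path) -> list[Path]:
    """Write the baseline, high-fertility and edge-case parameter files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    d, p = load_baseline_parameters()
    variants = {
        "baseline_mcl_sheep.yaml": d,
        "high_fertility.yaml": d.replace(parturition_rate=1.00),
        "zero_ysm.yaml": d.replace(lamb_mortality=0.0),
        "maximal_ysm.yaml": d.replace(lamb_mortality=1.0),
        "near_infeasible.yaml": _near_infeasible(d),
    }
    written = []
    for name, variant in variants.items():
        path = out_dir / name
        write_parameters(path, variant, p)
        written.append(path)
    return written
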