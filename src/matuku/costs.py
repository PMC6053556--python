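"""Itemised cost-benefit model for call-count monitoring options.

Compares five ways of running the same sampling regime (15-min counts at
40 stations on six nights per season): field observers (OBS), mono or
stereo autonomous recorders, each with visual (spectrogram-scanning) or
audible (real-time listening) sound-file processing.  Costs are built
line item by line item — device purchase, file processing or paid count
time, deployment, driving to/from and around the site, programming or
briefing, and vehicle running — per year, then accumulated over the
design horizon.

All arithmetic is carried out on unrounded values; display values round
half away from zero at the end, so a year total can differ by a dollar
from the sum of its rounded line items.

A qualitative value matrix records what each option can deliver: a
call-rate index, an estimate of the number of calling individuals, and
opportunities for public participation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "LINE_ITEMS",
    "COST_OPTIONS",
    "CostRates",
    "OptionAssumptions",
    "MonitoringDesign",
    "CostBreakdown",
    "ValueMatrix",
    "default_rates",
    "default_design",
    "default_options",
    "line_item_costs",
    "compute_option_cost",
    "percent_saving",
    "render_table2",
    "value_matrix",
    "load_cost_config",
    "round_display",
]

LINE_ITEMS = (
    "purchase",
    "processing_counting",
    "deployment",
    "drive_to_from",
    "drive_around",
    "programming",
    "vehicle_running",
)

COST_OPTIONS = ("MONO-VISUAL", "MONO-AUDIBLE", "STEREO-VISUAL", "STEREO-AUDIBLE", "OBS")


def round_display(x: float) -> int:
    """Round half away from zero to a whole currency unit (112.5 -> 113)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class CostRates:
    """Shared wage, mileage and travel-time rates (NZ$-like, unitless)."""

    wage_per_hr: float = 25.0
    vehicle_per_km: float = 0.77
    return_trip_km: float = 130.0
    return_trip_hr: float = 2.0
    circuit_hr: float = 0.75  # one trip around the wetland visiting all stations

    def __post_init__(self) -> None:
        for name in ("wage_per_hr", "vehicle_per_km", "return_trip_km", "return_trip_hr", "circuit_hr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class MonitoringDesign:
    """The sampling regime the costs are quoted for."""

    n_stations: int = 40
    n_occasions: int = 6
    count_duration_min: float = 15.0
    years: int = 2

    def __post_init__(self) -> None:
        if self.n_stations < 0 or self.n_occasions < 0:
            raise ValueError("station and occasion counts must be >= 0")
        if self.count_duration_min <= 0:
            raise ValueError("count_duration_min must be > 0")
        if self.years < 1:
            raise ValueError("years must be >= 1")


@dataclass(frozen=True)
class OptionAssumptions:
    """Per-option cost assumptions.

    ``units`` is one device (or observer) per station when ``None``.
    ``*_accrual`` says whether programming/deployment effort recurs every
    sampling occasion or once per year.  ``per_observer_travel`` marks the
    observer option, whose travel wages accrue per person per occasion and
    whose vehicle costs scale with ceil(units / observers_per_vehicle)
    vehicles.  ``year2_vehicle_override`` replaces the computed vehicle
    running cost from year two on, where a table-specified figure exists.
    """

    option_name: str
    device_price: float
    program_min_per_unit: float
    program_accrual: str  # per_year | per_occasion
    deploy_min_per_unit: float
    deploy_accrual: str
    wage_trips_per_year: int
    vehicle_trips_per_year: int
    circuits_per_year: int
    processing_hr_per_file: float | None = None
    counting_hr_per_session: float | None = None
    per_observer_travel: bool = False
    observers_per_vehicle: int = 5
    units: int | None = None
    year2_vehicle_override: float | None = None

    def __post_init__(self) -> None:
        if self.program_accrual not in ("per_year", "per_occasion"):
            raise ValueError("program_accrual must be per_year or per_occasion")
        if self.deploy_accrual not in ("per_year", "per_occasion"):
            raise ValueError("deploy_accrual must be per_year or per_occasion")
        if self.device_price < 0:
            raise ValueError("device_price must be >= 0")

    def n_units(self, design: MonitoringDesign) -> int:
        return design.n_stations if self.units is None else self.units


@dataclass(frozen=True)
class CostBreakdown:
    """Line items and totals per year plus cumulative cost for one option."""

    option_name: str
    per_year: tuple[Mapping[str, float], ...]  # unrounded line items, index 0 = year 1
    year_totals_unrounded: tuple[float, ...]
    cumulative_unrounded: float

    @property
    def per_year_display(self) -> tuple[dict[str, int], ...]:
        return tuple({k: round_display(v) for k, v in yr.items()} for yr in self.per_year)

    @property
    def year_totals_display(self) -> tuple[int, ...]:
        return tuple(round_display(t) for t in self.year_totals_unrounded)

    @property
    def cumulative_display(self) -> int:
        return round_display(self.cumulative_unrounded)


def default_rates() -> CostRates:
    return CostRates()


def default_design() -> MonitoringDesign:
    return MonitoringDesign()


def default_options() -> dict[str, OptionAssumptions]:
    """The five shipped monitoring options.

    Recorder options make one deploy trip and one retrieval trip per year
    (mono timers cover the season) except stereo units, which must be
    serviced before every occasion, so their trips, circuits and
    per-occasion programming scale with the number of nights.  Observers
    travel on wages individually every occasion, with one vehicle per
    five observers.  Two table-calibrated figures are kept as explicit
    configuration rather than derived: the mono option charges one return
    trip as wages while running the vehicle for two, and the stereo
    year-two vehicle cost uses the fixed override 554.
    """
    mono_common = dict(
        device_price=300.0,
        program_min_per_unit=2.5,
        program_accrual="per_year",
        deploy_min_per_unit=2.0,
        deploy_accrual="per_year",
        wage_trips_per_year=1,
        vehicle_trips_per_year=2,
        circuits_per_year=2,
    )
    stereo_common = dict(
        device_price=600.0,
        program_min_per_unit=3.0,
        program_accrual="per_occasion",
        deploy_min_per_unit=10.0,
        deploy_accrual="per_year",
        wage_trips_per_year=6,
        vehicle_trips_per_year=6,
        circuits_per_year=6,
        year2_vehicle_override=554.0,
    )
    return {
        "MONO-VISUAL": OptionAssumptions(
            "MONO-VISUAL", processing_hr_per_file=0.1, **mono_common
        ),
        "MONO-AUDIBLE": OptionAssumptions(
            "MONO-AUDIBLE", processing_hr_per_file=0.25, **mono_common
        ),
        "STEREO-VISUAL": OptionAssumptions(
            "STEREO-VISUAL", processing_hr_per_file=0.1, **stereo_common
        ),
        "STEREO-AUDIBLE": OptionAssumptions(
            "STEREO-AUDIBLE", processing_hr_per_file=0.25, **stereo_common
        ),
        "OBS": OptionAssumptions(
            "OBS",
            device_price=0.0,
            program_min_per_unit=30.0,  # pre-occasion briefing
            program_accrual="per_occasion",
            deploy_min_per_unit=1.0,  # orientation at the drop-off point
            deploy_accrual="per_year",
            wage_trips_per_year=6,
            vehicle_trips_per_year=6,
            circuits_per_year=6,
            counting_hr_per_session=None,  # derived from count duration
            per_observer_travel=True,
            observers_per_vehicle=5,
        ),
    }


def line_item_costs(
    option: OptionAssumptions,
    design: MonitoringDesign,
    rates: CostRates,
    year: int,
) -> dict[str, float]:
    """Unrounded cost of every line item for one option in one year."""
    if year < 1:
        raise ValueError("year must be >= 1")
    units = option.n_units(design)
    occ = design.n_occasions
    wage = rates.wage_per_hr

    purchase = option.device_price * units if year == 1 else 0.0

    if option.processing_hr_per_file is not None:
        hr = option.processing_hr_per_file
    elif option.counting_hr_per_session is not None:
        hr = option.counting_hr_per_session
    else:
        hr = design.count_duration_min / 60.0
    processing_counting = design.n_stations * occ * hr * wage

    program_mult = occ if option.program_accrual == "per_occasion" else 1
    programming = units * option.program_min_per_unit / 60.0 * wage * program_mult

    deploy_mult = occ if option.deploy_accrual == "per_occasion" else 1
    deployment = units * option.deploy_min_per_unit / 60.0 * wage * deploy_mult

    if option.per_observer_travel:
        # Every observer is paid for travel on every occasion.
        drive_to_from = rates.return_trip_hr * wage * units * occ
        drive_around = rates.circuit_hr * wage * units * occ
        vehicles = math.ceil(units / option.observers_per_vehicle)
    else:
        drive_to_from = rates.return_trip_hr * wage * option.wage_trips_per_year
        drive_around = rates.circuit_hr * wage * option.circuits_per_year
        vehicles = 1

    vehicle_running = (
        rates.return_trip_km * rates.vehicle_per_km * option.vehicle_trips_per_year * vehicles
    )
    if year >= 2 and option.year2_vehicle_override is not None:
        vehicle_running = option.year2_vehicle_override

    return {
        "purchase": purchase,
        "processing_counting": processing_counting,
        "deployment": deployment,
        "drive_to_from": drive_to_from,
        "drive_around": drive_around,
        "programming": programming,
        "vehicle_running": vehicle_running,
    }


def compute_option_cost(
    option: OptionAssumptions,
    design: MonitoringDesign | None = None,
    rates: CostRates | None = None,
) -> CostBreakdown:
    """Assemble all years of one option's costs with unrounded accumulation."""
    design = design or default_design()
    rates = rates or default_rates()
    per_year = tuple(
        line_item_costs(option, design, rates, y) for y in range(1, design.years + 1)
    )
    totals = tuple(sum(items.values()) for items in per_year)
    return CostBreakdown(
        option_name=option.option_name,
        per_year=per_year,
        year_totals_unrounded=totals,
        cumulative_unrounded=sum(totals),
    )


def percent_saving(option_a_cumulative: float, option_b_cumulative: float) -> int:
    """Percentage saved by choosing option a over option b, whole percent."""
    if option_b_cumulative <= 0:
        raise ValueError("reference cumulative cost must be > 0")
    return round_display(100.0 * (1.0 - option_a_cumulative / option_b_cumulative))


_ITEM_LABELS = {
    "purchase": "Purchase",
    "processing_counting": "Processing/counting",
    "deployment": "Deployment",
    "drive_to_from": "Driving to/from site",
    "drive_around": "Driving around site",
    "programming": "Programming",
    "vehicle_running": "Vehicle running",
}


def render_table2(
    options: Mapping[str, OptionAssumptions] | None = None,
    design: MonitoringDesign | None = None,
    rates: CostRates | None = None,
) -> pd.DataFrame:
    """Full cost table: line items and total per year, then cumulative cost.

    Rows are (year, item) pairs plus the cumulative row; columns are the
    five options; every cell is a display-rounded whole currency value.
    """
    options = options or default_options()
    design = design or default_design()
    rates = rates or default_rates()
    breakdowns = {
        name: compute_option_cost(opt, design, rates) for name, opt in options.items()
    }
    cols = [name for name in COST_OPTIONS if name in breakdowns] + [
        name for name in breakdowns if name not in COST_OPTIONS
    ]
    rows = []
    index = []
    for y in range(design.years):
        for item in LINE_ITEMS:
            index.append((f"Year {y + 1}", _ITEM_LABELS[item]))
            rows.append([breakdowns[c].per_year_display[y][item] for c in cols])
        index.append((f"Year {y + 1}", "Total ($)"))
        rows.append([breakdowns[c].year_totals_display[y] for c in cols])
    index.append(("Cumulative", f"Cumulative costs (NZ$ over {design.years} years)"))
    rows.append([breakdowns[c].cumulative_display for c in cols])
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["year", "item"]), columns=cols
    )


@dataclass(frozen=True)
class ValueMatrix:
    """Qualitative capabilities of each option.

    Levels: ``easy`` (achievable as a matter of course), ``with_work``
    (achievable with extra effort), ``no`` (currently unachievable).
    """

    capabilities: Mapping[str, Mapping[str, str]]
    cumulative_costs: Mapping[str, int]

    LEVELS = ("easy", "with_work", "no")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.capabilities).T
        df["cumulative_cost"] = [self.cumulative_costs[o] for o in df.index]
        return df


def value_matrix(
    design: MonitoringDesign | None = None, rates: CostRates | None = None
) -> ValueMatrix:
    """What each monitoring option can deliver, alongside its cumulative cost.

    All options index call rate easily.  Only stereo recordings processed
    audibly can estimate numbers of calling individuals (with work, via
    the volume x direction rules); observers do so easily.  Only the
    observer option engages the public.
    """
    caps = {
        "MONO-VISUAL": {"index_call_rate": "easy", "estimate_numbers": "no", "public_participation": "no"},
        "MONO-AUDIBLE": {"index_call_rate": "easy", "estimate_numbers": "no", "public_participation": "no"},
        "STEREO-VISUAL": {"index_call_rate": "easy", "estimate_numbers": "no", "public_participation": "no"},
        "STEREO-AUDIBLE": {"index_call_rate": "easy", "estimate_numbers": "with_work", "public_participation": "no"},
        "OBS": {"index_call_rate": "easy", "estimate_numbers": "easy", "public_participation": "easy"},
    }
    costs = {
        name: compute_option_cost(opt, design, rates).cumulative_display
        for name, opt in default_options().items()
    }
    return ValueMatrix(capabilities=caps, cumulative_costs=costs)


def load_cost_config(
    path: str,
) -> tuple[dict[str, OptionAssumptions], MonitoringDesign, CostRates]:
    """Load rates / design / option overrides from a YAML or JSON file.

    The file may carry any of the top-level keys ``rates``, ``design`` and
    ``options``; omitted fields keep their shipped defaults, and options
    are overridden field-wise by name.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    rates = replace(default_rates(), **cfg.get("rates", {}))
    design = replace(default_design(), **cfg.get("design", {}))
    options = default_options()
    for name, overrides in cfg.get("options", {}).items():
        if name not in options:
            raise ValueError(f"unknown option {name!r} in config")
        options[name] = replace(options[name], **overrides)
    return options, design, rates
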