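"""Techno-economic model of the green coconut biorefinery.

Covers six-tenths-rule equipment cost scaling, the batch mass balance,
product revenue, nominal discounted cash flows (NPV, IRR, payback) and
price-sensitivity scenarios.  The baseline scenario carries the plant
basis of the reference study: 1 t of green coconut per batch, 1346
batches per year over 300 operating days, products sold as cases of
10 x 1 L coconut water (US$16.80) and 10 x 0.4 kg pulp (US$11.20),
a 13% discount rate, 4% inflation, 20 operating years after a 30-month
construction period and 4-month startup.

Cash-flow timing is deliberately simple and fully stated: CAPEX is
spread over the construction years proportionally to calendar overlap,
operations begin after startup, revenue and OPEX inflate from year 0,
flows are nominal year-end sums, and NPV discounts flow t by
(1 + rate)^t.  Taxes, depreciation and working-capital release are not
modeled; headline profitability indicators of proprietary simulators
are therefore not reproduction targets, only the accounting identities
and orderings are.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize

__all__ = [
    "EquipmentCostSpec",
    "CoconutComposition",
    "PlantBasis",
    "Product",
    "RevenueModel",
    "CashFlowModel",
    "TEAResult",
    "epc_scale",
    "mass_balance",
    "annual_revenue",
    "build_cashflows",
    "npv",
    "irr",
    "payback",
    "run_tea",
    "sensitivity",
    "baseline_scenario",
]


@dataclass(frozen=True)
class EquipmentCostSpec:
    """Reference-capacity equipment cost with a power-law scale exponent."""

    name: str
    C0: float
    Q0: float
    Q: float
    a: float = 0.6

    def __post_init__(self) -> None:
        if self.C0 <= 0 or self.Q0 <= 0 or self.Q <= 0:
            raise ValueError("cost and capacities must be positive")
        if not (0.0 < self.a <= 1.0):
            raise ValueError("scale exponent must lie in (0, 1]")


def epc_scale(spec: EquipmentCostSpec) -> float:
    """Equipment purchase cost C0 * (Q/Q0)^a (the six-tenths rule at a=0.6)."""
    return spec.C0 * (spec.Q / spec.Q0) ** spec.a


@dataclass(frozen=True)
class CoconutComposition:
    """Whole-fruit mass fractions; must sum to 1."""

    husk: float = 0.336
    shell: float = 0.165
    albumen: float = 0.304
    water: float = 0.195

    def __post_init__(self) -> None:
        fr = (self.husk, self.shell, self.albumen, self.water)
        if any(f < 0 for f in fr):
            raise ValueError("mass fractions must be non-negative")
        if abs(sum(fr) - 1.0) > 1e-6:
            raise ValueError(f"mass fractions sum to {sum(fr)}, not 1")


@dataclass(frozen=True)
class PlantBasis:
    batch_mass_kg: float = 1000.0
    batches_per_year: int = 1346
    operating_days: int = 300
    design_flux_lhm: float = 300.0

    def __post_init__(self) -> None:
        if min(self.batch_mass_kg, self.batches_per_year,
               self.operating_days, self.design_flux_lhm) <= 0:
            raise ValueError("plant basis values must be positive")


def mass_balance(basis: PlantBasis, composition: CoconutComposition) -> dict[str, float]:
    """Annual feed and per-stream masses (kg/year)."""
    feed = basis.batch_mass_kg * basis.batches_per_year
    return {
        "feed": feed,
        "husk": feed * composition.husk,
        "shell": feed * composition.shell,
        "albumen": feed * composition.albumen,
        "water": feed * composition.water,
    }


@dataclass(frozen=True)
class Product:
    name: str
    cases_per_year: float
    price_per_case: float

    def __post_init__(self) -> None:
        if self.cases_per_year < 0 or self.price_per_case < 0:
            raise ValueError("quantities must be non-negative")


@dataclass
class RevenueModel:
    products: list[Product]

    def scaled(self, multiplier: float) -> "RevenueModel":
        return RevenueModel(
            products=[
                Product(p.name, p.cases_per_year, p.price_per_case * multiplier)
                for p in self.products
            ]
        )


def annual_revenue(model: RevenueModel) -> dict[str, float]:
    """Per-product and total annual revenue (US$)."""
    out = {p.name: p.cases_per_year * p.price_per_case for p in model.products}
    out["total"] = sum(out.values())
    return out


@dataclass
class CashFlowModel:
    capex_total: float
    opex_annual: float
    revenue_annual: float
    discount_rate: float = 0.13
    inflation: float = 0.04
    project_years: int = 20
    construction_months: int = 30
    startup_months: int = 4

    def __post_init__(self) -> None:
        for r in (self.discount_rate, self.inflation):
            if not (0.0 <= r < 1.0):
                raise ValueError("rates must lie in [0, 1)")
        if self.project_years <= 0 or self.construction_months < 0:
            raise ValueError("inconsistent project periods")


def build_cashflows(model: CashFlowModel) -> np.ndarray:
    """Nominal year-end net cash flows over the project timeline.

    Year 0 starts at the beginning of construction.  CAPEX is allocated
    to each calendar year by its overlap with the construction window;
    operating flows (revenue - OPEX) accrue from the end of startup for
    ``project_years`` years, pro-rated in partial years and inflated at
    the stated rate from year 0.
    """
    c_years = model.construction_months / 12.0
    op_start = c_years + model.startup_months / 12.0
    op_end = op_start + model.project_years
    n_years = int(np.ceil(op_end))
    flows = np.zeros(n_years)
    for y in range(n_years):
        capex_frac = (
            max(0.0, min(y + 1, c_years) - min(y, c_years)) / c_years
            if c_years > 0 else (1.0 if y == 0 else 0.0)
        )
        op_frac = max(0.0, min(y + 1, op_end) - max(y, op_start))
        net_op = op_frac * (model.revenue_annual - model.opex_annual)
        flows[y] = -capex_frac * model.capex_total + net_op * (1.0 + model.inflation) ** y
    return flows


def npv(flows, rate: float) -> float:
    """Net present value: sum of flow_t / (1+rate)^t, t = 0, 1, ..."""
    flows = np.asarray(flows, dtype=float)
    if flows.size == 0:
        raise ValueError("empty flow vector")
    t = np.arange(flows.size)
    return float(np.sum(flows / (1.0 + rate) ** t))


def irr(flows) -> float:
    """Internal rate of return (fraction) by bracketed root finding."""
    flows = np.asarray(flows, dtype=float)
    if not (np.any(flows > 0) and np.any(flows < 0)):
        raise ValueError("IRR undefined: flows have no sign change")
    lo, hi = -0.9999, 1.0
    while npv(flows, hi) > 0 and hi < 1e6:
        hi *= 2.0
    return float(optimize.brentq(lambda r: npv(flows, r), lo, hi, xtol=1e-10))


def payback(flows) -> float:
    """Years until cumulative undiscounted flow first reaches zero.

    Linear interpolation inside the crossing year; raises if the
    cumulative flow never turns non-negative.
    """
    flows = np.asarray(flows, dtype=float)
    cum = np.cumsum(flows)
    if cum[0] >= 0:
        return 0.0
    cross = np.flatnonzero(cum >= 0)
    if cross.size == 0:
        raise ValueError("cumulative cash flow never recovers the investment")
    t = int(cross[0])
    return float((t - 1) + (-cum[t - 1]) / flows[t])


@dataclass
class TEAResult:
    label: str
    price_multiplier: float
    prices: dict[str, float]
    revenue: dict[str, float]
    npv: float
    irr_pct: float
    payback_years: float
    gross_margin_pct: float
    flows: list[float] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return asdict(self)


@dataclass
class BiorefineryScenario:
    """Full techno-economic scenario: basis, prices, costs and rates."""

    basis: PlantBasis
    composition: CoconutComposition
    revenue: RevenueModel
    capex_items: dict[str, float]
    opex_items: dict[str, float]
    discount_rate: float = 0.13
    inflation: float = 0.04
    project_years: int = 20
    construction_months: int = 30
    startup_months: int = 4
    equipment: list[EquipmentCostSpec] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def capex_total(self) -> float:
        return sum(self.capex_items.values())

    @property
    def opex_total(self) -> float:
        return sum(self.opex_items.values())


def run_tea(
    scenario: BiorefineryScenario,
    price_multiplier: float = 1.0,
    label: str = "base",
) -> TEAResult:
    """Evaluate one scenario: revenue, cash flows, NPV/IRR/payback."""
    rev_model = scenario.revenue.scaled(price_multiplier)
    rev = annual_revenue(rev_model)
    cfm = CashFlowModel(
        capex_total=scenario.capex_total,
        opex_annual=scenario.opex_total,
        revenue_annual=rev["total"],
        discount_rate=scenario.discount_rate,
        inflation=scenario.inflation,
        project_years=scenario.project_years,
        construction_months=scenario.construction_months,
        startup_months=scenario.startup_months,
    )
    flows = build_cashflows(cfm)
    npv_val = npv(flows, scenario.discount_rate)
    try:
        irr_pct = 100.0 * irr(flows)
    except ValueError:
        irr_pct = float("nan")
    try:
        pb = payback(flows)
    except ValueError:
        pb = float("inf")
    margin = 100.0 * (rev["total"] - scenario.opex_total) / rev["total"] \
        if rev["total"] > 0 else float("nan")
    return TEAResult(
        label=label,
        price_multiplier=price_multiplier,
        prices={p.name: p.price_per_case for p in rev_model.products},
        revenue=rev,
        npv=npv_val,
        irr_pct=irr_pct,
        payback_years=pb,
        gross_margin_pct=margin,
        flows=flows.tolist(),
    )


def sensitivity(
    scenario: BiorefineryScenario,
    price_multipliers=(0.8, 0.9, 1.0, 1.1, 1.2),
) -> list[TEAResult]:
    """Scale both product prices by each multiplier and recompute."""
    return [
        run_tea(scenario, m, label=f"{(m - 1.0) * 100:+.0f}%" if m != 1.0 else "base")
        for m in price_multipliers
    ]


# ---- baseline fixture --------------------------------------------------

#: CAPEX line items (US$), screening-level composition of the baseline plant.
BASELINE_CAPEX = {
    "equipment_purchase": 135_000.0,
    "installation": 57_000.0,
    "process_piping": 47_000.0,
    "instrumentation": 54_000.0,
    "insulation": 4_000.0,
    "electrical": 14_000.0,
    "buildings": 61_000.0,
    "yard_improvement": 20_000.0,
    "auxiliary_facilities": 54_000.0,
    "engineering": 112_000.0,
    "construction": 156_000.0,
    "contractors_fee": 36_000.0,
    "contingency": 71_000.0,
    "working_capital": 97_000.0,
    "startup_cost": 41_000.0,
}

#: Annual OPEX line items (US$).
BASELINE_OPEX = {
    "raw_materials": 664_000.0,
    "labor": 245_000.0,
    "facility": 155_000.0,
    "consumables": 1_000.0,
    "waste_treatment": 57_000.0,
    "utilities": 1_000.0,
    "transportation": 55_000.0,
}


def baseline_scenario() -> BiorefineryScenario:
    """The baseline biorefinery scenario with its published basis.

    Coconut-water case count: the source text prints "2574.21 cases" but
    the stated water revenue (US$432,468 at US$16.80/case) implies
    25,742.1 cases - a probable decimal typo; the implied value is used
    and the printed string preserved in metadata.
    """
    return BiorefineryScenario(
        basis=PlantBasis(),
        composition=CoconutComposition(),
        revenue=RevenueModel(
            products=[
                Product("coconut_water", cases_per_year=25_742.1, price_per_case=16.80),
                Product("pulp", cases_per_year=103_226.25, price_per_case=11.20),
            ]
        ),
        capex_items=dict(BASELINE_CAPEX),
        opex_items=dict(BASELINE_OPEX),
        metadata={
            "currency": "US$",
            "base_year": 2023,
            "exchange_rate_BRL_per_USD": 5.00,
            "water_cases_printed": "2574.21",
            "water_cases_note": "implied by revenue 432,468 / 16.80 = 25,742.1",
            "operator_wage_usd_h": 1.86,
            "supervisor_wage_usd_h": 2.60,
        },
    )


def load_scenario(path) -> BiorefineryScenario:
    """Read a scenario config from JSON or YAML."""
    text = open(path, encoding="utf-8").read()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return BiorefineryScenario(
        basis=PlantBasis(**d.get("basis", {})),
        composition=CoconutComposition(**d.get("composition", {})),
        revenue=RevenueModel(products=[Product(**p) for p in d["products"]]),
        capex_items=d["capex_items"],
        opex_items=d["opex_items"],
        discount_rate=d.get("discount_rate", 0.13),
        inflation=d.get("inflation", 0.04),
        project_years=d.get("project_years", 20),
        construction_months=d.get("construction_months", 30),
        startup_months=d.get("startup_months", 4),
        equipment=[EquipmentCostSpec(**e) for e in d.get("equipment", [])],
        metadata=d.get("metadata", {}),
    )
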