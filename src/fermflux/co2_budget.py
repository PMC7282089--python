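"""CO2 supply-demand budget for a sparged fermentation.

Succinate formation fixes one CO2 per mol at the PEPCK carboxylation, so the
PEPCK demand per mol glucose equals the succinate yield. The only net
CO2-forming catabolic reaction is PFOR (one CO2 per turnover), so endogenous
production per mol glucose equals the PFOR flux. Exogenous supply is what the
sparge gas delivers over a time window, converted with a molar volume of
22.4 l/mol by default (standard molar volume; configurable for users wanting
a temperature-corrected value). Gas-liquid transfer is taken as 100%
efficient, so the supply figure is an upper bound on what reaches the broth.
The fermentation is called CO2 self-sufficient when endogenous production
covers the PEPCK demand on the per-glucose basis.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cofactor_balance import FluxVector
from .yield_pipeline import ConditionMeta, YieldProfile

__all__ = [
    "STANDARD_MOLAR_VOLUME_L_PER_MOL",
    "CO2Budget",
    "co2_supplied",
    "pepck_demand",
    "pfor_co2",
    "budget_report",
]

STANDARD_MOLAR_VOLUME_L_PER_MOL = 22.4


@dataclass(frozen=True)
class CO2Budget:
    """Supply, demand and endogenous production of CO2 over a window."""

    supplied_exogenous_mmol: float
    demand_pepck_per_glucose: float  # mol CO2 per mol glucose
    demand_pepck_mmol: float | None
    produced_pfor_per_glucose: float
    produced_pfor_mmol: float | None
    molar_volume_l_per_mol: float
    window_h: float
    self_sufficient: bool

    def __post_init__(self) -> None:
        for name in (
            "supplied_exogenous_mmol",
            "demand_pepck_per_glucose",
            "produced_pfor_per_glucose",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def verdict(self) -> str:
        rel = ">=" if self.self_sufficient else "<"
        state = (
            "self-sufficient: endogenous PFOR CO2 covers the PEPCK demand"
            if self.self_sufficient
            else "not self-sufficient: succinate formation depends on exogenous CO2"
        )
        return (
            f"Over {self.window_h:g} h the sparge gas supplied "
            f"{self.supplied_exogenous_mmol:.1f} mmol CO2. PEPCK fixes "
            f"{self.demand_pepck_per_glucose:.2f} mol CO2 per mol glucose for "
            f"the observed succinate production, while PFOR releases "
            f"{self.produced_pfor_per_glucose:.2f} mol CO2 per mol glucose "
            f"({self.produced_pfor_per_glucose:.2f} {rel} "
            f"{self.demand_pepck_per_glucose:.2f}). The fermentation is {state}."
        )


def co2_supplied(
    gas_flow_l_per_h: float,
    co2_fraction: float,
    duration_h: float,
    molar_volume_l_per_mol: float = STANDARD_MOLAR_VOLUME_L_PER_MOL,
) -> float:
    """CO2 delivered by the sparge gas over a window, in mmol.

    mmol = flow [l/h] x CO2 fraction x duration [h] / molar volume [l/mol]
    x 1000.
    """
    if min(gas_flow_l_per_h, co2_fraction, duration_h) < 0:
        raise ValueError("flow, fraction and duration must be >= 0")
    if not 0 <= co2_fraction <= 1:
        raise ValueError("co2_fraction must lie in [0, 1]")
    if molar_volume_l_per_mol <= 0:
        raise ValueError("molar volume must be > 0")
    return (
        gas_flow_l_per_h * co2_fraction * duration_h / molar_volume_l_per_mol * 1e3
    )


def pepck_demand(
    profile: YieldProfile, glucose_consumed_mmol: float | None = None
) -> tuple[float, float | None]:
    """PEPCK CO2 demand: (mol per mol glucose, mmol over the window).

    One CO2 is fixed per succinate, so the per-glucose demand is the
    succinate yield; the absolute figure needs the glucose consumed (mmol)
    over the window of interest and is None when that is not given.
    """
    y_succ = profile.yields.get("succinate", 0.0)
    if glucose_consumed_mmol is None:
        return y_succ, None
    if glucose_consumed_mmol <= 0:
        raise ValueError("glucose_consumed_mmol must be > 0")
    return y_succ, y_succ * glucose_consumed_mmol


def pfor_co2(fluxes: FluxVector) -> float:
    """Endogenous CO2 from PFOR, mol per mol glucose (one per turnover)."""
    return fluxes.pfor


def budget_report(
    profile: YieldProfile,
    fluxes: FluxVector,
    meta: ConditionMeta | None = None,
    window_h: float = 24.0,
    glucose_consumed_mmol: float | None = None,
    gas_flow_l_per_h: float | None = None,
    co2_fraction: float | None = None,
    molar_volume_l_per_mol: float = STANDARD_MOLAR_VOLUME_L_PER_MOL,
) -> CO2Budget:
    """Assemble the full CO2 budget for one condition.

    Sparge parameters default to the run's :class:`ConditionMeta`; explicit
    arguments override. The window is a user parameter (the supply figure
    scales linearly with it), not inferred from the time series.
    """
    meta = meta if meta is not None else profile.meta
    flow = gas_flow_l_per_h if gas_flow_l_per_h is not None else meta.gas_flow_l_per_h
    frac = co2_fraction if co2_fraction is not None else meta.co2_fraction
    if flow is None or frac is None:
        raise ValueError(
            "gas flow and CO2 fraction must be given (argument or metadata)"
        )
    supplied = co2_supplied(flow, frac, window_h, molar_volume_l_per_mol)
    demand_per_glc, demand_mmol = pepck_demand(profile, glucose_consumed_mmol)
    produced_per_glc = pfor_co2(fluxes)
    produced_mmol = (
        produced_per_glc * glucose_consumed_mmol
        if glucose_consumed_mmol is not None
        else None
    )
    return CO2Budget(
        supplied_exogenous_mmol=supplied,
        demand_pepck_per_glucose=demand_per_glc,
        demand_pepck_mmol=demand_mmol,
        produced_pfor_per_glucose=produced_per_glc,
        produced_pfor_mmol=produced_mmol,
        molar_volume_l_per_mol=molar_volume_l_per_mol,
        window_h=window_h,
        self_sufficient=produced_per_glc >= demand_per_glc,
    )
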