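"""Cofactor flux accounting: from product yields to the eight derived
cofactor quantities, and between-condition comparison.

Because every pathway from PEP to an excreted product is linear, the internal
fluxes (in mol per mol glucose) are fully determined by the yields: each
product's pathway flux equals its yield, formate marks the PFL flux, and the
PFOR flux closes the acetyl-CoA node::

    pfl  = Y_formate
    pfor = Y_acetate + Y_ethanol - Y_formate

The summary maps fluxes through the model's per-unit cofactor vectors to the
eight quantities reported per mol glucose (production positive, consumption
negative): acetyl-CoA turnover, reduced ferredoxin from PFOR alone, total
reduced ferredoxin, NADH, NADPH, total redox cofactors (electron pairs),
acetate-kinase ATP alone, and total ATP-equivalents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .stoich_model import (
    COFACTORS,
    MEASURED_PRODUCTS,
    REACTION_IDS,
    AssumptionSet,
    PathwayModel,
)
from .yield_pipeline import YieldProfile

__all__ = [
    "SUMMARY_FIELDS",
    "FluxVector",
    "CofactorSummary",
    "ConditionComparison",
    "infer_fluxes",
    "cofactor_summary",
    "compare_conditions",
    "summary_against_oracle",
    "oracle_mismatches",
]

#: The eight derived quantities, in report order.
SUMMARY_FIELDS = (
    "accoa",
    "fd_pfor_only",
    "fd_total",
    "nadh",
    "nadph",
    "total_redox",
    "atp_ak_only",
    "atp_eq",
)

_CLOSURE_TOL = 1e-9


@dataclass(frozen=True)
class FluxVector:
    """Pathway fluxes in mol per mol glucose."""

    succinate: float = 0.0
    lactate: float = 0.0
    acetate: float = 0.0
    ethanol: float = 0.0
    pfl: float = 0.0
    pfor: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {rid: getattr(self, rid) for rid in REACTION_IDS}

    def scaled(self, k: float) -> "FluxVector":
        return FluxVector(**{r: k * v for r, v in self.as_dict().items()})

    def __add__(self, other: "FluxVector") -> "FluxVector":
        return FluxVector(
            **{r: v + getattr(other, r) for r, v in self.as_dict().items()}
        )

    def closure_gap(self) -> float:
        """Acetyl-CoA node imbalance: pfl + pfor - (acetate + ethanol)."""
        return self.pfl + self.pfor - (self.acetate + self.ethanol)


def _check_closure(fluxes: FluxVector, tol: float = _CLOSURE_TOL) -> None:
    gap = fluxes.closure_gap()
    if abs(gap) > tol:
        raise ValueError(
            f"acetyl-CoA node not closed: pfl + pfor - (acetate + ethanol) "
            f"= {gap:.3g}"
        )


def infer_fluxes(
    profile: YieldProfile,
    model: PathwayModel | None = None,
    allow_negative_pfor: bool = False,
    tol: float = _CLOSURE_TOL,
) -> FluxVector:
    """Determine pathway fluxes from a yield profile.

    A formate yield exceeding the acetyl-CoA demand (acetate + ethanol) would
    force a negative PFOR flux, which the pathway topology forbids; this is
    an error unless ``allow_negative_pfor`` is set, in which case PFOR is
    clamped to 0 and the PFL flux rescaled to close the node (with a warning).
    """
    y = {}
    for p in MEASURED_PRODUCTS:
        if p not in profile.yields:
            warnings.warn(f"yield for {p!r} missing; treated as 0")
        y[p] = profile.yields.get(p, 0.0)
    pfl = y["formate"]
    pfor = y["acetate"] + y["ethanol"] - y["formate"]
    if pfor < -tol:
        if not allow_negative_pfor:
            raise ValueError(
                f"formate yield exceeds acetyl-CoA demand by {-pfor:.4g} "
                "mol/mol glucose (negative PFOR flux); pass "
                "allow_negative_pfor=True to clamp"
            )
        warnings.warn(
            f"negative PFOR flux {pfor:.4g} clamped to 0; PFL rescaled to "
            "acetate + ethanol"
        )
        pfl = y["acetate"] + y["ethanol"]
        pfor = 0.0
    pfor = max(pfor, 0.0)
    return FluxVector(
        succinate=y["succinate"],
        lactate=y["lactate"],
        acetate=y["acetate"],
        ethanol=y["ethanol"],
        pfl=pfl,
        pfor=pfor,
    )


@dataclass(frozen=True)
class CofactorSummary:
    """The eight derived cofactor quantities, mol per mol glucose."""

    accoa: float
    fd_pfor_only: float
    fd_total: float
    nadh: float
    nadph: float
    total_redox: float
    atp_ak_only: float
    atp_eq: float
    assumptions: AssumptionSet = field(default=AssumptionSet(), compare=False)

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in SUMMARY_FIELDS}


def cofactor_summary(fluxes: FluxVector, model: PathwayModel) -> CofactorSummary:
    """Flux-weighted cofactor totals per mol glucose.

    The net malate-shunt transhydrogenation of the assumption set is applied
    once per mol glucose: it moves ``malate_shunt_transhydrogenation`` mol of
    reducing equivalents from the NADH ledger to the NADPH ledger.
    """
    _check_closure(fluxes)
    flux = np.array([getattr(fluxes, rid) for rid in REACTION_IDS])
    # reactions x cofactors stoichiometric matrix
    S = np.array(
        [list(model.reactions[rid].cofactors) for rid in REACTION_IDS]
    )
    totals = dict(zip(COFACTORS, flux @ S))

    a = model.assumptions
    shunt = a.malate_shunt_transhydrogenation
    nadh = totals["nadh"] - shunt
    nadph = totals["nadph"] + shunt
    fd_total = totals["fd_red"]
    fd_pfor_only = fluxes.pfor * model.reactions["pfor"].cofactors.fd_red
    # acetate kinase ATP = acetate's atp_eq beyond the PEP->pyruvate credit
    ak_stoich = (
        model.reactions["acetate"].cofactors.atp_eq - a.atp_per_pep_to_pyruvate
    )
    return CofactorSummary(
        accoa=totals["accoa"],
        fd_pfor_only=fd_pfor_only,
        fd_total=fd_total,
        nadh=nadh,
        nadph=nadph,
        total_redox=fd_total + nadh + nadph,
        atp_ak_only=fluxes.acetate * ak_stoich,
        atp_eq=totals["atp_eq"],
        assumptions=a,
    )


@dataclass(frozen=True)
class ConditionComparison:
    """Componentwise difference of two summaries (condition A - condition B).

    ``highlights`` restates the differences in the direction they are usually
    discussed for a CO2-limited (A) vs CO2-replete (B) pair: extra ferredoxin
    reduced via PFOR, fewer NADH oxidized, extra NADPH oxidized, the
    A-relative redox surplus in electron pairs (presumed discharged as H2),
    and the ATP-equivalent change with its acetate-kinase share.
    """

    differences: dict[str, float]
    redox_surplus: float
    highlights: dict[str, float]


def compare_conditions(
    a: CofactorSummary, b: CofactorSummary
) -> ConditionComparison:
    if a.assumptions != b.assumptions:
        raise ValueError(
            "summaries were computed under different model assumptions; "
            "rebuild both under one AssumptionSet before comparing"
        )
    diffs = {f: getattr(a, f) - getattr(b, f) for f in SUMMARY_FIELDS}
    surplus = diffs["total_redox"]
    highlights = {
        "extra_fd_red_via_pfor": diffs["fd_pfor_only"],
        "extra_fd_red_total": diffs["fd_total"],
        "fewer_nadh_oxidized": diffs["nadh"],
        "extra_nadph_oxidized": -diffs["nadph"],
        "redox_surplus_electron_pairs": surplus,
        "atp_eq_change": diffs["atp_eq"],
        "atp_change_from_acetate_kinase": diffs["atp_ak_only"],
    }
    return ConditionComparison(
        differences=diffs, redox_surplus=surplus, highlights=highlights
    )


def _oracle_summary(fluxes: FluxVector, model: PathwayModel) -> dict[str, float]:
    """Per-reaction loop recomputation of every summary field.

    Deliberately avoids the matrix product of :func:`cofactor_summary` so the
    two routes are independent implementations of the same definition; both
    enforce the same acetyl-CoA closure check.
    """
    _check_closure(fluxes)
    accoa = fd_total = nadh = nadph = atp_eq = 0.0
    for rid in REACTION_IDS:
        f = getattr(fluxes, rid)
        vec = model.reactions[rid].cofactors
        accoa += f * vec.accoa
        fd_total += f * vec.fd_red
        nadh += f * vec.nadh
        nadph += f * vec.nadph
        atp_eq += f * vec.atp_eq
    shunt = model.assumptions.malate_shunt_transhydrogenation
    nadh -= shunt
    nadph += shunt
    fd_pfor_only = fluxes.pfor * model.reactions["pfor"].cofactors.fd_red
    atp_ak_only = fluxes.acetate * (
        model.reactions["acetate"].cofactors.atp_eq
        - model.assumptions.atp_per_pep_to_pyruvate
    )
    return {
        "accoa": accoa,
        "fd_pfor_only": fd_pfor_only,
        "fd_total": fd_total,
        "nadh": nadh,
        "nadph": nadph,
        "total_redox": fd_total + nadh + nadph,
        "atp_ak_only": atp_ak_only,
        "atp_eq": atp_eq,
    }


def oracle_mismatches(
    fluxes: FluxVector, model: PathwayModel, tol: float = 1e-12
) -> list[str]:
    """Names of summary fields where the matrix and loop routes disagree."""
    fast = cofactor_summary(fluxes, model).as_dict()
    slow = _oracle_summary(fluxes, model)
    return [f for f in SUMMARY_FIELDS if abs(fast[f] - slow[f]) > tol]


def summary_against_oracle(
    fluxes: FluxVector, model: PathwayModel, tol: float = 1e-12
) -> bool:
    """True when both summary routes agree on every field within ``tol``."""
    return not oracle_mismatches(fluxes, model, tol)
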