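"""Declarative stoichiometry of the PEP branch point in a thermophilic
mixed-acid fermenter.

The model covers the pathways from phosphoenolpyruvate (PEP) to the excreted
fermentation products of *Pseudoclostridium thermosuccinogenes* — succinate,
lactate, acetate and ethanol — plus two bookkeeping entries for the
acetyl-CoA-forming pyruvate cleavage reactions:

* ``pfl``  — pyruvate formate lyase: pyruvate -> acetyl-CoA + formate.
  Redox-neutral; the C1 unit leaves as formate.
* ``pfor`` — pyruvate:ferredoxin oxidoreductase: pyruvate -> acetyl-CoA +
  CO2 + reduced ferredoxin (one electron pair).

Each reaction carries a :class:`CofactorVector` per unit flux (mol per mol of
product, production positive / consumption negative) and a glucose-carbon
coefficient used by the C-mole balance. Glycolytic cofactors (2 NADH and the
net ATP from glucose -> 2 PEP) are deliberately excluded: the ledger accounts
for the PEP-to-product branches only, which is the part that differs between
conditions. Cofactor assumptions that are genuinely uncertain in this
organism are explicit toggles in :class:`AssumptionSet`:

* fumarate reduction coupled to ferredoxin reduction through the
  electron-bifurcating NADH dehydrogenase / heterodisulfide reductase
  complex (succinate then costs 3 NADH and yields 1 reduced ferredoxin per
  mol, instead of 2 NADH);
* an NADPH-dependent alcohol dehydrogenase (ethanol then costs 1 NADH at the
  acetaldehyde step and 1 NADPH at the alcohol step);
* the ATP-equivalent credited per PEP -> pyruvate conversion;
* a net NADH -> NADPH transhydrogenation by the malate shunt, applied per mol
  glucose (it cancels in between-condition comparisons and defaults to 0).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import yaml

__all__ = [
    "COFACTORS",
    "MEASURED_PRODUCTS",
    "EXCRETED_CARBON_PRODUCTS",
    "REACTION_IDS",
    "CofactorVector",
    "Reaction",
    "AssumptionSet",
    "PathwayModel",
    "build_default_model",
    "glucose_carbon_coefficients",
    "carbon_coefficient",
    "model_to_config",
    "model_from_config",
    "save_model",
    "load_model",
]

#: Cofactor / intermediate ledger entries, in canonical order.
COFACTORS = ("nadh", "nadph", "fd_red", "atp_eq", "co2", "accoa")

#: Products quantified in the fermentation broth (HPLC).
MEASURED_PRODUCTS = ("succinate", "acetate", "formate", "lactate", "ethanol")

#: Excreted products that enter the C-mole balance (formate's C1 is counted
#: implicitly with its acetyl-CoA sibling, see :func:`glucose_carbon_coefficients`).
EXCRETED_CARBON_PRODUCTS = ("succinate", "acetate", "lactate", "ethanol")

#: The six reaction ids a valid model must contain.
REACTION_IDS = ("succinate", "lactate", "acetate", "ethanol", "pfl", "pfor")


@dataclass(frozen=True)
class CofactorVector:
    """Cofactor turnover per unit flux (production positive).

    ``fd_red`` counts reduced ferredoxin in electron-pair equivalents;
    ``co2`` is positive when released, negative when fixed; ``accoa`` tracks
    acetyl-CoA demand satisfied by the flux.
    """

    nadh: float = 0.0
    nadph: float = 0.0
    fd_red: float = 0.0
    atp_eq: float = 0.0
    co2: float = 0.0
    accoa: float = 0.0

    def __post_init__(self) -> None:
        for name in COFACTORS:
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite cofactor entry {name!r}")

    def __add__(self, other: "CofactorVector") -> "CofactorVector":
        return CofactorVector(
            **{c: getattr(self, c) + getattr(other, c) for c in COFACTORS}
        )

    def __mul__(self, k: float) -> "CofactorVector":
        return CofactorVector(**{c: k * getattr(self, c) for c in COFACTORS})

    __rmul__ = __mul__

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in COFACTORS}

    def __iter__(self) -> Iterator[float]:
        return (getattr(self, c) for c in COFACTORS)


@dataclass(frozen=True)
class Reaction:
    """One branch of the PEP node with its per-unit-flux cofactor ledger."""

    id: str
    product: str
    cofactors: CofactorVector
    glucose_carbon: int  # glucose-derived C atoms counted per mol of product

    def __post_init__(self) -> None:
        if self.glucose_carbon not in (0, 3):
            raise ValueError(
                f"glucose_carbon must be 0 or 3, got {self.glucose_carbon}"
            )


@dataclass(frozen=True)
class AssumptionSet:
    """Toggleable cofactor assumptions of the pathway model (see module docs)."""

    fr_ferredoxin_linked: bool = True
    adh_nadph_dependent: bool = True
    atp_per_pep_to_pyruvate: float = 1.0
    malate_shunt_transhydrogenation: float = 0.0

    def __post_init__(self) -> None:
        if self.atp_per_pep_to_pyruvate < 0:
            raise ValueError("atp_per_pep_to_pyruvate must be >= 0")
        if self.malate_shunt_transhydrogenation < 0:
            raise ValueError("malate_shunt_transhydrogenation must be >= 0")


@dataclass(frozen=True)
class PathwayModel:
    """The reaction ledger plus the assumption set it was built under."""

    reactions: Mapping[str, Reaction]
    assumptions: AssumptionSet

    def __post_init__(self) -> None:
        if set(self.reactions) != set(REACTION_IDS):
            raise ValueError(
                f"model must contain exactly the reactions {set(REACTION_IDS)}, "
                f"got {set(self.reactions)}"
            )

    def __getitem__(self, rid: str) -> Reaction:
        return self.reactions[rid]


def build_default_model(assumptions: AssumptionSet | None = None) -> PathwayModel:
    """Build the pathway model for a given :class:`AssumptionSet`.

    Under default assumptions the per-unit-flux vectors are:

    ========= ===== ====== ====== ====== ==== =====
    reaction  nadh  nadph  fd_red atp_eq co2  accoa
    ========= ===== ====== ====== ====== ==== =====
    succinate  -3     0      +1     +1    -1    0
    lactate    -1     0       0     +1     0    0
    acetate     0     0       0     +2     0   +1
    ethanol    -1    -1       0     +1     0   +1
    pfl         0     0       0      0     0    0
    pfor        0     0      +1      0    +1    0
    ========= ===== ====== ====== ====== ==== =====

    Succinate: PEP is carboxylated by PEPCK (one CO2 fixed, one GTP ≡ ATP
    gained), then malate dehydrogenase and the ferredoxin-coupled fumarate
    reduction together oxidize 3 NADH while reducing 1 ferredoxin pair. With
    ``fr_ferredoxin_linked`` off, fumarate reduction draws on NADH directly
    and succinate becomes (nadh -2, fd_red 0) — the total electron pairs
    spent per succinate are unchanged.

    Acetate and ethanol drain acetyl-CoA, which is resupplied by the PFL/PFOR
    bookkeeping fluxes; their atp_eq includes the PEP -> pyruvate credit, and
    acetate additionally the acetate-kinase ATP.
    """
    a = assumptions if assumptions is not None else AssumptionSet()
    app = a.atp_per_pep_to_pyruvate

    if a.fr_ferredoxin_linked:
        succ = CofactorVector(nadh=-3.0, fd_red=1.0, atp_eq=1.0, co2=-1.0)
    else:
        succ = CofactorVector(nadh=-2.0, fd_red=0.0, atp_eq=1.0, co2=-1.0)

    if a.adh_nadph_dependent:
        etoh = CofactorVector(nadh=-1.0, nadph=-1.0, atp_eq=app, accoa=1.0)
    else:
        etoh = CofactorVector(nadh=-2.0, nadph=0.0, atp_eq=app, accoa=1.0)

    reactions = {
        "succinate": Reaction("succinate", "succinate", succ, 3),
        "lactate": Reaction(
            "lactate", "lactate", CofactorVector(nadh=-1.0, atp_eq=app), 3
        ),
        "acetate": Reaction(
            "acetate", "acetate", CofactorVector(atp_eq=app + 1.0, accoa=1.0), 3
        ),
        "ethanol": Reaction("ethanol", "ethanol", etoh, 3),
        "pfl": Reaction("pfl", "pfl", CofactorVector(), 0),
        "pfor": Reaction("pfor", "pfor", CofactorVector(fd_red=1.0, co2=1.0), 0),
    }
    return PathwayModel(reactions=reactions, assumptions=a)


def glucose_carbon_coefficients(model: PathwayModel) -> dict[str, int]:
    """Glucose-derived C atoms counted per mol of each excreted product.

    All four products count 3: for succinate the fourth carbon is fixed CO2,
    not glucose carbon; for acetate and ethanol the coefficient implicitly
    covers the C1 sibling (formate or CO2) split off from pyruvate. Glucose
    itself contributes 6 C-mol per mol.
    """
    return {
        p: model.reactions[p].glucose_carbon for p in EXCRETED_CARBON_PRODUCTS
    }


def carbon_coefficient(model: PathwayModel, product: str) -> int:
    """Look up one product's C-mole coefficient; unknown ids are an error."""
    coeffs = glucose_carbon_coefficients(model)
    if product not in coeffs:
        raise KeyError(
            f"no glucose-carbon coefficient for {product!r}; the balance "
            f"counts only {EXCRETED_CARBON_PRODUCTS} (formate's C1 is folded "
            "into the acetate/ethanol coefficient)"
        )
    return coeffs[product]


# --- serialization -----------------------------------------------------------
#
# Flat config layout:
#   assumptions: {fr_ferredoxin_linked: true, ...}
#   overrides:   {"succinate.nadh": -2.0, ...}   # optional per-reaction tweaks


def model_to_config(model: PathwayModel) -> dict:
    """Dump a model to a plain dict (YAML/JSON friendly)."""
    cfg: dict = {"assumptions": dataclasses.asdict(model.assumptions)}
    default = build_default_model(model.assumptions)
    overrides: dict[str, float] = {}
    for rid in REACTION_IDS:
        for c in COFACTORS:
            v = getattr(model.reactions[rid].cofactors, c)
            if v != getattr(default.reactions[rid].cofactors, c):
                overrides[f"{rid}.{c}"] = v
    if overrides:
        cfg["overrides"] = overrides
    return cfg


def model_from_config(cfg: Mapping) -> PathwayModel:
    """Rebuild a model from :func:`model_to_config` output.

    Unknown assumption keys, reaction ids or cofactor names are errors so a
    typo in a hand-edited config cannot silently fall back to defaults.
    """
    assumptions = AssumptionSet(**dict(cfg.get("assumptions", {})))
    model = build_default_model(assumptions)
    overrides = cfg.get("overrides", {}) or {}
    reactions = dict(model.reactions)
    for key, value in overrides.items():
        rid, _, cof = key.partition(".")
        if rid not in reactions:
            raise KeyError(f"override for unknown reaction {rid!r}")
        if cof not in COFACTORS:
            raise KeyError(f"override for unknown cofactor {cof!r}")
        rxn = reactions[rid]
        reactions[rid] = dataclasses.replace(
            rxn, cofactors=dataclasses.replace(rxn.cofactors, **{cof: float(value)})
        )
    return PathwayModel(reactions=reactions, assumptions=assumptions)


def save_model(model: PathwayModel, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_config(model), sort_keys=True))


def load_model(path: str | Path) -> PathwayModel:
    return model_from_config(yaml.safe_load(Path(path).read_text()))
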