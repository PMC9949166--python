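"""Domain types for constraint-based metabolic models, growth media, and
phenotype/annotation tables, plus readers and writers for the supported formats.

Conventions
-----------
Fluxes are in mmol/gDW/hr; growth rate is the flux of the biomass reaction
(1/hr). An *exchange reaction* moves a single external-compartment metabolite
across the system boundary with stoichiometric coefficient -1, so negative
exchange flux means uptake and positive flux means secretion. A
:class:`Medium` lists the maximum availability of environmental compounds;
applying it sets exchange lower bounds to ``-availability`` (uptake rate equals
the maximum available amount) and closes every exchange the medium does not
mention, unless the exchange is whitelisted (e.g. water, protons, O2 for
aerobic conditions).
"""

from __future__ import annotations

import copy
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Default numerical "infinity" for reaction bounds.
BIG = 1000.0

EXTERNAL_COMPARTMENT = "e"


class ModelFormatError(ValueError):
    """A model file could not be parsed in the named dialect."""


class ModelValidationError(ValueError):
    """A parsed model violates a structural invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelValidationError(f"metabolite {self.id!r}: compartment must be non-empty")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = BIG
    is_exchange: bool = False
    objective_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > upper_bound {self.upper_bound}"
            )

    @property
    def exchange_metabolite(self) -> str:
        """The single metabolite of an exchange reaction."""
        if not self.is_exchange:
            raise ValueError(f"{self.id!r} is not an exchange reaction")
        return next(iter(self.stoichiometry))


@dataclass
class MetabolicModel:
    """A stoichiometric network with bounded reactions and one biomass objective."""

    id: str
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    biomass_reaction_id: str

    def validate(self) -> None:
        if self.biomass_reaction_id not in self.reactions:
            raise ModelValidationError(
                f"model {self.id!r}: biomass reaction {self.biomass_reaction_id!r} not found"
            )
        if self.reactions[self.biomass_reaction_id].objective_coefficient <= 0:
            raise ModelValidationError(
                f"model {self.id!r}: biomass reaction must have objective_coefficient > 0"
            )
        n_exchange = 0
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelValidationError(
                        f"model {self.id!r}: reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )
            if rxn.is_exchange:
                n_exchange += 1
                if len(rxn.stoichiometry) != 1:
                    raise ModelValidationError(
                        f"model {self.id!r}: exchange {rxn.id!r} must reference exactly one metabolite"
                    )
                met_id, coef = next(iter(rxn.stoichiometry.items()))
                if self.metabolites[met_id].compartment != EXTERNAL_COMPARTMENT:
                    raise ModelValidationError(
                        f"model {self.id!r}: exchange {rxn.id!r} metabolite {met_id!r} is not external"
                    )
                if coef != -1:
                    raise ModelValidationError(
                        f"model {self.id!r}: exchange {rxn.id!r} must have coefficient -1"
                    )
        if n_exchange == 0:
            raise ModelValidationError(f"model {self.id!r}: no exchange reactions")

    @property
    def exchange_reactions(self) -> dict[str, Reaction]:
        return {rid: r for rid, r in self.reactions.items() if r.is_exchange}

    def exchange_for(self, metabolite_id: str) -> Reaction | None:
        """The exchange reaction of an external compound, or None."""
        for rxn in self.reactions.values():
            if rxn.is_exchange and rxn.exchange_metabolite == metabolite_id:
                return rxn
        return None

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)


@dataclass
class Medium:
    """Availability of environmental compounds.

    Values are maximum uptake fluxes (mmol/gDW/hr) in the batch modes and
    concentrations (mM) when feeding the spatial simulator.
    """

    availabilities: dict[str, float] = field(default_factory=dict)
    name: str = "medium"

    def __post_init__(self) -> None:
        for cid, val in self.availabilities.items():
            if val < 0:
                raise ValueError(f"medium {self.name!r}: negative availability for {cid!r}")

    def copy(self) -> "Medium":
        return Medium(dict(self.availabilities), self.name)


@dataclass
class CompoundAnnotation:
    """HMDB-style chemical-class labels per metabolite."""

    classes: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, labels in self.classes.items():
            if any(not lab for lab in labels):
                raise ValueError(f"empty class label for compound {cid!r}")

    def all_classes(self) -> set[str]:
        out: set[str] = set()
        for labels in self.classes.values():
            out |= labels
        return out


#: Sentinel returned by biolog_growth_call for compounds absent from the plate.
NOT_ASSAYED = None


@dataclass
class BiologTable:
    """Phenotype-microarray growth table.

    Each row maps a compound to either a pair of optical densities
    ``(od590, od750)`` or a precomputed growth boolean.
    """

    rows: dict[str, tuple[float, float] | bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, val in self.rows.items():
            if isinstance(val, tuple):
                if val[0] < 0 or val[1] < 0:
                    raise ValueError(f"biolog row {cid!r}: negative OD")


def biolog_growth_call(table: BiologTable, compound: str) -> bool | None:
    """Growth call on a phenotype plate: growth iff OD590 - OD750 > 0.1 (strict).

    Returns ``NOT_ASSAYED`` (None) for compounds absent from the table — a
    compound that was never on the plate is not evidence of no growth.
    """
    if compound not in table.rows:
        return NOT_ASSAYED
    val = table.rows[compound]
    if isinstance(val, bool):
        return val
    od590, od750 = val
    return (od590 - od750) > 0.1


# ---------------------------------------------------------------------------
# Medium operations
# ---------------------------------------------------------------------------


def apply_medium(
    model: MetabolicModel,
    medium: Medium,
    keep_default: Iterable[str] = (),
) -> MetabolicModel:
    """Constrain exchange lower bounds from a medium.

    For each exchange reaction whose compound appears in the medium,
    ``lower_bound = -availability``; exchanges for compounds the medium does
    not list are closed to uptake (``lower_bound = 0``) unless their compound
    is in ``keep_default``, in which case the model's own bound is preserved
    (used for water/protons/O2 under aerobic conditions, and for metal ions
    whose inflow should not restrict growth). Upper bounds are never touched.
    Returns a new model; the input is not modified.
    """
    keep = set(keep_default)
    out = model.copy()
    matched: set[str] = set()
    for rxn in out.reactions.values():
        if not rxn.is_exchange:
            continue
        met = rxn.exchange_metabolite
        if met in medium.availabilities:
            rxn.lower_bound = -float(medium.availabilities[met])
            matched.add(met)
        elif met not in keep:
            rxn.lower_bound = 0.0
    unmatched = set(medium.availabilities) - matched
    if unmatched:
        logger.warning(
            "medium %r: %d compound(s) match no exchange reaction of model %r: %s",
            medium.name, len(unmatched), model.id, sorted(unmatched),
        )
    return out


def supplement_medium(medium: Medium, compound: str, amount: float) -> Medium:
    """Increase the availability of one compound by ``amount`` (created if absent)."""
    if amount < 0:
        raise ValueError(f"supplement amount must be >= 0, got {amount}")
    out = medium.copy()
    out.availabilities[compound] = out.availabilities.get(compound, 0.0) + float(amount)
    out.name = f"{medium.name}+{compound}"
    return out


# ---------------------------------------------------------------------------
# Model I/O: internal tabular-JSON dialect
# ---------------------------------------------------------------------------
#
# Schema (documented contract of the repo):
# {
#   "id": "<species name>",
#   "biomass_reaction_id": "<reaction id>",
#   "metabolites": [{"id", "name", "compartment", "formula"}],
#   "reactions": [{"id", "stoichiometry": {met_id: coef}, "lower_bound",
#                  "upper_bound", "is_exchange", "objective_coefficient"}]
# }
# "is_exchange" may be omitted; single-metabolite external reactions with
# coefficient -1 are then auto-detected as exchanges.


def _autodetect_exchanges(model: MetabolicModel) -> None:
    for rxn in model.reactions.values():
        if rxn.is_exchange or len(rxn.stoichiometry) != 1:
            continue
        met_id, coef = next(iter(rxn.stoichiometry.items()))
        met = model.metabolites.get(met_id)
        if met is not None and met.compartment == EXTERNAL_COMPARTMENT and coef == -1:
            rxn.is_exchange = True


def _model_from_dict(data: Mapping, source: str) -> MetabolicModel:
    try:
        mets = {
            m["id"]: Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m["compartment"],
                formula=m.get("formula"),
            )
            for m in data["metabolites"]
        }
        rxns = {
            r["id"]: Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", 0.0)),
                upper_bound=float(r.get("upper_bound", BIG)),
                is_exchange=bool(r.get("is_exchange", False)),
                objective_coefficient=float(r.get("objective_coefficient", 0.0)),
            )
            for r in data["reactions"]
        }
        model = MetabolicModel(
            id=data["id"],
            metabolites=mets,
            reactions=rxns,
            biomass_reaction_id=data["biomass_reaction_id"],
        )
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"{source}: malformed model element: {exc!r}") from exc
    _autodetect_exchanges(model)
    model.validate()
    return model


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "biomass_reaction_id": model.biomass_reaction_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment, "formula": m.formula}
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "is_exchange": r.is_exchange,
                "objective_coefficient": r.objective_coefficient,
            }
            for r in model.reactions.values()
        ],
    }


# ---------------------------------------------------------------------------
# Model I/O: SBML Level 3 + FBC, delegated to cobrapy
# ---------------------------------------------------------------------------


def _from_cobra(cmodel) -> MetabolicModel:
    mets = {
        m.id: Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "c",
                         formula=m.formula)
        for m in cmodel.metabolites
    }
    rxns: dict[str, Reaction] = {}
    biomass_id = None
    for r in cmodel.reactions:
        obj = float(r.objective_coefficient)
        rxns[r.id] = Reaction(
            id=r.id,
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound) if math.isfinite(r.lower_bound) else -BIG,
            upper_bound=float(r.upper_bound) if math.isfinite(r.upper_bound) else BIG,
            is_exchange=False,
            objective_coefficient=obj,
        )
        if obj > 0:
            biomass_id = r.id
    if biomass_id is None:
        raise ModelValidationError(f"SBML model {cmodel.id!r}: no reaction with positive objective")
    model = MetabolicModel(id=cmodel.id or "model", metabolites=mets, reactions=rxns,
                           biomass_reaction_id=biomass_id)
    _autodetect_exchanges(model)
    model.validate()
    return model


def _to_cobra(model: MetabolicModel):
    import cobra

    cmodel = cobra.Model(model.id)
    cmets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment,
                               formula=m.formula)
        for m in model.metabolites.values()
    }
    crxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.add_metabolites({cmets[mid]: coef for mid, coef in r.stoichiometry.items()})
        crxns.append(cr)
    cmodel.add_reactions(crxns)
    cmodel.objective = {
        cmodel.reactions.get_by_id(r.id): r.objective_coefficient
        for r in model.reactions.values()
        if r.objective_coefficient != 0
    }
    return cmodel


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a metabolic model from SBML-FBC or the internal JSON dialect.

    ``format`` is ``"sbml"`` or ``"tabular-json"``; when None it is inferred
    from the file extension (.xml/.sbml vs .json).
    """
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "tabular-json"
    if format == "tabular-json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"{path}: invalid JSON: {exc}") from exc
        return _model_from_dict(data, str(path))
    if format == "sbml":
        import cobra.io

        try:
            cmodel = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # cobra raises several parser exception types
            raise ModelFormatError(f"{path}: SBML parse failure: {exc}") from exc
        return _from_cobra(cmodel)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Write a model as SBML-FBC or internal JSON (inferred from extension)."""
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "tabular-json"
    if format == "tabular-json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1))
    elif format == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(_to_cobra(model), str(path))
    else:
        raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# TSV tables (mandated headers)
# ---------------------------------------------------------------------------


def read_medium_tsv(path: str | Path, name: str | None = None) -> Medium:
    """Medium TSV with columns ``compound_id``, ``availability``."""
    df = pd.read_csv(path, sep="\t")
    return Medium(
        availabilities=dict(zip(df["compound_id"], df["availability"].astype(float))),
        name=name or Path(path).stem,
    )


def write_medium_tsv(medium: Medium, path: str | Path) -> None:
    pd.DataFrame(
        {"compound_id": list(medium.availabilities), "availability": list(medium.availabilities.values())}
    ).to_csv(path, sep="\t", index=False)


def read_biolog_tsv(path: str | Path) -> BiologTable:
    """Biolog TSV with columns ``compound_id``, ``od590``, ``od750``."""
    df = pd.read_csv(path, sep="\t")
    return BiologTable(
        rows={
            row.compound_id: (float(row.od590), float(row.od750))
            for row in df.itertuples()
        }
    )


def write_biolog_tsv(table: BiologTable, path: str | Path) -> None:
    recs = []
    for cid, val in table.rows.items():
        if isinstance(val, bool):
            # encode booleans as saturating/flat OD pairs
            od590, od750 = (1.0, 0.0) if val else (0.0, 0.0)
        else:
            od590, od750 = val
        recs.append({"compound_id": cid, "od590": od590, "od750": od750})
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | Path) -> CompoundAnnotation:
    """Annotation TSV with columns ``compound_id``, ``class`` (one row per label)."""
    df = pd.read_csv(path, sep="\t")
    classes: dict[str, set[str]] = {}
    for cid, lab in zip(df["compound_id"], df["class"]):
        classes.setdefault(cid, set()).add(str(lab))
    return CompoundAnnotation(classes=classes)


def write_annotation_tsv(annotation: CompoundAnnotation, path: str | Path) -> None:
    recs = [
        {"compound_id": cid, "class": lab}
        for cid, labels in annotation.classes.items()
        for lab in sorted(labels)
    ]
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False)


def read_colonization_tsv(path: str | Path) -> pd.DataFrame:
    """Colonization TSV with columns ``condition``, ``compartment``, ``species``, ``proportion``."""
    df = pd.read_csv(path, sep="\t")
    required = {"condition", "compartment", "species", "proportion"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"colonization table missing columns: {sorted(missing)}")
    bad = df[(df["proportion"] < 0) | (df["proportion"] > 1)]
    if len(bad):
        raise ValueError("colonization proportions must be in [0, 1]")
    return df
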