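"""Stoichiometric metabolic model data structures and native JSON I/O.

A :class:`MetabolicModel` is the usual constraint-based triple: a sparse
stoichiometric matrix ``S`` (metabolites x reactions, negative coefficients
for consumption, positive for production), per-reaction flux bounds in
mmol gDW^-1 h^-1, and boolean GPR rules gating each enzymatic reaction.

Metabolite ids carry their compartment as a square-bracket suffix
(``crn[c]``, ``crn[m]``); :attr:`Metabolite.base_id` strips it, which is what
cross-compartment metabolite merging in the biomarker ranking relies on.

Exchange (boundary) reactions are exactly the reactions with a single
nonzero stoichiometric entry, written as consumption of the metabolite
(``{met: -1}``): positive flux is secretion, negative flux is uptake, and
"opening uptake" means lowering the lower bound.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ModelParseError, ModelValidationError
from .gpr import gpr_genes

#: Conventional "unbounded" flux sentinel used when a file omits bounds.
DEFAULT_BOUND = 1000.0

_COMPARTMENT_RE = re.compile(r"^(?P<base>.+)\[(?P<comp>[^\[\]]+)\]$")


def split_compartment(metabolite_id: str) -> tuple[str, str]:
    """Split ``"crn[c]"`` into ``("crn", "c")``; no suffix -> empty compartment."""
    match = _COMPARTMENT_RE.match(metabolite_id)
    if match is None:
        return metabolite_id, ""
    return match.group("base"), match.group("comp")


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""

    @property
    def base_id(self) -> str:
        return split_compartment(self.id)[0]

    @property
    def compartment(self) -> str:
        return split_compartment(self.id)[1]


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    subsystem: str = ""
    name: str = ""

    @property
    def is_exchange(self) -> bool:
        """True iff the reaction has exactly one nonzero stoichiometric entry."""
        return sum(1 for c in self.stoichiometry.values() if c != 0.0) == 1

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    objective_id: str = ""
    name: str = ""

    # -- lookups ---------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, reaction_id: str) -> Reaction:
        for reaction in self.reactions:
            if reaction.id == reaction_id:
                return reaction
        raise KeyError(f"no reaction {reaction_id!r} in model")

    def has_reaction(self, reaction_id: str) -> bool:
        return any(r.id == reaction_id for r in self.reactions)

    # -- matrix view -----------------------------------------------------

    def stoichiometric_matrix(self) -> tuple[np.ndarray, dict[str, int], dict[str, int]]:
        """Dense S (m x n) plus metabolite/reaction id -> index maps."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        rxn_index = {r.id: j for j, r in enumerate(self.reactions)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, reaction in enumerate(self.reactions):
            for met_id, coeff in reaction.stoichiometry.items():
                S[met_index[met_id], j] = coeff
        return S, met_index, rxn_index

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            genes=list(self.genes),
            objective_id=self.objective_id,
            name=self.name,
        )


def validate(model: MetabolicModel) -> None:
    """Raise :class:`ModelValidationError` on any structural invariant breach."""
    met_ids = model.metabolite_ids
    if len(set(met_ids)) != len(met_ids):
        dupes = sorted({i for i in met_ids if met_ids.count(i) > 1})
        raise ModelValidationError(f"duplicate metabolite ids: {dupes}")
    rxn_ids = model.reaction_ids
    if len(set(rxn_ids)) != len(rxn_ids):
        dupes = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
        raise ModelValidationError(f"duplicate reaction ids: {dupes}")
    for met in model.metabolites:
        if not met.base_id:
            raise ModelValidationError(f"metabolite {met.id!r} has empty base id")
    known_mets = set(met_ids)
    known_genes = set(model.genes)
    for reaction in model.reactions:
        if not any(c != 0.0 for c in reaction.stoichiometry.values()):
            raise ModelValidationError(
                f"reaction {reaction.id!r} has no nonzero stoichiometry"
            )
        if not (reaction.lower_bound <= reaction.upper_bound):
            raise ModelValidationError(
                f"reaction {reaction.id!r} has lower_bound > upper_bound"
            )
        for value in (reaction.lower_bound, reaction.upper_bound):
            if math.isnan(value):
                raise ModelValidationError(f"reaction {reaction.id!r} has NaN bound")
        unknown = set(reaction.stoichiometry) - known_mets
        if unknown:
            raise ModelValidationError(
                f"reaction {reaction.id!r} references unknown metabolites: "
                f"{sorted(unknown)}"
            )
        unknown_genes = gpr_genes(reaction.gpr) - known_genes
        if unknown_genes:
            raise ModelValidationError(
                f"reaction {reaction.id!r} GPR references genes not in model: "
                f"{sorted(unknown_genes)}"
            )
    if model.objective_id and not model.has_reaction(model.objective_id):
        raise ModelValidationError(
            f"objective reaction {model.objective_id!r} not in model"
        )


def identify_exchanges(model: MetabolicModel) -> set[str]:
    """Ids of all boundary reactions (single nonzero stoichiometric entry)."""
    return {r.id for r in model.reactions if r.is_exchange}


# -- native JSON dialect -------------------------------------------------
#
# Schema (see docs/native_json_schema.md): top-level keys "name",
# "objective", "genes", "metabolites" (list of {id, name}), "reactions"
# (list of {id, name, stoichiometry, lower_bound, upper_bound, gpr,
# subsystem}).  Bounds default to +/-1000 when absent.  Serialization is
# canonical (sorted keys, fixed indentation) so identical models produce
# bit-identical files.


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "name": model.name,
        "objective": model.objective_id,
        "genes": sorted(model.genes),
        "metabolites": [{"id": m.id, "name": m.name} for m in model.metabolites],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr,
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
    }


def _model_from_dict(data: dict, source: str = "<native-json>") -> MetabolicModel:
    try:
        metabolites = [
            Metabolite(id=entry["id"], name=entry.get("name", ""))
            for entry in data.get("metabolites", [])
        ]
        reactions = [
            Reaction(
                id=entry["id"],
                stoichiometry={k: float(v) for k, v in entry["stoichiometry"].items()},
                lower_bound=float(entry.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(entry.get("upper_bound", DEFAULT_BOUND)),
                gpr=entry.get("gpr", ""),
                subsystem=entry.get("subsystem", ""),
                name=entry.get("name", ""),
            )
            for entry in data.get("reactions", [])
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelParseError(f"{source}: malformed model entry: {exc}") from exc
    genes = data.get("genes")
    if genes is None:
        genes = sorted(set().union(*(gpr_genes(r.gpr) for r in reactions), set()))
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=list(genes),
        objective_id=data.get("objective", ""),
        name=data.get("name", ""),
    )
    validate(model)
    return model


def read_model(path, format: str = "native-json") -> MetabolicModel:
    """Read a model from ``path`` (``native-json`` or ``sbml-subset``)."""
    if format == "native-json":
        try:
            with open(path, encoding="utf-8") as handle:
                data = json.load(handle)
        except json.JSONDecodeError as exc:
            raise ModelParseError(
                f"{path}: invalid JSON at line {exc.lineno}, column {exc.colno}"
            ) from exc
        return _model_from_dict(data, source=str(path))
    if format == "sbml-subset":
        from .sbml import read_sbml_model

        return read_sbml_model(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path, format: str = "native-json") -> None:
    """Write a model; native-json output is canonical (round-trips bit-exact)."""
    if format == "native-json":
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(_model_to_dict(model), handle, indent=2, sort_keys=True)
            handle.write("\n")
        return
    if format == "sbml-subset":
        from .sbml import write_sbml_model

        write_sbml_model(model, path)
        return
    raise ValueError(f"unknown model format {format!r}")


def model_to_json(model: MetabolicModel) -> str:
    """Canonical native-json text for a model (used for checksums/manifests)."""
    return json.dumps(_model_to_dict(model), indent=2, sort_keys=True) + "\n"
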