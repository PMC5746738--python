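"""Metabolic model I/O and validation.

A :class:`MetabolicModel` is the stoichiometric backbone of the analysis:
an ordered list of reactions over compartment-qualified metabolites.  All
downstream matrices (bipartite connectivity, reaction-centric adjacency)
index metabolites and reactions by the order stored here, so ordering is
fixed and reproducible across runs on the same file.

Two on-disk formats are supported: SBML Level 3 (read-only, via libsbml)
and a small canonical JSON dialect (read/write) that makes fixtures exact::

    {"name": ..., "compartments": [...],
     "metabolites": [{"id": "glyc[c]", "base_name": "glyc", "compartment": "c"}],
     "reactions":   [{"id": "R1", "reversible": false,
                      "stoich": {"glyc[c]": -1, "dha[c]": 1}}]}

Stoichiometric coefficients are signed: negative = reactant, positive =
product.  Compartment-qualified identifiers use a bracket suffix
(``glyc[c]``), the common genome-scale-model convention.

Currency metabolites (protons, water, inorganic ions ...) are flagged as
*excluded* rather than deleted: they stay in the model but never form
graph edges.  Energy cofactors (ATP, NAD(P)H, FADH2) are deliberately
*not* on the default exclusion list — cofactor-mediated reaction coupling
is exactly what the downstream modularity analysis is meant to surface.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

_NODE_ID_RE = re.compile(r"^(?P<base>.+?)\[(?P<comp>[^\[\]]+)\]$")


class ModelValidationError(ValueError):
    """Raised when a model file violates referential integrity."""


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed at all."""


@dataclass(frozen=True)
class Metabolite:
    """A compartment-qualified metabolite node.

    ``node_id`` is unique within a model; ``base_name`` is the
    compartment-free measured name used to match mass-spec data.
    """

    node_id: str
    base_name: str
    compartment: str
    excluded: bool = False
    pathway_ids: frozenset[str] = frozenset()


@dataclass(frozen=True)
class Reaction:
    """A reaction with positive stoichiometric maps for each side.

    A metabolite may legitimately appear on both sides (e.g. catalytic
    cycles written explicitly).  ``reversible`` reactions contribute both
    orientations to every graph built downstream.
    """

    reaction_id: str
    reversible: bool
    reactants: Mapping[str, float]
    products: Mapping[str, float]
    ec_number: str | None = None

    @property
    def metabolite_ids(self) -> frozenset[str]:
        return frozenset(self.reactants) | frozenset(self.products)


@dataclass(frozen=True)
class MetabolicModel:
    """An ordered, validated collection of reactions and metabolites."""

    name: str
    reactions: tuple[Reaction, ...]
    metabolites: tuple[Metabolite, ...]

    def __post_init__(self) -> None:
        _validate(self)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def metabolites_by_id(self) -> dict[str, Metabolite]:
        return {m.node_id: m for m in self.metabolites}

    @property
    def reactions_by_id(self) -> dict[str, Reaction]:
        return {r.reaction_id: r for r in self.reactions}

    def excluded_ids(self) -> frozenset[str]:
        return frozenset(m.node_id for m in self.metabolites if m.excluded)

    def base_name_of(self, node_id: str) -> str:
        return self.metabolites_by_id[node_id].base_name


def _validate(model: MetabolicModel) -> None:
    seen_r: set[str] = set()
    for r in model.reactions:
        if r.reaction_id in seen_r:
            raise ModelValidationError(f"duplicate reaction_id {r.reaction_id!r}")
        seen_r.add(r.reaction_id)
        if not r.reactants and not r.products:
            raise ModelValidationError(
                f"reaction {r.reaction_id!r} has no reactants or products"
            )
        for side in (r.reactants, r.products):
            for node_id, coeff in side.items():
                if coeff <= 0:
                    raise ModelValidationError(
                        f"reaction {r.reaction_id!r}: non-positive coefficient "
                        f"for {node_id!r}"
                    )
    seen_m: set[str] = set()
    pairs: set[tuple[str, str]] = set()
    for m in model.metabolites:
        if m.node_id in seen_m:
            raise ModelValidationError(f"duplicate metabolite node_id {m.node_id!r}")
        seen_m.add(m.node_id)
        key = (m.base_name, m.compartment)
        if key in pairs:
            raise ModelValidationError(
                f"(base_name, compartment) pair {key!r} maps to multiple node_ids"
            )
        pairs.add(key)
    for r in model.reactions:
        for node_id in r.metabolite_ids:
            if node_id not in seen_m:
                raise ModelValidationError(
                    f"reaction {r.reaction_id!r} references undeclared "
                    f"metabolite {node_id!r}"
                )


def split_node_id(node_id: str) -> tuple[str, str]:
    """Split ``"glyc[c]"`` into ``("glyc", "c")``.

    Falls back to ``(node_id, "")`` when no bracket suffix is present.
    """
    m = _NODE_ID_RE.match(node_id)
    if m is None:
        return node_id, ""
    return m.group("base"), m.group("comp")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_model(path: str | Path, format: str = "json") -> MetabolicModel:
    """Read a metabolic model from ``path`` in the named format.

    Parameters
    ----------
    path : path to the model file.
    format : ``"json"`` (this package's canonical dialect) or ``"sbml"``
        (SBML Level 2/3, read through libsbml).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "json":
        return _read_json(path)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def _read_json(path: Path) -> MetabolicModel:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"{path}: invalid JSON: {exc}") from exc
    try:
        metabolites = tuple(
            Metabolite(
                node_id=m["id"],
                base_name=m.get("base_name", split_node_id(m["id"])[0]),
                compartment=m.get("compartment", split_node_id(m["id"])[1]),
                excluded=bool(m.get("excluded", False)),
            )
            for m in doc["metabolites"]
        )
        reactions = []
        for r in doc["reactions"]:
            stoich = r["stoich"]
            reactants = {k: -v for k, v in stoich.items() if v < 0}
            products = {k: v for k, v in stoich.items() if v > 0}
            reactions.append(
                Reaction(
                    reaction_id=r["id"],
                    reversible=bool(r.get("reversible", False)),
                    reactants=reactants,
                    products=products,
                    ec_number=r.get("ec_number"),
                )
            )
    except KeyError as exc:
        raise ModelParseError(f"{path}: missing required field {exc}") from exc
    return MetabolicModel(
        name=doc.get("name", path.stem),
        reactions=tuple(reactions),
        metabolites=metabolites,
    )


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() > 0 and doc.getError(0).getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
        raise ModelParseError(f"{path}: {doc.getError(0).getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path}: no model element")

    metabolites = []
    for sp in sbml_model.getListOfSpecies():
        comp = sp.getCompartment() or ""
        sid = sp.getId()
        base = sp.getName() or sid
        metabolites.append(
            Metabolite(node_id=f"{sid}[{comp}]", base_name=base, compartment=comp)
        )
    id_map = {m.node_id.rsplit("[", 1)[0]: m.node_id for m in metabolites}

    reactions = []
    for rx in sbml_model.getListOfReactions():
        reactants = {
            id_map[sr.getSpecies()]: sr.getStoichiometry() or 1.0
            for sr in rx.getListOfReactants()
        }
        products = {
            id_map[sr.getSpecies()]: sr.getStoichiometry() or 1.0
            for sr in rx.getListOfProducts()
        }
        reactions.append(
            Reaction(
                reaction_id=rx.getId(),
                reversible=bool(rx.getReversible()),
                reactants=reactants,
                products=products,
            )
        )
    return MetabolicModel(
        name=sbml_model.getName() or sbml_model.getId() or path.stem,
        reactions=tuple(reactions),
        metabolites=tuple(metabolites),
    )


def write_model_json(model: MetabolicModel, path: str | Path) -> None:
    """Write ``model`` in the canonical JSON dialect (round-trip exact)."""
    doc = {
        "name": model.name,
        "compartments": sorted({m.compartment for m in model.metabolites}),
        "metabolites": [
            {
                "id": m.node_id,
                "base_name": m.base_name,
                "compartment": m.compartment,
                "excluded": m.excluded,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.reaction_id,
                "reversible": r.reversible,
                "stoich": {
                    **{k: -v for k, v in r.reactants.items()},
                    **{
                        k: (v - r.reactants.get(k, 0.0)) if k in r.reactants else v
                        for k, v in r.products.items()
                    },
                },
                **({"ec_number": r.ec_number} if r.ec_number else {}),
            }
            for r in model.reactions
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=False) + "\n")


# ---------------------------------------------------------------------------
# exclusion policy
# ---------------------------------------------------------------------------

def apply_exclusions(
    model: MetabolicModel, exclusion_list: Iterable[str]
) -> MetabolicModel:
    """Flag currency metabolites as excluded; idempotent.

    Entries match either a base name (all compartmental versions flagged)
    or an exact node_id.  Unknown entries are ignored with a warning.
    Returns a new model; the input is untouched.
    """
    entries = set(exclusion_list)
    base_names = {m.base_name for m in model.metabolites}
    node_ids = {m.node_id for m in model.metabolites}
    unknown = entries - base_names - node_ids
    if unknown:
        logger.warning(
            "exclusion entries not present in model %s: %s",
            model.name,
            ", ".join(sorted(unknown)),
        )
    new_mets = tuple(
        replace(m, excluded=True)
        if (m.base_name in entries or m.node_id in entries)
        else m
        for m in model.metabolites
    )
    return MetabolicModel(
        name=model.name, reactions=model.reactions, metabolites=new_mets
    )


def load_exclusion_list(path: str | Path) -> set[str]:
    """Read an exclusion list: one entry per line, ``#`` comments allowed."""
    entries: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            entries.add(line)
    return entries


def default_exclusions() -> set[str]:
    """The bundled default currency/inorganic exclusion list.

    A curated reconstruction of the usual suspects (protons, water,
    phosphate, CO2, O2 and similar inorganics); users analysing a real
    genome-scale model should review and override it.  Energy cofactors
    are intentionally absent.
    """
    with resources.files("mma").joinpath("data/default_exclusions.txt").open() as fh:
        return {
            line.split("#", 1)[0].strip()
            for line in fh
            if line.split("#", 1)[0].strip()
        }


# ---------------------------------------------------------------------------
# compartment map
# ---------------------------------------------------------------------------

@dataclass
class CompartmentMap:
    """Measured base name -> set of model node_ids, plus an unmatched report."""

    mapping: dict[str, set[str]]
    unmatched: list[tuple[str, str]] = field(default_factory=list)

    def __getitem__(self, base_name: str) -> set[str]:
        return self.mapping[base_name]

    def get(self, base_name: str, default: set[str] | None = None) -> set[str] | None:
        return self.mapping.get(base_name, default)

    def __contains__(self, base_name: str) -> bool:
        return base_name in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)


def load_compartment_map(
    path: str | Path, model: MetabolicModel | None = None
) -> CompartmentMap:
    """Load a 2-column TSV (measured_name, node_id) with header.

    Many-to-many: a measured name may map to several compartmental nodes.
    When ``model`` is given, rows whose node_id is not in the model are
    collected in ``unmatched`` (reported, never silently dropped).
    """
    mapping: dict[str, set[str]] = {}
    unmatched: list[tuple[str, str]] = []
    known = set(model.metabolites_by_id) if model is not None else None
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if lineno == 1 or not line.strip():
            continue  # header / blank
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        name, node_id = parts
        if known is not None and node_id not in known:
            unmatched.append((name, node_id))
            continue
        mapping.setdefault(name, set()).add(node_id)
    if unmatched:
        logger.warning(
            "%d compartment-map rows reference node_ids absent from the model",
            len(unmatched),
        )
    return CompartmentMap(mapping=mapping, unmatched=unmatched)


def identity_compartment_map(model: MetabolicModel) -> CompartmentMap:
    """Map every base name in the model to all its compartmental nodes."""
    mapping: dict[str, set[str]] = {}
    for m in model.metabolites:
        mapping.setdefault(m.base_name, set()).add(m.node_id)
    return CompartmentMap(mapping=mapping)
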