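"""Pathway-enrichment comparison, cofactor modules and conservation.

*Pathway enrichment* here is a count comparison, not a statistical test:
a module's unique SSMs (base names — compartments collapsed, because the
same measured species may appear in several compartments) are intersected
with each annotated pathway, and the module is flagged *counter-intuitive*
when no single pathway contains all of them — the interaction the module
captures spans canonical pathways.

*Conservation* asks whether a high-SSM-density module found under one
condition re-appears under another: among the other partition's modules
whose reaction set contains all of the reference module's reactions
(the component root always does), the one deepest in the hierarchy is
selected — ties broken by higher SSM density, then smaller size — and the
module counts as conserved when that match's density exceeds 0.5.

The weighted-vs-unweighted comparison reuses the containment search to
quantify how much of the weighted partition's module structure survives
when all edges are forced to distance 1, and counts baseline modules
built around the shared production and consumption of energy cofactors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from mma.model_io import MetabolicModel, split_node_id
from mma.partition import ModuleNode, ModuleTree

logger = logging.getLogger(__name__)

DEFAULT_COFACTORS = ("atp", "nadh", "nadph", "fadh2")


# ---------------------------------------------------------------------------
# pathway enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    """Pathway coverage of one module's unique SSMs."""

    module_id: int
    n_unique_ssms: int
    max_pathway_count: int
    best_pathways: frozenset[str]
    counter_intuitive: bool


def load_annotation(path: str | Path) -> dict[str, set[str]]:
    """Read a (metabolite_base_name, pathway) TSV with header."""
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise ValueError(f"{path}: expected >= 2 tab-separated columns")
    name_col, pathway_col = table.columns[:2]
    annotation: dict[str, set[str]] = {}
    for name, pathway in zip(table[name_col], table[pathway_col]):
        annotation.setdefault(str(name), set()).add(str(pathway))
    return annotation


def _module_ssm_base_names(
    module: ModuleNode, model: MetabolicModel | None
) -> set[str]:
    if model is not None:
        lookup = model.metabolites_by_id
        return {lookup[n].base_name for n in module.ssm_node_ids}
    return {split_node_id(n)[0] for n in module.ssm_node_ids}


def pathway_enrichment(
    module: ModuleNode,
    annotation: Mapping[str, set[str]],
    model: MetabolicModel | None = None,
) -> EnrichmentResult:
    """Count how well a single annotated pathway covers the module's SSMs.

    The module must be annotated (``ssm_node_ids`` filled by
    ``annotate_tree``).  SSMs without any annotation entry contribute to
    ``n_unique_ssms`` but to no pathway, so an entirely unannotated
    SSM-bearing module is counter-intuitive by definition.
    """
    bases = _module_ssm_base_names(module, model)
    per_pathway: dict[str, int] = {}
    for base in bases:
        for pathway in annotation.get(base, ()):
            per_pathway[pathway] = per_pathway.get(pathway, 0) + 1
    max_count = max(per_pathway.values(), default=0)
    best = frozenset(p for p, c in per_pathway.items() if c == max_count and c > 0)
    return EnrichmentResult(
        module_id=module.module_id,
        n_unique_ssms=len(bases),
        max_pathway_count=max_count,
        best_pathways=best,
        counter_intuitive=max_count < len(bases),
    )


def enrichment_summary(
    tree: ModuleTree,
    annotation: Mapping[str, set[str]],
    model: MetabolicModel | None = None,
) -> pd.DataFrame:
    """Enrichment for every baseline module, as a DataFrame (TSV-ready)."""
    rows = []
    for m in tree.baseline_modules():
        res = pathway_enrichment(m, annotation, model)
        rows.append(
            {
                "module_id": res.module_id,
                "size": m.size,
                "ssm_density": m.ssm_density,
                "n_unique_ssms": res.n_unique_ssms,
                "max_pathway_count": res.max_pathway_count,
                "best_pathways": ";".join(sorted(res.best_pathways)),
                "counter_intuitive": res.counter_intuitive,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "module_id", "size", "ssm_density", "n_unique_ssms",
            "max_pathway_count", "best_pathways", "counter_intuitive",
        ],
    )


def percent_counter_intuitive(summary: pd.DataFrame) -> float:
    """Share (%) of baseline modules flagged counter-intuitive."""
    if len(summary) == 0:
        return 0.0
    return 100.0 * float(summary["counter_intuitive"].mean())


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

@dataclass
class ConservationMatrix:
    """Best containing-module densities of reference modules across partitions."""

    densities: pd.DataFrame  # rows: module_id, cols: partition names
    conserved: pd.DataFrame  # same shape, boolean (> 0.5)
    matches: pd.DataFrame    # matched module_id in each partition

    def to_csv(self, path: str | Path) -> None:
        self.densities.to_csv(path)


def _best_containing(tree: ModuleTree, reactions: frozenset[str]) -> ModuleNode:
    """The deepest module of ``tree`` containing all of ``reactions``.

    Containing modules form a chain along the ancestry, so the deepest is
    unique; ties on depth (impossible on a chain, kept for safety) break
    by higher density then smaller size.
    """
    candidates = [m for m in tree if reactions <= m.reaction_ids]
    if not candidates:
        raise ValueError("no module contains the reference reaction set")
    return max(
        candidates,
        key=lambda m: (
            tree.depth(m.module_id),
            m.ssm_density if m.ssm_density is not None else -1.0,
            -m.size,
        ),
    )


def conservation(
    reference: ModuleTree,
    others: Mapping[str, ModuleTree],
    modules: Sequence[ModuleNode] | None = None,
    threshold: float = 0.5,
) -> ConservationMatrix:
    """Conservation of reference baseline modules across other partitions.

    ``others`` maps a condition name to its annotated ModuleTree; all
    partitions must cover the same reaction universe.  Rows default to
    the reference partition's baseline modules.
    """
    if modules is None:
        modules = reference.baseline_modules()
    universe = reference.reaction_universe()
    for name, tree in others.items():
        missing = universe - tree.reaction_universe()
        extra = tree.reaction_universe() - universe
        if missing or extra:
            raise ValueError(
                f"partition {name!r} covers a different reaction universe "
                f"(missing {sorted(missing)[:5]}, extra {sorted(extra)[:5]})"
            )
    index = [m.module_id for m in modules]
    dens = pd.DataFrame(index=index, columns=list(others), dtype=float)
    match = pd.DataFrame(index=index, columns=list(others), dtype="Int64")
    for m in modules:
        for name, tree in others.items():
            best = _best_containing(tree, m.reaction_ids)
            d = best.ssm_density if best.ssm_density is not None else 0.0
            dens.loc[m.module_id, name] = d
            match.loc[m.module_id, name] = best.module_id
    return ConservationMatrix(
        densities=dens, conserved=dens > threshold, matches=match
    )


# ---------------------------------------------------------------------------
# weighted vs unweighted comparison, cofactor modules
# ---------------------------------------------------------------------------

def _produces_consumes(model: MetabolicModel, base_name: str):
    """Reaction-id sets that produce / consume any compartmental version
    of ``base_name`` (reversible reactions count as both)."""
    nodes = {m.node_id for m in model.metabolites if m.base_name == base_name}
    producers: set[str] = set()
    consumers: set[str] = set()
    for r in model.reactions:
        has_prod = bool(nodes & set(r.products))
        has_reac = bool(nodes & set(r.reactants))
        if has_prod or (r.reversible and has_reac):
            producers.add(r.reaction_id)
        if has_reac or (r.reversible and has_prod):
            consumers.add(r.reaction_id)
    return producers, consumers


def count_cofactor_modules(
    tree: ModuleTree,
    model: MetabolicModel,
    cofactors: Iterable[str] = DEFAULT_COFACTORS,
) -> dict[str, int]:
    """Baseline modules whose reactions collectively both produce and
    consume each cofactor (any compartment — compartments pooled)."""
    counts: dict[str, int] = {}
    for cof in cofactors:
        producers, consumers = _produces_consumes(model, cof)
        counts[cof] = sum(
            1
            for m in tree.baseline_modules()
            if (m.reaction_ids & producers) and (m.reaction_ids & consumers)
        )
    return counts


@dataclass
class WeightComparison:
    """Weighted-partition modules traced into the unweighted partition."""

    densities: pd.DataFrame           # per weighted baseline module: best unweighted density
    n_baseline_weighted: int
    n_corresponding_unweighted: int   # unweighted match also satisfies baseline criteria
    cofactor_counts_weighted: dict[str, int] = field(default_factory=dict)
    cofactor_counts_unweighted: dict[str, int] = field(default_factory=dict)


def weighted_vs_unweighted_comparison(
    weighted_tree: ModuleTree,
    unweighted_tree: ModuleTree,
    model: MetabolicModel,
    cofactors: Iterable[str] = DEFAULT_COFACTORS,
) -> WeightComparison:
    """Trace each weighted baseline module into the unweighted partition.

    For each weighted baseline module, the best (deepest) unweighted
    module containing all its reactions is found; the module *corresponds*
    when that match itself satisfies the baseline criteria.  Cofactor
    module counts are reported for both partitions.
    """
    cons = conservation(
        weighted_tree, {"unweighted": unweighted_tree}
    )
    base = weighted_tree.baseline_modules()
    n_corr = 0
    for m in base:
        mid = cons.matches.loc[m.module_id, "unweighted"]
        matched = unweighted_tree[int(mid)]
        if matched.baseline:
            n_corr += 1
    return WeightComparison(
        densities=cons.densities,
        n_baseline_weighted=len(base),
        n_corresponding_unweighted=n_corr,
        cofactor_counts_weighted=count_cofactor_modules(weighted_tree, model, cofactors),
        cofactor_counts_unweighted=count_cofactor_modules(unweighted_tree, model, cofactors),
    )
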