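"""Bipartite and reaction-centric graph construction.

The bipartite graph is the directed reaction/metabolite connectivity:
reaction -> metabolite for products, metabolite -> reaction for reactants,
both orientations for reversible reactions.  Excluded (currency)
metabolites are isolated — they carry no edges.

The reaction-centric graph collapses metabolites into shared resources:
reactions ``Ri`` and ``Rj`` are adjacent iff some non-excluded metabolite
produced by one is consumed by the other.  Each reaction carries a
*reaction score* RS — the number of distinct SSM nodes it produces or
consumes — and in the weighted graph the edge distance is::

    RG(i, j) = 1 / (RS_i + RS_j)        if RS_i + RS_j > 0
    RG(i, j) = 1.0                      otherwise

so reaction pairs dense in significant metabolites sit close together.
Pairs with no SSM involvement get distance 1.0, the supremum of the
weighted formula over scored pairs, keeping them reachable but maximally
far.  Self-loops are never created.

The O(N^2) pair scan decomposes into independent index-range chunks whose
union is bit-identical to the serial scan (see :func:`pair_chunks`), so
large models can be processed in parallel by any external scheduler.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

from mma.model_io import MetabolicModel


def build_bipartite(model: MetabolicModel) -> nx.DiGraph:
    """Directed bipartite graph over reaction and metabolite nodes.

    Node attribute ``kind`` is ``"reaction"`` or ``"metabolite"``.
    Excluded metabolites are present but isolated.
    """
    g = nx.DiGraph(name=model.name)
    excluded = model.excluded_ids()
    for m in model.metabolites:
        g.add_node(m.node_id, kind="metabolite", excluded=m.excluded)
    for r in model.reactions:
        g.add_node(r.reaction_id, kind="reaction")
        for met in r.reactants:
            if met in excluded:
                continue
            g.add_edge(met, r.reaction_id)
            if r.reversible:
                g.add_edge(r.reaction_id, met)
        for met in r.products:
            if met in excluded:
                continue
            g.add_edge(r.reaction_id, met)
            if r.reversible:
                g.add_edge(met, r.reaction_id)
    return g


def reaction_scores(
    model: MetabolicModel, ssm_nodes: Iterable[str]
) -> np.ndarray:
    """RS vector: per reaction, the count of distinct SSM nodes it touches.

    Counting is by set membership — a metabolite appearing as both
    reactant and product, or with stoichiometry > 1, still counts once.
    Excluded metabolites never count (they are flagged before expansion,
    and are removed here defensively as well).
    """
    ssm = set(ssm_nodes) - model.excluded_ids()
    unknown = ssm - set(model.metabolites_by_id)
    if unknown:
        raise ValueError(f"ssm_nodes not in model: {sorted(unknown)}")
    return np.array(
        [len(r.metabolite_ids & ssm) for r in model.reactions], dtype=int
    )


def reaction_ssm_map(
    model: MetabolicModel, ssm_nodes: Iterable[str]
) -> dict[str, frozenset[str]]:
    """Per reaction_id, the set of SSM nodes it produces or consumes."""
    ssm = set(ssm_nodes) - model.excluded_ids()
    return {
        r.reaction_id: frozenset(r.metabolite_ids & ssm) for r in model.reactions
    }


def n_pairs(n: int) -> int:
    """Number of unordered node pairs, n(n-1)/2 — the pair-scan workload."""
    return n * (n - 1) // 2


def pair_chunks(n: int, chunk_size: int) -> Iterator[tuple[int, int]]:
    """Partition the linearised pair index range [0, n_pairs) into chunks.

    Chunks are disjoint, ordered, and cover the range exactly; evaluating
    them in any order reproduces the serial scan bit-for-bit.
    """
    total = n_pairs(n)
    for start in range(0, total, chunk_size):
        yield start, min(start + chunk_size, total)


def _pair_from_linear(k: int, n: int) -> tuple[int, int]:
    # row-major upper triangle: k -> (i, j), i < j
    i = int(n - 2 - np.floor(np.sqrt(-8 * k + 4 * n * (n - 1) - 7) / 2.0 - 0.5))
    j = int(k + i + 1 - n * (n - 1) // 2 + (n - i) * ((n - i) - 1) // 2)
    return i, j


def _production_consumption(model: MetabolicModel):
    """Per reaction: (produced, consumed) non-excluded metabolite sets,
    reversibility folded in (a reversible reaction produces and consumes
    everything on both sides)."""
    excluded = model.excluded_ids()
    produced, consumed = [], []
    for r in model.reactions:
        prods = set(r.products) - excluded
        reacts = set(r.reactants) - excluded
        if r.reversible:
            both = prods | reacts
            produced.append(both)
            consumed.append(both)
        else:
            produced.append(prods)
            consumed.append(reacts)
    return produced, consumed


def reaction_graph_chunk(
    model: MetabolicModel,
    rs: Sequence[int],
    weighted: bool,
    chunk: tuple[int, int],
) -> list[tuple[int, int, float]]:
    """Evaluate one linear-index chunk of the pair scan.

    Returns ``(i, j, weight)`` triples for pairs that share a produced ->
    consumed metabolite in either orientation.  Order-independent and
    deterministic: the concatenation over any chunking equals the serial
    scan.
    """
    produced, consumed = _production_consumption(model)
    n = model.n_reactions
    out: list[tuple[int, int, float]] = []
    start, stop = chunk
    for k in range(start, stop):
        i, j = _pair_from_linear(k, n)
        if (produced[i] & consumed[j]) or (produced[j] & consumed[i]):
            if weighted:
                s = rs[i] + rs[j]
                w = 1.0 / s if s > 0 else 1.0
            else:
                w = 1.0
            out.append((i, j, w))
    return out


def build_reaction_graph(
    model: MetabolicModel,
    rs: Sequence[int] | None = None,
    weighted: bool = True,
    chunk_size: int | None = None,
) -> nx.Graph:
    """Undirected, symmetric reaction-centric graph with edge distances.

    Parameters
    ----------
    model : validated model with exclusions applied.
    rs : reaction-score vector aligned to ``model.reactions``; defaults to
        all zeros (every edge then gets distance 1.0).
    weighted : apply the reciprocal-score distance; if False all edges are 1.0.
    chunk_size : optional chunk length for the pair scan (result identical
        for any value; exposed for the decomposability contract).

    The edge *set* is independent of ``weighted`` and of ``rs``: only the
    distances differ.
    """
    n = model.n_reactions
    if rs is None:
        rs = np.zeros(n, dtype=int)
    rs = np.asarray(rs)
    if len(rs) != n:
        raise ValueError("rs length must equal the number of reactions")

    if chunk_size is None:
        # serial fast path: same arithmetic, plain double loop
        produced, consumed = _production_consumption(model)
        triples = []
        for i in range(n):
            pi, ci = produced[i], consumed[i]
            for j in range(i + 1, n):
                if (pi & consumed[j]) or (produced[j] & ci):
                    if weighted:
                        s = rs[i] + rs[j]
                        w = 1.0 / s if s > 0 else 1.0
                    else:
                        w = 1.0
                    triples.append((i, j, w))
    else:
        triples = []
        for chunk in pair_chunks(n, chunk_size):
            triples.extend(reaction_graph_chunk(model, rs, weighted, chunk))

    g = nx.Graph(name=model.name, weighted=weighted)
    ids = [r.reaction_id for r in model.reactions]
    for idx, r in enumerate(model.reactions):
        g.add_node(r.reaction_id, rs=int(rs[idx]))
    for i, j, w in triples:
        g.add_edge(ids[i], ids[j], weight=w)
    return g


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def write_sif(g: nx.Graph, path, relation: str = "rr") -> None:
    """Simple interaction format: ``source<TAB>relation<TAB>target``."""
    with open(path, "w") as fh:
        for u, v in sorted(g.edges()):
            fh.write(f"{u}\t{relation}\t{v}\n")
        for node in sorted(n for n in g.nodes() if g.degree(n) == 0):
            fh.write(f"{node}\n")


def write_edge_list(g: nx.Graph, path) -> None:
    """3-column weighted edge list TSV with header."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('weight', 1.0):.10g}\n")
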