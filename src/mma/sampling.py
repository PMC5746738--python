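"""Random connected-subgraph null model.

Significance of a module's SSM content is judged against random connected
subgraphs of the same size drawn from the reaction-centric graph.  The
growth procedure: seed at a uniform random reaction node, absorb one
random neighbour, then repeatedly pick a uniform random node already in
the subnetwork and a uniform random edge incident to it in a *working
copy* of the graph — if the far node is new it is absorbed, otherwise
that edge is deleted from the working copy — until the subnetwork reaches
the requested size.  Edge deletion only ever touches the per-sample
working copy, so the source graph is unchanged and samples are i.i.d.

This is the growth process as such, not a uniform sampler over connected
subgraphs: high-degree regions are over-represented.  All empirical
probabilities derived from it are therefore relative to this process.

Empirical tail probabilities use the (r + 1) / (n + 1) convention so that
finite sampling never reports an exact zero.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from mma.graph_build import reaction_ssm_map
from mma.model_io import MetabolicModel
from mma.partition import ModuleNode


@dataclass(frozen=True)
class SubgraphSample:
    """One sampled connected reaction set with its SSM content."""

    reaction_ids: frozenset[str]
    ssm_count: int

    @property
    def size(self) -> int:
        return len(self.reaction_ids)

    @property
    def ssm_density(self) -> float:
        return self.ssm_count / self.size


@dataclass
class NullDistribution:
    """SSM counts over repeated random connected subgraphs of one size."""

    size: int
    ssm_counts: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.ssm_counts)

    @property
    def mean(self) -> float:
        return float(np.mean(self.ssm_counts))

    @property
    def sd(self) -> float:
        return float(np.std(self.ssm_counts, ddof=1)) if self.n_samples > 1 else 0.0

    def to_tsv(self, path: str | Path, seed: int | None = None,
               graph_hash: str | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("size\tsample_index\tssm_count\n")
            for idx, c in enumerate(self.ssm_counts):
                fh.write(f"{self.size}\t{idx}\t{int(c)}\n")
        sidecar = {
            "size": self.size,
            "n_samples": self.n_samples,
            "seed": seed,
            "graph_hash": graph_hash,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1) + "\n")


def graph_hash(rg: nx.Graph) -> str:
    """Stable content hash of the node/edge/weight structure."""
    h = hashlib.sha256()
    for node in sorted(rg.nodes()):
        h.update(str(node).encode())
    for u, v, data in sorted(rg.edges(data=True)):
        h.update(f"{u}|{v}|{data.get('weight', 1.0):.12g}".encode())
    return h.hexdigest()[:16]


def random_connected_subgraph(
    rg: nx.Graph,
    size: int,
    rng: np.random.Generator,
    ssm_map: dict[str, frozenset[str]] | None = None,
    _adj: dict[str, list[str]] | None = None,
    _component_sizes: dict[str, int] | None = None,
) -> SubgraphSample:
    """Draw one connected subgraph of exactly ``size`` reaction nodes.

    ``ssm_map`` (reaction -> SSM node set) fills in the sample's SSM
    count; without it the count is 0.  The private ``_adj`` /
    ``_component_sizes`` parameters let bulk callers amortise the
    adjacency extraction; results are identical.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    adj = _adj if _adj is not None else {n: sorted(rg.neighbors(n)) for n in sorted(rg.nodes())}
    nodes = sorted(adj)
    if _component_sizes is None:
        _component_sizes = {}
        for comp in nx.connected_components(rg):
            for n in comp:
                _component_sizes[n] = len(comp)
    if max(_component_sizes.values(), default=0) < size:
        raise ValueError(f"no connected component has >= {size} nodes")

    while True:
        seed = nodes[rng.integers(len(nodes))]
        if _component_sizes[seed] < size:
            continue
        members = _grow(adj, seed, size, rng)
        if members is not None:
            break

    if ssm_map is None:
        count = 0
    else:
        touched: set[str] = set()
        for rid in members:
            touched.update(ssm_map.get(rid, ()))
        count = len(touched)
    return SubgraphSample(reaction_ids=frozenset(members), ssm_count=count)


def _grow(
    adj: dict[str, list[str]], seed: str, size: int, rng: np.random.Generator
) -> list[str] | None:
    """One attempt of the growth loop on a lazily-copied working adjacency.

    Returns the member list, or None if the attempt dead-ends (caller
    restarts from a fresh seed and a fresh working copy).
    """
    members = [seed]
    member_set = {seed}
    if size == 1:
        return members

    copied: dict[str, list[str]] = {}

    def edges_of(u: str) -> list[str]:
        if u not in copied:
            copied[u] = list(adj[u])
        return copied[u]

    # first step: one random edge from the seed
    seed_edges = edges_of(seed)
    if not seed_edges:
        return None
    first = seed_edges[rng.integers(len(seed_edges))]
    members.append(first)
    member_set.add(first)

    while len(members) < size:
        # dead end: no member has any incident edge left in the copy
        if all(not edges_of(u) for u in members):
            return None
        u = members[rng.integers(len(members))]
        eu = edges_of(u)
        if not eu:
            continue
        v = eu[rng.integers(len(eu))]
        if v in member_set:
            # remove the edge u-v from the working copy (both directions)
            eu.remove(v)
            ev = edges_of(v)
            if u in ev:
                ev.remove(u)
        else:
            members.append(v)
            member_set.add(v)
    return members


def draw_samples(
    rg: nx.Graph,
    size: int,
    n_samples: int,
    rng: np.random.Generator,
    ssm_map: dict[str, frozenset[str]] | None = None,
) -> list[SubgraphSample]:
    """Draw ``n_samples`` i.i.d. connected subgraphs of one size."""
    adj = {n: sorted(rg.neighbors(n)) for n in sorted(rg.nodes())}
    comp_sizes: dict[str, int] = {}
    for comp in nx.connected_components(rg):
        for n in comp:
            comp_sizes[n] = len(comp)
    return [
        random_connected_subgraph(
            rg, size, rng, ssm_map=ssm_map, _adj=adj, _component_sizes=comp_sizes
        )
        for _ in range(n_samples)
    ]


def ssm_frequency_distribution(
    rg: nx.Graph,
    model: MetabolicModel,
    ssm_nodes: Iterable[str],
    size: int,
    n_samples: int,
    rng: np.random.Generator,
) -> NullDistribution:
    """SSM-count distribution over random connected subgraphs.

    Counting matches the module annotation rule: distinct SSM model nodes
    touched by the sampled reactions.
    """
    ssm_map = reaction_ssm_map(model, ssm_nodes)
    samples = draw_samples(rg, size, n_samples, rng, ssm_map=ssm_map)
    return NullDistribution(
        size=size, ssm_counts=np.array([s.ssm_count for s in samples], dtype=int)
    )


def baseline_fraction_by_size(
    rg: nx.Graph,
    model: MetabolicModel,
    ssm_nodes: Iterable[str],
    sizes: Sequence[int],
    n_samples: int,
    rng: np.random.Generator,
    n_repeats: int = 10,
) -> dict[int, tuple[float, float]]:
    """Per size: (mean, sd) over repeat batches of the fraction of random
    connected subgraphs whose SSM density exceeds 0.5.

    Each of the ``n_repeats`` batches draws ``n_samples`` subgraphs; the
    sd quantifies batch-to-batch sampling noise.
    """
    ssm_map = reaction_ssm_map(model, ssm_nodes)
    out: dict[int, tuple[float, float]] = {}
    for size in sizes:
        fracs = []
        for _ in range(n_repeats):
            samples = draw_samples(rg, size, n_samples, rng, ssm_map=ssm_map)
            fracs.append(float(np.mean([s.ssm_density > 0.5 for s in samples])))
        out[size] = (float(np.mean(fracs)), float(np.std(fracs, ddof=1)) if n_repeats > 1 else 0.0)
    return out


def module_probability(module: ModuleNode, null: NullDistribution) -> float:
    """Empirical chance a random connected subgraph of the module's size
    has at least as many SSMs as the module: (r + 1) / (n + 1), capped at 1.
    """
    if module.ssm_count is None:
        raise ValueError("module is not annotated (ssm_count missing)")
    if null.size != module.size:
        raise ValueError(
            f"null distribution size {null.size} != module size {module.size}"
        )
    r = int((null.ssm_counts >= module.ssm_count).sum())
    return min(1.0, (r + 1) / (null.n_samples + 1))


def attach_probabilities(
    tree,
    rg: nx.Graph,
    model: MetabolicModel,
    ssm_nodes: Iterable[str],
    n_samples: int,
    rng: np.random.Generator,
    max_size: int | None = None,
) -> None:
    """Fill ``probability`` for every annotated module whose size has a
    feasible null (optionally only up to ``max_size`` reactions)."""
    sizes = sorted(
        {
            m.size
            for m in tree
            if (max_size is None or m.size <= max_size)
        }
    )
    comp_max = max((len(c) for c in nx.connected_components(rg)), default=0)
    nulls: dict[int, NullDistribution] = {}
    for size in sizes:
        if size > comp_max:
            continue
        nulls[size] = ssm_frequency_distribution(
            rg, model, ssm_nodes, size, n_samples, rng
        )
    for m in tree:
        if m.size in nulls:
            m.probability = module_probability(m, nulls[m.size])
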