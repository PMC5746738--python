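"""Hierarchical partitioning of the reaction-centric graph.

The pipeline per connected component is:

1. ``D`` — all-pairs shortest-path distances under the edge weights
   (Dijkstra; weights are non-negative by construction).
2. ``B`` — a rank-transformed similarity matrix in [-1, 1]: for each pair
   (i, j) the distance D(i, j) is ranked (midranks for ties) within the
   pooled vector of all distances either node is involved in, and the
   rank is mapped linearly so the shortest distance maps to +1 and the
   longest to -1.
3. Newman's leading-eigenvector bipartition: the sign pattern of the
   dominant eigenvector of ``B`` proposes a two-way split, scored by

       Q = sum_ij B_ij s_i s_j ,   s_i in {-1, +1}.

   The split is accepted only when Q > 0 (up to a 1e-12 floating guard)
   and both sides are non-empty.
4. Each side is broken into its connected components; every component
   becomes a child module and is recursively re-partitioned on its own
   restricted D and B.

Every module ever instantiated — root components, intermediate splits,
terminal leaves — appears in the resulting :class:`ModuleTree`.  Q here
is the literal unnormalised double sum; only its sign drives termination,
so any positive rescaling would yield the identical partition.

Determinism: components and nodes are processed in sorted order, and the
eigenvector sign is fixed by orienting its first non-zero entry positive,
so identical inputs give identical trees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import dijkstra

from mma.model_io import MetabolicModel

Q_TOL = 1e-12


# ---------------------------------------------------------------------------
# distance matrix
# ---------------------------------------------------------------------------

def shortest_path_distances(
    rg: nx.Graph, component: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """All-pairs shortest-path distance matrix over one connected component.

    Returns ``(D, nodes)`` where ``nodes`` is the sorted node order the
    matrix rows follow.  Raises if the induced subgraph is disconnected
    (components must be split before calling).
    """
    nodes = sorted(rg.nodes()) if component is None else sorted(component)
    sub = rg.subgraph(nodes)
    adj = nx.to_scipy_sparse_array(sub, nodelist=nodes, weight="weight", format="csr")
    d = dijkstra(adj, directed=False)
    if np.isinf(d).any():
        raise ValueError(
            "graph is disconnected; split into connected components first"
        )
    return d, nodes


# ---------------------------------------------------------------------------
# B-matrix
# ---------------------------------------------------------------------------

def _b_value_rank(d_ij: float, row_i: np.ndarray, row_j: np.ndarray, L: int) -> float:
    # midrank of d_ij within {row_i} u {row_j} u {d_ij}
    less = int((row_i < d_ij).sum() + (row_j < d_ij).sum())
    equal = int((row_i == d_ij).sum() + (row_j == d_ij).sum()) + 1
    r = less + (equal + 1) / 2.0
    return 1.0 - 2.0 * (r - 1.0) / (L - 1.0)


def _b_value_linear(d_ij: float, row_i: np.ndarray, row_j: np.ndarray) -> float:
    lo = min(row_i.min(initial=d_ij), row_j.min(initial=d_ij))
    hi = max(row_i.max(initial=d_ij), row_j.max(initial=d_ij))
    if hi == lo:
        return 0.0
    return 1.0 - 2.0 * (d_ij - lo) / (hi - lo)


def b_matrix_chunk(
    D: np.ndarray,
    pairs: Sequence[tuple[int, int]],
    convention: Literal["rank", "value"] = "rank",
) -> list[tuple[int, int, float]]:
    """Evaluate B for an arbitrary subset of (i, j) pairs.

    Per-pair computation is independent; any chunked evaluation assembles
    to exactly the serial matrix.
    """
    n = D.shape[0]
    L = 2 * (n - 2) + 1
    out = []

    def other_row(i: int, j: int) -> np.ndarray:
        # D(i, x) for x not in {i, j}
        row = D[i]
        keep = np.ones(n, dtype=bool)
        keep[i] = keep[j] = False
        return row[keep]

    for i, j in pairs:
        d_ij = D[i, j]
        row_i = other_row(i, j)
        row_j = other_row(j, i)
        if convention == "rank":
            if L <= 1:  # two-node component
                b = 1.0
            else:
                b = _b_value_rank(d_ij, row_i, row_j, L)
        else:
            b = _b_value_linear(d_ij, row_i, row_j) if n > 2 else 1.0
        out.append((i, j, b))
    return out


def build_b_matrix(
    D: np.ndarray,
    convention: Literal["rank", "value"] = "rank",
    chunk_size: int | None = None,
) -> np.ndarray:
    """Rank-based similarity matrix B in [-1, 1] from a distance matrix.

    For each pair (i, j) the comparison vector pools D(i, x) and D(j, x)
    for every third node x, plus D(i, j) itself (length L = 2(n-2) + 1);
    the midrank r of D(i, j) in that vector maps linearly to
    ``B = 1 - 2 (r - 1) / (L - 1)``, so rank 1 (shortest) gives +1 and
    rank L (longest) gives -1.  A two-node component gets B = 1.

    ``convention="value"`` switches to the min/max-interpolation reading
    (linear in the distance value rather than its rank).
    """
    n = D.shape[0]
    B = np.zeros((n, n), dtype=float)
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if chunk_size is None:
        chunks: list[Sequence[tuple[int, int]]] = [all_pairs]
    else:
        chunks = [
            all_pairs[k : k + chunk_size] for k in range(0, len(all_pairs), chunk_size)
        ]
    for chunk in chunks:
        for i, j, b in b_matrix_chunk(D, chunk, convention):
            B[i, j] = B[j, i] = b
    return B


# ---------------------------------------------------------------------------
# Newman leading-eigenvector split
# ---------------------------------------------------------------------------

def modularity_q(B: np.ndarray, s: Sequence[int]) -> float:
    """Q = sum_ij B_ij s_i s_j (diagonal contributes 0 since B_ii = 0)."""
    s = np.asarray(s, dtype=float)
    if s.shape[0] != B.shape[0]:
        raise ValueError("sign vector length must match B dimension")
    return float(s @ B @ s)


def leading_eigenvector_split(
    B: np.ndarray,
) -> tuple[np.ndarray, float, bool]:
    """Propose a bipartition from the dominant eigenvector of B.

    Returns ``(s, Q, split_found)``.  The eigenvector is oriented so its
    first entry with magnitude above 1e-12 is positive; entries below
    that magnitude are assigned +1.  ``split_found`` is False when all
    signs agree or Q <= 0 (within the 1e-12 guard).
    """
    n = B.shape[0]
    if n == 1:
        return np.array([1]), 0.0, False
    eigvals, eigvecs = np.linalg.eigh(B)
    v = eigvecs[:, -1]  # eigh returns ascending eigenvalues
    nz = np.flatnonzero(np.abs(v) > 1e-12)
    if nz.size and v[nz[0]] < 0:
        v = -v
    s = np.where(v < -1e-12, -1, 1).astype(int)
    q = modularity_q(B, s)
    split_found = bool((s != s[0]).any() and q > Q_TOL)
    return s, q, split_found


# ---------------------------------------------------------------------------
# module tree
# ---------------------------------------------------------------------------

@dataclass
class ModuleNode:
    """One module in the hierarchy: a set of reactions plus annotations."""

    module_id: int
    reaction_ids: frozenset[str]
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    q_split: float | None = None
    ssm_count: int | None = None
    ssm_density: float | None = None
    ssm_node_ids: frozenset[str] = frozenset()
    height: int | None = None
    probability: float | None = None
    baseline: bool | None = None

    @property
    def size(self) -> int:
        return len(self.reaction_ids)

    @property
    def is_terminal(self) -> bool:
        return not self.children


@dataclass
class ModuleTree:
    """Forest of modules, one root per connected component."""

    nodes: dict[int, ModuleNode] = field(default_factory=dict)
    roots: list[int] = field(default_factory=list)
    _next_id: int = 0

    def add(self, reaction_ids: Sequence[str], parent: int | None) -> int:
        mid = self._next_id
        self._next_id += 1
        self.nodes[mid] = ModuleNode(
            module_id=mid, reaction_ids=frozenset(reaction_ids), parent=parent
        )
        if parent is None:
            self.roots.append(mid)
        else:
            self.nodes[parent].children.append(mid)
        return mid

    def __getitem__(self, module_id: int) -> ModuleNode:
        return self.nodes[module_id]

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self) -> Iterator[ModuleNode]:
        return iter(self.nodes.values())

    def leaves(self) -> list[ModuleNode]:
        return [m for m in self if m.is_terminal]

    def baseline_modules(self) -> list[ModuleNode]:
        return [m for m in self if m.baseline]

    def depth(self, module_id: int) -> int:
        d, m = 0, self.nodes[module_id]
        while m.parent is not None:
            d += 1
            m = self.nodes[m.parent]
        return d

    def reaction_universe(self) -> frozenset[str]:
        return frozenset().union(*(self.nodes[r].reaction_ids for r in self.roots))

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "roots": self.roots,
            "modules": [
                {
                    "module_id": m.module_id,
                    "parent": m.parent,
                    "children": m.children,
                    "reaction_ids": sorted(m.reaction_ids),
                    "q_split": m.q_split,
                    "ssm_count": m.ssm_count,
                    "ssm_density": m.ssm_density,
                    "ssm_node_ids": sorted(m.ssm_node_ids),
                    "height": m.height,
                    "probability": m.probability,
                    "baseline": m.baseline,
                    "size": m.size,
                }
                for m in sorted(self, key=lambda m: m.module_id)
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ModuleTree":
        doc = json.loads(Path(path).read_text())
        tree = cls()
        for rec in doc["modules"]:
            node = ModuleNode(
                module_id=rec["module_id"],
                reaction_ids=frozenset(rec["reaction_ids"]),
                parent=rec["parent"],
                children=list(rec["children"]),
                q_split=rec["q_split"],
                ssm_count=rec["ssm_count"],
                ssm_density=rec["ssm_density"],
                ssm_node_ids=frozenset(rec.get("ssm_node_ids", [])),
                height=rec["height"],
                probability=rec["probability"],
                baseline=rec["baseline"],
            )
            tree.nodes[node.module_id] = node
        tree.roots = list(doc["roots"])
        tree._next_id = max(tree.nodes, default=-1) + 1
        return tree

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "module_id\tparent\tsize\theight\tssm_count\tssm_density\t"
                "q_split\tbaseline\tprobability\treaction_ids\n"
            )
            for m in sorted(self, key=lambda m: m.module_id):
                fh.write(
                    "\t".join(
                        [
                            str(m.module_id),
                            "" if m.parent is None else str(m.parent),
                            str(m.size),
                            "" if m.height is None else str(m.height),
                            "" if m.ssm_count is None else str(m.ssm_count),
                            "" if m.ssm_density is None else f"{m.ssm_density:.6g}",
                            "" if m.q_split is None else f"{m.q_split:.6g}",
                            "" if m.baseline is None else str(m.baseline),
                            "" if m.probability is None else f"{m.probability:.6g}",
                            ";".join(sorted(m.reaction_ids)),
                        ]
                    )
                    + "\n"
                )


def module_subgraph(rg: nx.Graph, module: ModuleNode) -> nx.Graph:
    """Induced reaction-centric subgraph of one module (for export)."""
    return rg.subgraph(sorted(module.reaction_ids)).copy()


# ---------------------------------------------------------------------------
# recursive partition
# ---------------------------------------------------------------------------

def recursive_partition(
    rg: nx.Graph,
    convention: Literal["rank", "value"] = "rank",
) -> ModuleTree:
    """Recursively bipartition each connected component of ``rg``.

    Depth-first: each module's D and B are recomputed restricted to its
    own node set; an accepted split's sides are decomposed into connected
    components, each becoming a child module.  A module that yields no
    positive-Q two-sided split is terminal.
    """
    tree = ModuleTree()
    components = sorted(nx.connected_components(rg), key=lambda c: sorted(c)[0])
    stack: list[int] = []
    for comp in components:
        stack.append(tree.add(sorted(comp), parent=None))

    while stack:
        mid = stack.pop()
        nodes = sorted(tree[mid].reaction_ids)
        if len(nodes) < 2:
            continue
        D, order = shortest_path_distances(rg, nodes)
        B = build_b_matrix(D, convention=convention)
        s, q, found = leading_eigenvector_split(B)
        if not found:
            continue
        tree[mid].q_split = q
        for side in (1, -1):
            side_nodes = [order[k] for k in range(len(order)) if s[k] == side]
            sub = rg.subgraph(side_nodes)
            for comp in sorted(nx.connected_components(sub), key=lambda c: sorted(c)[0]):
                stack.append(tree.add(sorted(comp), parent=mid))
    return tree


def annotate_tree(
    tree: ModuleTree,
    model: MetabolicModel,
    ssm_nodes: Sequence[str] | frozenset[str],
) -> ModuleTree:
    """Annotate every module with SSM count/density, height and the
    baseline-criteria flag (size >= 2 and SSM density > 0.5); in place,
    returned for chaining.

    SSM density counts distinct SSM *model nodes* (compartments are NOT
    collapsed here — pathway enrichment collapses them separately), so a
    density above 1 is possible and meaningful: more significant species
    than reactions in the module.
    """
    from mma.graph_build import reaction_ssm_map

    per_reaction = reaction_ssm_map(model, ssm_nodes)
    for m in tree:
        touched: set[str] = set()
        for rid in m.reaction_ids:
            touched.update(per_reaction.get(rid, ()))
        m.ssm_node_ids = frozenset(touched)
        m.ssm_count = len(touched)
        m.ssm_density = len(touched) / m.size
        m.baseline = m.size >= 2 and m.ssm_density > 0.5

    # heights bottom-up
    def _height(mid: int) -> int:
        node = tree[mid]
        if node.height is not None:
            return node.height
        node.height = (
            0 if not node.children else 1 + max(_height(c) for c in node.children)
        )
        return node.height

    for m in tree:
        m.height = None
    for root in tree.roots:
        _height(root)
    return tree
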