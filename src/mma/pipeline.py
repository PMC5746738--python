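"""End-to-end composition of the analysis stages.

Thin glue used by the command-line interface, the test suite and any
script: model -> SSM calls -> expansion -> reaction scores -> weighted
reaction-centric graph -> hierarchical partition -> annotated tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import networkx as nx
import numpy as np

from mma.graph_build import build_reaction_graph, reaction_scores
from mma.model_io import CompartmentMap, MetabolicModel
from mma.partition import ModuleTree, annotate_tree, recursive_partition
from mma.ssm_stats import MetabolomicsDataset, SSMTable, call_ssms, expand_to_model


@dataclass
class PartitionResult:
    """Everything one partition run produces."""

    rs: np.ndarray
    graph: nx.Graph
    tree: ModuleTree

    def summary(self) -> dict[str, int]:
        """Run-log counts: modules, SSM-bearing modules, baseline modules."""
        return {
            "n_modules": len(self.tree),
            "n_modules_with_ssm": sum(
                1 for m in self.tree if (m.ssm_count or 0) > 0
            ),
            "n_baseline_modules": len(self.tree.baseline_modules()),
        }


def partition_model(
    model: MetabolicModel,
    ssm_nodes: frozenset[str] | set[str],
    weighted: bool = True,
    convention: Literal["rank", "value"] = "rank",
) -> PartitionResult:
    """Score, weight, partition and annotate one model/SSM assignment."""
    rs = reaction_scores(model, ssm_nodes)
    rg = build_reaction_graph(model, rs, weighted=weighted)
    tree = recursive_partition(rg, convention=convention)
    annotate_tree(tree, model, ssm_nodes)
    return PartitionResult(rs=rs, graph=rg, tree=tree)


def ssm_workflow(
    dataset: MetabolomicsDataset,
    model: MetabolicModel,
    compartment_map: CompartmentMap,
    t0: str,
    t1: str,
    alpha: float = 0.05,
    method: Literal["exact", "normal_approx", "auto"] = "auto",
) -> SSMTable:
    """Call SSMs between two timepoints and expand them to model nodes."""
    table = call_ssms(dataset, t0, t1, alpha=alpha, method=method)
    return expand_to_model(table, compartment_map, model)
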