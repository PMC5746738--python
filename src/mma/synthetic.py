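"""Synthetic metabolic models and metabolomics data with planted structure.

Everything downstream of mass-spec peak integration is testable without
any external genome-scale model: these generators emit the same JSON /
CSV / TSV dialects the readers consume, and are pure functions of their
spec and seed.

Two kinds of structure are planted:

* *SSM-dense modules* — disjoint sets of reactions wired through a pool
  of shared metabolites that are shifted between timepoints, so that
  after SSM calling the reactions carry high reaction scores and short
  mutual edge distances.  Recovery of these sets as baseline-criteria
  modules is the headline end-to-end property.
* *A cofactor-coupled pair* — two reactions whose only link is the
  production and consumption of a significantly-changing cofactor
  (modelled on NADPH) that also fans out to many unrelated reactions.
  Distance weighting pulls the pair together; with unit edge distances
  the fan-out branching obscures it — the qualitative contrast the edge
  weighting exists to create.

The replicate noise model is log-normal (peak areas are positive and
multiplicative); shifted metabolites get a constant fold change at the
second timepoint, alternating accumulation and depletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from mma.model_io import (
    MetabolicModel,
    Metabolite,
    Reaction,
    apply_exclusions,
    default_exclusions,
)
from mma.ssm_stats import MetabolomicsDataset


@dataclass(frozen=True)
class PlantedModule:
    """A reaction set sharing a designated pool of shifted metabolites."""

    n_reactions: int = 6
    n_shared_ssms: int = 7


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings; defaults are the package's standard test bed.

    ``n_replicates`` defaults to 5: with log-normal noise at sigma 0.2
    and an 8-fold shift, five replicates put the exact rank-sum test at
    its minimum two-sided p of 2/252, comfortably below alpha = 0.05.
    (Three replicates — a common technical-replicate depth — cannot reach
    p < 0.05 under the exact test at all; see the ssm_stats module.)
    """

    n_reactions: int = 60
    n_metabolites: int = 80
    n_compartments: int = 2
    currency_fraction: float = 0.05
    planted_modules: tuple[PlantedModule, ...] = (PlantedModule(),)
    include_cofactor_pair: bool = True
    sigma: float = 0.2
    effect_size: float = 8.0
    n_replicates: int = 5
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_reactions, self.n_metabolites, self.n_compartments,
               self.n_replicates) < 1:
            raise ValueError("all counts must be positive")
        planted = sum(p.n_reactions for p in self.planted_modules)
        planted += 2 if self.include_cofactor_pair else 0
        if planted > self.n_reactions:
            raise ValueError(
                f"planted reactions ({planted}) exceed n_reactions "
                f"({self.n_reactions})"
            )
        if not 0.0 <= self.currency_fraction < 1.0:
            raise ValueError("currency_fraction must lie in [0, 1)")


@dataclass
class Truth:
    """Ground truth returned alongside generated data."""

    ssm_bases: frozenset[str]
    planted_reactions: list[frozenset[str]] = field(default_factory=list)
    cofactor_pair: frozenset[str] = frozenset()
    cofactor_base: str = ""


# ---------------------------------------------------------------------------
# worked-example fixture
# ---------------------------------------------------------------------------

def toy_model() -> tuple[MetabolicModel, frozenset[str]]:
    """The canonical five-reaction worked example.

    A fixed 5-reaction, 9-metabolite model in which R1 touches exactly
    three SSM nodes and R2 exactly two, sharing one of them (s3, produced
    by R1 and consumed by R2), with three further score-zero reactions
    hanging off R2's product chain.  Under distance weighting the R1-R2
    edge is 1/(3+2) = 0.2.  The wiring beyond those constraints is this
    package's own reconstruction and is frozen here as the canonical
    fixture.
    """
    comp = "c"
    bases = ["a", "b", "c", "d", "e", "s1", "s2", "s3", "s4"]
    metabolites = tuple(
        Metabolite(node_id=f"{b}[{comp}]", base_name=b, compartment=comp)
        for b in bases
    )

    def mid(b: str) -> str:
        return f"{b}[{comp}]"

    reactions = (
        Reaction("R1", False, {mid("s1"): 1, mid("a"): 1}, {mid("s2"): 1, mid("s3"): 1}),
        Reaction("R2", False, {mid("s3"): 1, mid("b"): 1}, {mid("s4"): 1, mid("c"): 1}),
        Reaction("R3", False, {mid("c"): 1}, {mid("d"): 1}),
        Reaction("R4", False, {mid("c"): 1}, {mid("e"): 1}),
        Reaction("R5", False, {mid("d"): 1}, {mid("e"): 1}),
    )
    model = MetabolicModel(name="toy5", reactions=reactions, metabolites=metabolites)
    ssm_nodes = frozenset({mid("s1"), mid("s2"), mid("s3"), mid("s4")})
    return model, ssm_nodes


# ---------------------------------------------------------------------------
# random model
# ---------------------------------------------------------------------------

def _compartment(i: int, n_compartments: int) -> str:
    return f"c{i % n_compartments}"


def random_model(spec: SyntheticSpec) -> MetabolicModel:
    """A random background model: a backbone chain of transformations
    with random side-substrates and optional high-degree currency hubs.

    Deterministic in ``spec.seed``: identical specs give byte-identical
    JSON on disk.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_currency = int(round(spec.currency_fraction * spec.n_metabolites))
    n_pool = spec.n_metabolites - n_currency

    metabolites: list[Metabolite] = []
    pool_ids: list[str] = []
    for i in range(n_pool):
        comp = _compartment(i, spec.n_compartments)
        node = f"m{i:03d}[{comp}]"
        metabolites.append(Metabolite(node, f"m{i:03d}", comp))
        pool_ids.append(node)
    currency_ids: list[str] = []
    for i in range(n_currency):
        node = f"cur{i}[c0]"
        metabolites.append(Metabolite(node, f"cur{i}", "c0"))
        currency_ids.append(node)

    reactions: list[Reaction] = []
    for i in range(spec.n_reactions):
        reactants = {pool_ids[i % n_pool]: 1.0}
        products = {pool_ids[(i + 1) % n_pool]: 1.0}
        # random side metabolites
        for _ in range(int(rng.integers(0, 3))):
            m = pool_ids[int(rng.integers(n_pool))]
            side = reactants if rng.random() < 0.5 else products
            if m not in reactants and m not in products:
                side[m] = 1.0
        # currency hubs attach broadly
        for cur in currency_ids:
            if rng.random() < 0.4:
                side = reactants if rng.random() < 0.5 else products
                side.setdefault(cur, 1.0)
        reactions.append(
            Reaction(
                reaction_id=f"R{i:03d}",
                reversible=bool(rng.random() < 0.2),
                reactants=reactants,
                products=products,
            )
        )
    return MetabolicModel(
        name=f"synthetic-{spec.seed}",
        reactions=tuple(reactions),
        metabolites=tuple(metabolites),
    )


# ---------------------------------------------------------------------------
# planted model + measurements
# ---------------------------------------------------------------------------

def plant_and_measure(
    spec: SyntheticSpec,
) -> tuple[MetabolicModel, MetabolomicsDataset, Truth]:
    """Build a model with planted SSM-dense structure and measure it.

    Returns the model (currency exclusions already applied), a replicate
    peak-area dataset over two timepoints (``0h`` and ``3h``) covering
    every non-currency base name, and the ground truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    ssm_bases: set[str] = set()
    truth = Truth(ssm_bases=frozenset())

    def add_met(base: str, comp: str) -> str:
        node = f"{base}[{comp}]"
        metabolites.append(Metabolite(node, base, comp))
        return node

    # background backbone
    n_planted = sum(p.n_reactions for p in spec.planted_modules)
    n_pair = 2 if spec.include_cofactor_pair else 0
    n_background = spec.n_reactions - n_planted - n_pair
    n_backbone = max(n_background, 1)
    backbone = [add_met(f"b{i:03d}", _compartment(i, spec.n_compartments))
                for i in range(n_backbone)]

    for i in range(n_background):
        reactants = {backbone[i % n_backbone]: 1.0}
        products = {backbone[(i + 1) % n_backbone]: 1.0}
        reactions.append(Reaction(f"BG{i:03d}", False, reactants, products))

    # planted SSM-dense modules
    for j, planted in enumerate(spec.planted_modules):
        shared = [add_met(f"p{j}s{t}", "c0") for t in range(planted.n_shared_ssms)]
        ssm_bases.update(f"p{j}s{t}" for t in range(planted.n_shared_ssms))
        s = len(shared)
        rids = []
        for k in range(planted.n_reactions):
            reactants = {shared[k % s]: 1.0}
            products = {shared[(k + 1) % s]: 1.0}
            if s > 3:
                reactants[shared[(k + 2) % s]] = 1.0
                products[shared[(k + 3) % s]] = 1.0
            if k == 0 and n_background > 0:
                # one anchor into the background chain
                reactants[backbone[j % n_backbone]] = 1.0
            rid = f"P{j}_{k}"
            rids.append(rid)
            reactions.append(Reaction(rid, False, reactants, products))
        truth.planted_reactions.append(frozenset(rids))

    # cofactor-coupled pair: two reactions whose only mutual link is the
    # production/consumption of a significant cofactor, while each member
    # also has distant unit-weight alternatives into the backbone and the
    # cofactor's other compartmental pool fans out across the background.
    if spec.include_cofactor_pair:
        cof = "nadph"
        cof_nodes = [add_met(cof, _compartment(c, spec.n_compartments))
                     for c in range(min(2, spec.n_compartments))]
        fan_node = cof_nodes[-1]
        ssm_bases.add(cof)
        donors = [add_met(f"cofa{t}", "c0") for t in range(2)]
        acceptors = [add_met(f"cofb{t}", "c0") for t in range(2)]
        ssm_bases.update({f"cofa{t}" for t in range(2)})
        ssm_bases.update({f"cofb{t}" for t in range(2)})
        anchors = [backbone[(7 + 12 * t) % n_backbone] for t in range(4)]
        reactions.append(
            Reaction(
                "CFA", False,
                {**{d: 1.0 for d in donors}, anchors[0]: 1.0},
                {cof_nodes[0]: 1.0, anchors[1]: 1.0},
            )
        )
        reactions.append(
            Reaction(
                "CFB", False,
                {cof_nodes[0]: 1.0, anchors[2]: 1.0},
                {**{a: 1.0 for a in acceptors}, anchors[3]: 1.0},
            )
        )
        truth.cofactor_pair = frozenset({"CFA", "CFB"})
        truth.cofactor_base = cof
        # hub fan-out through the other compartmental pool
        if n_background > 0 and fan_node != cof_nodes[0]:
            fan = [i for i in range(n_background) if i % 5 == 2]
            for i in fan:
                old = reactions[i]
                if (i // 5) % 2 == 0:
                    reactants = dict(old.reactants); reactants[fan_node] = 1.0
                    products = dict(old.products)
                else:
                    reactants = dict(old.reactants)
                    products = dict(old.products); products[fan_node] = 1.0
                reactions[i] = Reaction(old.reaction_id, old.reversible,
                                        reactants, products)

    # currency metabolites attach everywhere and are excluded downstream
    n_currency = int(round(spec.currency_fraction * spec.n_metabolites))
    currency_bases = ["h", "h2o", "pi", "co2", "o2"][:n_currency] + [
        f"cur{i}" for i in range(max(0, n_currency - 5))
    ]
    for base in currency_bases:
        node = add_met(base, "c0")
        for i, r in enumerate(reactions):
            if rng.random() < 0.4:
                reactants = dict(r.reactants)
                products = dict(r.products)
                (reactants if rng.random() < 0.5 else products)[node] = 1.0
                reactions[i] = Reaction(r.reaction_id, r.reversible,
                                        reactants, products)

    model = MetabolicModel(
        name=f"planted-{spec.seed}",
        reactions=tuple(reactions),
        metabolites=tuple(metabolites),
    )
    model = apply_exclusions(model, default_exclusions())
    truth.ssm_bases = frozenset(ssm_bases)

    dataset = measure(model, truth.ssm_bases, spec, rng)
    return model, dataset, truth


def measure(
    model: MetabolicModel,
    ssm_bases: Sequence[str] | frozenset[str],
    spec: SyntheticSpec,
    rng: np.random.Generator,
    t0: str = "0h",
    t1: str = "3h",
) -> MetabolomicsDataset:
    """Simulate replicate peak areas for every non-excluded base name.

    Baseline areas are log-normal around 1e6 with sigma ``spec.sigma``;
    metabolites in ``ssm_bases`` get a ``spec.effect_size``-fold shift at
    ``t1``, alternating accumulation and depletion.
    """
    bases = sorted({m.base_name for m in model.metabolites if not m.excluded})
    shifted = set(ssm_bases)
    rows = []
    for b_idx, base in enumerate(bases):
        mu = np.log(1e6)
        for tp in (t0, t1):
            loc = mu
            if tp == t1 and base in shifted:
                fold = spec.effect_size if b_idx % 2 == 0 else 1.0 / spec.effect_size
                loc = mu + np.log(fold)
            areas = rng.lognormal(mean=loc, sigma=spec.sigma, size=spec.n_replicates)
            for rep, area in enumerate(areas, start=1):
                rows.append((base, tp, rep, float(area)))
    return MetabolomicsDataset(
        pd.DataFrame(rows, columns=["base_name", "timepoint", "replicate", "peak_area"])
    )


def write_dataset_csv(dataset: MetabolomicsDataset, path) -> None:
    dataset.table.to_csv(path, index=False)


def write_compartment_map_tsv(model: MetabolicModel, path) -> None:
    """Identity measured-name -> node_id map for a synthetic model."""
    with open(path, "w") as fh:
        fh.write("measured_name\tnode_id\n")
        for m in model.metabolites:
            if not m.excluded:
                fh.write(f"{m.base_name}\t{m.node_id}\n")
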