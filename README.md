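# mma — Metabolomic Modularity Analysis

Tools for partitioning a genome-scale metabolic network into a hierarchy
of **reaction modules enriched in statistically significant metabolites
(SSMs)**, for researchers who have replicate metabolomics data (e.g.
time-course peak areas from tissue biopsies) and a stoichiometric model,
and who want module discovery that is *not* limited to predefined
biochemical pathways — in particular, modules coupled through the shared
production and consumption of energy cofactors (ATP, NAD(P)H, FADH2),
which classical pathway enrichment cannot see.

## Method

1. **SSM calling.** Each measured metabolite's replicate peak areas at
   two timepoints are compared with a two-sided Mann–Whitney U test;
   metabolites with p < α and a median shift are flagged accumulated or
   depleted. Because extraction is not compartment-specific, a call on a
   measured name is expanded to *all* compartmental versions of that
   metabolite in the model.
2. **Reaction-centric graph.** Reactions are nodes; an edge joins
   Ri and Rj when a (non-currency) metabolite produced by one is
   consumed by the other, reversibility respected. Each reaction gets a
   score RSᵢ = number of distinct SSM nodes it produces or consumes, and
   the edge *distance* is

   RG(i,j) = 1 / (RSᵢ + RSⱼ)   (1.0 when both scores are zero),

   so SSM-dense reaction pairs sit close together. Currency metabolites
   (H⁺, H₂O, Pᵢ, …) are excluded from edge formation; energy cofactors
   are deliberately retained.
3. **Hierarchical partition.** Per connected component: all-pairs
   shortest-path distances D → a rank-transformed similarity matrix
   B ∈ [−1,1] (the midrank of D(i,j) among all distances either node is
   involved in, mapped linearly so nearest → +1, farthest → −1) →
   Newman's leading-eigenvector bipartition scored by
   Q = Σᵢⱼ Bᵢⱼ sᵢ sⱼ, sᵢ ∈ {−1,+1}. Splits recurse while Q > 0, each
   side re-decomposed into connected components, giving a module tree.
   Modules with ≥ 2 reactions and SSM density > 0.5 satisfy the
   *baseline module criteria*.
4. **Statistics around the partition.** Random connected-subgraph null
   distributions give each module an empirical probability; a
   pathway-coverage comparison flags *counter-intuitive* modules whose
   SSMs span multiple annotated pathways; a containment search
   quantifies module conservation across conditions and against an
   unweighted (all edges = 1) partition.

## Worked example

```python
from mma.synthetic import SyntheticSpec, plant_and_measure
from mma.model_io import identity_compartment_map
from mma.pipeline import partition_model, ssm_workflow

spec = SyntheticSpec(seed=42)               # planted SSM-dense module + cofactor pair
model, data, truth = plant_and_measure(spec)
table = ssm_workflow(data, model, identity_compartment_map(model),
                     t0="0h", t1="3h", method="exact")
print(f"{table.n_ssm} SSM base names -> {len(table.ssm_nodes)} model nodes")

result = partition_model(model, table.ssm_nodes, weighted=True)
print(result.summary())
for m in sorted(result.tree.baseline_modules(), key=lambda m: -m.ssm_density)[:3]:
    print(f"module {m.module_id}: size={m.size} ssm_density={m.ssm_density:.2f} "
          f"height={m.height} reactions={sorted(m.reaction_ids)[:6]}")
```

prints

```
15 SSM base names -> 16 model nodes
{'n_modules': 60, 'n_modules_with_ssm': 30, 'n_baseline_modules': 13}
module 58: size=3 ssm_density=2.33 height=0 reactions=['P0_1', 'P0_2', 'P0_5']
module 54: size=2 ssm_density=2.00 height=0 reactions=['BG051', 'P0_0']
module 56: size=4 ssm_density=1.75 height=1 reactions=['P0_1', 'P0_2', 'P0_4', 'P0_5']
```

15 of the measured metabolites changed significantly between 0 h and
3 h (the 12 planted ones plus a few exact-test false positives); the
partition produced 60 hierarchical modules of which 13 meet the baseline
criteria, and the densest of them (`P0_*` reactions) are exactly the
planted SSM-sharing module — an SSM density of 2.33 means the three
reactions collectively turn over seven significant species.

The same workflow is available from the shell:

```sh
mma ssm --model model.json --data peaks.csv --compartment-map map.tsv --outdir out/
mma partition --model model.json --ssm-nodes out/ssm_nodes.tsv --outdir out/
mma null --model model.json --sizes 2-10 --n-samples 1000 --seed 1 --outdir out/
mma enrich --model model.json --tree out/modules.json --annotation kegg.tsv --outdir out/
mma conserve --reference out/modules.json --other liver2 out2/modules.json --outdir out/
```

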