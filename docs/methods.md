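# Methods

## Scope and data model

The package analyses a *reaction-centric* view of a compartmentalised
stoichiometric network: reactions are the nodes, metabolites are shared
resources that induce edges. This representation deliberately avoids
assigning high-degree metabolites (energy cofactors above all) to any
single pathway, which is what lets the partition surface modules coupled
purely by cofactor turnover. Flux inference, gene–protein–reaction
rules, thermodynamics and allosteric regulation are out of scope: the
output describes where significant concentration changes cluster on the
network, and deliberately says nothing about the direction of flux
changes.

Models are read from SBML Level 2/3 (via libsbml) or from a canonical
JSON dialect defined by this package (signed stoichiometry, bracketed
compartment suffixes such as `glyc[c]`). The JSON dialect cannot encode
a metabolite appearing on both sides of one reaction — the writer nets
such entries — but the in-memory representation supports it, and
reaction scoring uses set semantics so such species count once.

## SSM calling

Per metabolite, replicate peak areas at two timepoints are compared with
a two-sided Mann–Whitney U test; direction is the sign of the median
shift, and a significant metabolite with equal medians is *not* called
(an SSM must be accumulated or depleted). Two conventions are exposed:

* `exact` — the exact U distribution. With very small groups the
  attainable p-values are coarse: at n = m = 3 the two-sided minimum is
  2/20 = 0.1, so **no** call can pass α = 0.05; at n = m = 5 the
  minimum is 2/252 ≈ 0.0079 and the realised type-I level at α = 0.05
  is 8/252 ≈ 0.032 (the test is conservative).
* `normal_approx` — tie-corrected, continuity-corrected normal
  approximation, the only route to p < 0.05 at three replicates.

The default `auto` uses the exact distribution for groups of ≤ 8
without ties. Raw p-values are compared to α with no multiple-testing
correction by default (Benjamini–Hochberg behind a flag): the workflow
treats SSM calling as a labelling step feeding the network analysis,
not as a final inference. An SSM call on a measured base name is
expanded to all compartmental model nodes mapped to it in a
user-supplied two-column map; unmatched names are reported, never
dropped.

## Graph construction

The directed bipartite graph assigns reaction→metabolite edges for
products and metabolite→reaction edges for reactants, both orientations
for reversible reactions. Metabolites on a currency exclusion list
(default: protons, water, phosphate, dissolved gases and similar
inorganics; user-overridable, energy cofactors intentionally absent)
are flagged and never form edges.

Reactions Ri, Rj are adjacent in the reaction-centric graph when a
non-excluded metabolite produced by one is consumed by the other, with
reversible reactions producing and consuming both sides. The reaction
score RSᵢ counts *distinct* SSM nodes in a reaction's participant set —
stoichiometric multiplicity is chemistry, not evidence. Edge distances
are 1/(RSᵢ+RSⱼ) when the sum is positive. Pairs with both scores zero
get distance 1.0: this is the supremum of the weighted formula over
scored pairs (attained at score sum 1), so unscored pairs are at least
as far apart as any scored pair without becoming unreachable. Self
loops are never created. The O(N²) pair scan is decomposable into
arbitrary index-range chunks whose union is bit-identical to the serial
scan, so genome-scale models can be processed in parallel by any
external scheduler.

## Partitioning

Per connected component: exact Dijkstra all-pairs distances D, then the
similarity matrix B. For each pair (i,j) the comparison vector pools
D(i,x) and D(j,x) over all third nodes x plus D(i,j) itself (length
L = 2(n−2)+1); the midrank r of D(i,j) maps linearly to
B(i,j) = 1 − 2(r−1)/(L−1). *Rank*-linearity was chosen over
value-linear interpolation because ranking is the natural reading of a
distance-order transform and is insensitive to the heavy tail of
shortest-path distances; the value-linear alternative is available via
`convention="value"`. With the pair distance included, a fully tied
vector maps to exactly 0 and a two-node component degenerates to
B = 1, which correctly yields no split.

The split is the sign pattern of the dominant eigenvector of B
(`numpy.linalg.eigh`; eigenvector oriented so its first entry of
magnitude > 1e−12 is positive, near-zero entries assigned +1 — a pure
determinism device), scored by the literal unnormalised
Q = Σᵢⱼ Bᵢⱼsᵢsⱼ. Only the sign of Q matters for termination, so any
positive normalisation would produce the identical tree; the printed
double-sum form is implemented as such. A split is accepted iff both
signs occur and Q > 1e−12 (floating-point zero guard); accepted sides
are re-decomposed into connected components, each becoming a child
module, and recursion proceeds on the component-restricted D and B.
Components and node lists are processed in sorted order throughout, so
identical inputs give identical trees.

Annotation: a module's SSM count is the number of distinct SSM *model
nodes* its reactions touch (compartments NOT collapsed — density above
1 is meaningful), density = count/size, height = longest downward path
to a leaf, and the *baseline module criteria* are size ≥ 2 with density
> 0.5. Pathway coverage analysis, by contrast, collapses compartments
to unique measured species before counting — the two conventions
coexist deliberately and are both documented at their call sites.

## Random connected-subgraph null

The sampler implements the stated growth process verbatim: seed
uniformly, absorb one random neighbour, then repeatedly pick a uniform
member node and a uniform incident edge in a working copy — absorbing
the far node if new, deleting the edge from the working copy otherwise —
until the target size. Edge deletion operates on a per-sample copy of
the adjacency (restoring between samples is the only choice that keeps
samples identically distributed), so the source graph is never mutated.
This process is **not** a uniform sampler over connected subgraphs —
high-degree regions are over-represented — and no such claim is made;
empirical probabilities are defined relative to this process. The
module probability is the (r+1)/(n+1) upper-tail estimate (capped at
1.0) of drawing at least the module's SSM count at the module's size;
the pseudocount avoids zero p-values from finite sampling.

## Enrichment, conservation, weighting comparison

A module is *counter-intuitive* when no single annotated pathway
contains all of its unique SSMs (unannotated SSMs count toward the
total and toward no pathway). Conservation of a module into another
partition takes, among the other partition's modules containing the
full reference reaction set (the component root always qualifies), the
one deepest in the hierarchy — on a containment chain this is unique
and has the highest density — and flags conservation at density > 0.5;
the raw matched density is always reported so sub-threshold structure
remains visible. The weighted-vs-unweighted comparison reuses this
containment search against a unit-distance partition, and counts
*cofactor modules* as baseline modules in which at least one reaction
produces and at least one consumes the cofactor, any compartment,
reversible reactions counting as both; "shared production/consumption"
is not defined more precisely upstream, and this operationalisation is
the weakest reading that still excludes modules that only drain or only
charge a cofactor pool.

## Synthetic data

The generators emulate the *statistical shape* of a two-timepoint
replicate metabolomics experiment on a modest network — they do not
simulate perfusion biochemistry. Defaults, chosen once:

| parameter | default | rationale |
| --- | --- | --- |
| reactions / metabolites | 60 / ~70 | smallest scale at which backbone, planted module, cofactor fan-out and currency hubs coexist |
| replicates per timepoint | 5 | the exact rank-sum test has usable power (min p 2/252); three technical replicates, though common in practice, make exact p < 0.05 unattainable |
| noise | log-normal, σ = 0.2 | peak areas are positive and multiplicative; σ = 0.2 ≈ 20 % CV, a typical well-behaved platform |
| effect size | 8-fold | a strong, clearly detectable shift at the above noise; alternating accumulation/depletion |
| planted module | 6 reactions / 7 shared shifted metabolites | reproduces a density-above-1 module |
| currency fraction | 0.05 | a few ubiquitous excluded species wired to ~40 % of reactions |

The planted cofactor pair couples two reactions solely through a
significantly-shifted cofactor pool (modelled on NADPH, present in two
compartments), gives each member distant unit-weight alternatives into
the backbone, and fans the other compartmental pool across the
background — the configuration in which score-based weighting pulls the
pair into one terminal module while unit distances dissolve it into its
branches. Passing tests on these generators demonstrate correctness of
the mechanics and the qualitative weighting contrast; they do not
demonstrate recovery rates on real genome-scale networks, where SSM
expansion is noisier, exclusion lists matter more, and module sizes are
far larger.

## Numerical and degenerate-case choices

* Q acceptance tolerance 1e−12; eigen-decomposition is dense symmetric
  (`eigh`), deterministic at these sizes, with the sign convention above
  resolving the ±v ambiguity (and eigenvalue ties, by using the solver's
  fixed ordering as-is).
* Singleton modules and two-node components terminate without
  eigen-analysis (B degenerates to +1).
* Metabolites measured at only one timepoint get p = 1 / direction
  `none`; groups with ties fall back to the asymptotic method under
  `auto`.
* Sampler dead-ends (a seed whose component is smaller than the target
  size) restart from a fresh seed and a fresh working copy; component
  sizes are pre-screened so the loop terminates.

## Problem sizes used in the checks

The standard test bed runs the full pipeline on ~60-reaction synthetic
networks (20 seeded replicates for the recovery property), draws 10,000
subgraph samples on a 200-reaction network for the sampler contract,
10,000 null simulations for rank-sum calibration, and checks the
spectral split against exhaustive enumeration on 200 random graphs of
≤ 10 nodes — sizes at which the exhaustive oracles are exact and the
whole suite completes in a few minutes on one core.

## Known limitations

* The B-matrix rank transform discards distance magnitudes; two very
  different geometries can produce the same B.
* The subgraph sampler's non-uniformity biases null distributions
  toward high-degree neighbourhoods (inherent to the stated process).
* Conservation requires exact reaction-universe identity across
  partitions; cross-model comparison would need an identifier mapping
  layer that is not provided.
* The unnormalised Q has no absolute scale; Q values are comparable
  only within one matrix, which is why only its sign is used.
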