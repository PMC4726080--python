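# Methods

This note documents the models and procedures implemented in `cofactornet`,
the parameter defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical/design decisions
made where the design was genuinely open.

## Catalog representation

A cofactor catalog is a set of (protein, cofactor) records. Protein and
gene identifiers are treated as one opaque id space — the upstream curated
resources use them interchangeably — and cofactor names are normalized by
whitespace-trimming plus a case-insensitive alias map ("Mg2+", "magnesium"
→ "Mg"; the non-specific metal requirement is the single token "metal").
The alias map is configuration, not code: name curation is judgment-laden,
so users can supply their own YAML. Duplicate pairs from different source
databases are collapsed to one record with merged source tags and an OR-ed
binding-site-variant flag; the catalog counts *unique* interactions.

## Augmented network

Catalog proteins are matched into a simple undirected PPI graph
(self-loops and duplicate edges in either orientation are removed at read
time). The network analyzed is the PPI subgraph induced on:

* catalog proteins present in the PPI, plus
* non-catalog proteins adjacent to **at least two** catalog proteins.

The ≥ 2 rule keeps only neighbors that bridge catalog-rich regions and
avoids diluting the network with peripheral proteins. Because the node-
induced subgraph is taken over kept nodes only, edges between two rejected
neighbors cannot appear, while kept neighbors may interconnect (`nn`
edges). Catalog proteins absent from the PPI are dropped silently from the
network but surfaced in the assembly report. Edge classes `cc`/`cn`/`nn`
partition the edge set by construction; the report asserts this identity.

One subtlety: a "shared-by-two" count could in principle be taken over
catalog proteins that mapped into the PPI or over the full catalog. In this
implementation proteins are matched by exact identifier, so the two
universes coincide and no switch is exposed.

## Module detection

The detector follows the classic molecular-complex detection scheme:

* **Vertex weight**: `w(v) = k_max · density(H)` where `H` is the highest
  k-core of the subgraph induced by the closed neighborhood `N[v]` and
  density uses the loop-free convention `2m / n(n−1)` (graphs are simple).
  Vertices below the degree cutoff (default 2) get weight 0.
* **Seeded growth**: seeds in descending weight (ties broken by id, so
  output is independent of input row order); a breadth-first expansion
  admits an unassigned neighbor when its weight exceeds
  `w(seed) · (1 − node_score_cutoff)` (default cutoff 0.2), up to
  `max_depth` (default 100) levels. Modules are vertex-disjoint
  (first-claimed wins); the overlapping "fluff" option exists but defaults
  to off.
* **Post-processing**: modules not containing a 2-core are discarded;
  "haircut" (default on) iteratively removes members with fewer than two
  intra-module connections, so singly-connected proteins never remain.

Modules are scored by `density · size` and those with at least
`min_report_size` members are reported. The default is 10 *inclusive*: the
reporting convention ("more than 10") is self-contradicting in practice —
reference module tables list 10-protein modules — and the inclusive bound
is the one consistent with the tables.

Two behaviors of this algorithm are worth knowing. First, in sparse random
graphs triangles give their vertices weight 2.0, and any edge between two
triangle-vertices lets growth chain them into a reported module that
survives the haircut (each triangle is a 2-core); such background modules
have low scores (density·size ≈ 2–3) and are cleanly separable from dense
complexes (score > 8 for a 15-node module at density 0.9). Second, when two
dense modules of similar internal density are connected by even one
background edge, the weight threshold admits the bridge endpoint and the
neighboring module floods in: the detector merges them. This is intrinsic
to the published growth rule, not an implementation choice; consequently
planted-partition recovery degrades with background density (at
p_bg = 0.01 two 15-node modules are bridged with probability
1 − 0.99²²⁵ ≈ 0.9 and recovery Jaccard falls from ≈ 0.8 to ≈ 0.3–0.5).
Module scores, not sizes, remain informative in that regime.

Per-module cofactor over-representation uses the right-tail hypergeometric
test (universe = network proteins, marked = proteins of one cofactor,
drawn = module members) with Benjamini–Hochberg adjustment across all
(module, cofactor) tests. Functional (GO/pathway) enrichment over
user-supplied annotation sets goes through the same generic operation; no
web service is called.

## Permutation tests

All permutation tests are one-sided "greater" — the hypotheses are
directional (are catalog proteins more connected / more co-expressed /
more broadly expressed?) — and use the add-one estimator
`p = (1 + #{null ≥ observed}) / (n_perm + 1)`, which lies in (0, 1] and
never returns 0. Default `n_perm` is 10,000; the test suite uses 2,000 to
keep runtimes short. Every test is reproducible from an explicit seed, and
the pipeline derives per-stage substream seeds from
`seed XOR crc32(stage)` so adding a stage never perturbs another stage's
draws.

* **Hub test**: hubs are the top `round(0.02 · n)` proteins by degree
  (half-up rounding; degree ties at the cutoff broken lexicographically —
  a fractional quota and an integer hub count cannot both be exact, so the
  formula wins and the count is reported). Observed = hub fraction among
  catalog proteins; null draws are size-matched samples from non-catalog
  proteins (`null_universe="all"` switches to all proteins). The hub-count
  statistic is discrete, so its add-one p-value is conservative
  (super-uniform): at α = 0.05 the realized type-I error sits at or below
  α, the appropriate check being an upper bound rather than a two-sided
  band. Type-I calibration in a two-sided band is demonstrated on the
  co-expression statistic, whose null distribution is continuous.
* **Co-expression test**: for a cofactor's protein set (≥ 10 genes after
  intersection with the expression matrix; smaller groups return an
  explicit "excluded" marker), observed = mean Pearson *r* over all
  unordered gene pairs across tissues; null groups are size-matched uniform
  draws from all expressed genes (zero-variance genes, for which *r* is
  undefined, are dropped and logged). *r* is computed on the abundance
  values as provided — no transform by default, an optional log2(x+1) is
  available — since the analysis is scale-invariant per gene.
* **Expressed-in-all test**: observed = fraction of catalog genes
  classified `expressed_in_all`; null draws are size-matched gene sets
  from all classified genes.

## Tissue-specificity classification

Six mutually exclusive categories, evaluated in precedence order
tissue enriched → group enriched → tissue enhanced → expressed in all →
mixed → not detected, with "detected" meaning abundance ≥ detection
threshold (default 1.0 expression unit, the historical FPKM ≥ 1
convention; the source analyses never state one) and fold = 5:

* *tissue enriched*: one tissue ≥ 5× every other tissue;
* *group enriched*: a group of 2–7 tissues each ≥ 5× all tissues outside
  the group;
* *tissue enhanced*: some tissue ≥ 5× the mean over all tissues;
* *expressed in all*: detected everywhere;
* *mixed*: detected somewhere but not everywhere, not elevated;
* *not detected*: detected nowhere.

"Mixed" generalizes the atlas definition ("detected in fewer than 32
tissues") to "detected in ≥ 1 but not all tissues", since the tissue count
is data-dependent. The group-enriched search sorts tissues by descending
abundance and tests only prefixes of size 2–7: any qualifying subset must
consist of the top-k tissues (each member must exceed 5× every non-member,
with fold > 1 no non-member can out-rank a member), so the O(T log T)
greedy prefix scan is equivalent to the exponential exhaustive subset
search — the test suite checks this equivalence against an exhaustive
oracle. The whole classification is invariant under joint rescaling of the
matrix and the detection threshold.

Reported percentages always carry their numerator and denominator: the
category shares use each group's own classified-gene denominator, and the
catalog summary reports interaction-based and protein-based percentages
separately, because several published percentages of this kind have
ambiguous denominators.

## Disease network and nestedness

The disease × cofactor incidence weights each pair by the number of shared
proteins (`|proteins(c) ∩ genes(d)|`); all-zero disease rows are dropped.
Nestedness is computed on the binary support (weights > 0) — NODF is a
binary metric, the weights are retained for reporting — and cofactors
linked to no retained disease are not part of the bipartite network, so
their empty columns are excluded.

* **NODF** (0–100): for every unordered pair of rows and of columns, the
  paired overlap (share of the sparser line's presences found in the
  denser line) contributes when the marginal totals strictly decrease;
  equal fills contribute 0. The mean over all pairs is order-invariant.
* **Per-disease nested rank** (0–1): diseases with **more than**
  `min_genes` (default 5, strict) cofactor-interacting genes are retained;
  rows are packed by descending repertoire size, ties broken by descending
  total overlap with other rows, then by id; the index is the normalized
  rank `(rank − 1)/(n − 1)`. The disease whose repertoire contains every
  other's gets 0 ("interacts with the most diverse cofactors"), the
  narrowest gets 1. Among several per-row nestedness constructs this is
  the one that is per-row, normalized to [0, 1], and assigns the extreme
  value 0 to the most broadly connected disease. With identical
  repertoires the ranking falls back to lexicographic ids — the indices
  are then arbitrary within the tied block and documented as such.

Mendelian-like (OMIM-style) and complex-trait-like (GWAS-style) disease
maps are analyzed separately, never pooled. Per-disease gene enrichment
(are cofactor-interacting proteins over-represented among the disease's
genes?) uses the right-tail hypergeometric test against a user-supplied
gene universe with BH adjustment across diseases.

## Synthetic data generator

`SyntheticSpec` defaults are sized to the curated scale of this kind of
analysis: 49 cofactors, 2,301 catalog proteins, ~1.23 cofactors per protein
(per-protein cofactor count = 1 + Binomial(48, 0.0048)), 3,500 additional
non-catalog interactome proteins (catalog proteins are a minority of real
interactomes), 16 tissues, 12 planted modules of 15 at intra-module edge
probability 0.9 over a background of 0.002, noise sd 0.5 on co-expressed
groups, 20 diseases, detection threshold 1.0. Cofactor popularity is
skewed (∝ 1/rank) so abundant metals dominate, matching curated catalogs.
All generators are pure functions of (spec, stage): per-stage substreams
are derived from (seed, stage tag), the same seed yields byte-identical
outputs, and ground truth is returned separately — never encoded in
identifiers the pipeline could read (disease ids are shuffled relative to
the planted nested order).

What is emulated: bipartite catalog structure with multi-cofactor
proteins; planted-partition PPI topology; co-expressed groups sharing a
latent tissue profile with additive Gaussian noise clipped at zero
(count-distributed noise is not simulated — the downstream analysis uses
only fold ratios and Pearson r on processed abundances); tissue-enriched
genes at a configurable fold (default 10); all-zero genes; disease gene
sets whose induced incidence is perfectly nested (built from
single-cofactor proteins so the planted repertoire is exact), noisily
nested, or random.

What is not emulated: real interactome degree distributions beyond
density/modularity, sequence-level features, identifier mapping noise,
count-based expression noise, disease-ontology structure. Passing tests on
synthetic data therefore demonstrate algorithmic correctness and
recoverability of planted structure, not performance on any specific real
snapshot — headline counts from mined 2015-era databases are not
reproducible at desk scale and are out of scope.

The nested generator's repertoire chain spans `n_diseases` prefix sets
with a minimum repertoire of 6 cofactors, keeping every planted disease
above the default strict min-genes filter (> 5).

## Problem sizes used in the tests

The suite exercises graphs of 25–500 nodes, expression matrices up to
1,000 × 16, and 400-replicate × 2,000-permutation calibration runs; the
full suite completes in well under a minute on one CPU. Monte-Carlo
properties use 20–50 fixed seeds; hypothesis-based property tests are
seeded and deterministic.

## Known limitations

* The module detector inherits the merging and triangle-chain behaviors of
  the published seeded-growth rule described above.
* NODF and the nested rank are computed exactly (no null-model
  standardization); comparisons across matrices of very different fill
  should use a null-model ensemble, which is out of scope here.
* The discrete hub-count permutation p-value is conservative for small
  graphs; at interactome scale (hundreds of hubs) the discreteness is
  negligible.
* GO/pathway enrichment relies on user-supplied annotation tables; no
  ontology handling or term merging is performed.
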