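# cofactornet

Multi-layer network analysis of micronutrient-derived cofactors, the
proteins that require them, the protein–protein interaction (PPI) network
those proteins live in, their tissue expression, and the diseases their
genes associate with.

Micronutrients act in metabolism largely as enzyme cofactors: metal ions
(Mg²⁺, Zn²⁺, Mn²⁺, …), vitamin-derived organic molecules (FAD, TPP, PLP,
THF, …) and in-vivo metabolites (SAM, glutathione, heme, …). A curated
catalog of cofactor–protein interactions can be turned into a multi-layer
network that links nutrition to biological processes and disease. This
package implements that analysis as a reusable, tested pipeline for
researchers in nutritional systems biology:

1. **Catalog layer** — a table of (protein, cofactor) records, normalized
   and deduplicated; bipartite cofactor × protein incidence.
2. **Interactome layer** — the PPI subnetwork of cofactor-interacting
   proteins augmented with the first-degree neighbors shared by ≥ 2 of them
   (bridging proteins), with every edge classed `cc`/`cn`/`nn` by its
   endpoint roles.
3. **Modules** — MCODE-style molecular-complex detection (k-core–based
   vertex weights `w(v) = k_max · density(k_max-core of N[v])`, seeded
   growth at the default node-score cutoff 0.2, haircut), with per-module
   cofactor over-representation (hypergeometric + Benjamini–Hochberg).
4. **Topology** — hubs as the top 2 % most-connected proteins and a
   one-sided permutation test of whether catalog proteins are
   over-represented among hubs; per-cofactor tissue co-expression (mean
   pairwise Pearson *r* vs size-matched random gene groups,
   `p = (1 + #{null ≥ obs})/(B + 1)`).
5. **Tissue specificity** — the six atlas-style categories
   (tissue enriched / group enriched / tissue enhanced / expressed in all /
   mixed / not detected, ≥ 5-fold rules) and the per-tissue share of
   cofactor-interacting proteins among tissue-enriched proteins.
6. **Disease layer** — weighted disease × cofactor incidence (weights count
   shared proteins), per-disease enrichment of catalog genes, matrix-wide
   NODF nestedness (0–100) and a per-disease nested rank in [0, 1]
   (0 = the disease interacting with the most diverse cofactor set).

Because the original mined inputs (curated cofactor catalogs, interactome
snapshots, multi-tissue RNAseq, disease–gene catalogs) cannot be
redistributed, the package ships a first-class synthetic generator that
emulates all four input classes with planted structure — dense modules,
co-expressed gene groups, tissue-enriched genes, nested disease–cofactor
incidence — so every stage has a ground truth to recover.

## Worked example

Generate synthetic inputs and run the full pipeline:

```sh
cofactornet simulate --outdir sim --seed 42      # writes catalog/ppi/expression/disease TSVs
cofactornet run --config config.yaml             # paths + seed + n_perm
```

or from Python:

```python
import cofactornet as cn

spec = cn.SyntheticSpec(seed=42, n_cofactors=20, n_proteins=300,
                        n_extra_proteins=900, n_modules=4, module_size=15,
                        background_edge_prob=0.005, n_diseases=12)
cn.simulate_all(spec, "sim")
summary = cn.run_all(cn.validate_config("config.yaml"))
```

With that spec and `n_perm=2000` the summary reports:

```
catalog:  {'n_cofactors': 20, 'n_proteins': 300, 'n_unique_pairs': 321}
assembly: {'n_cofactor_proteins_mapped': 299, 'n_neighbors_kept': 413,
           'n_neighbors_rejected': 296,
           'edge_counts': {'cc': 222, 'cn': 1126, 'nn': 605}}
modules:  {'n_reported': 4, 'sizes': [14, 19, 26, 46]}
hubs:     {'n_hubs': 24, 'observed_cofactor_hub_count': 3, 'p_value': 0.987}
tissues:  expressed_in_all: 470 of 600, permutation p = 0.0010
gwas diseases: matrix NODF 85.3, 12 diseases ranked
```

Reading: 321 unique catalog pairs over 300 proteins (~1.1 cofactors per
protein); the augmented network keeps 413 bridging neighbors and its edge
classes partition the 1,953 edges (222 + 1,126 + 605); module detection
recovers the four planted dense modules; catalog proteins are *not*
over-represented among hubs here (p = 0.987) but are strongly
over-represented among genes expressed in all tissues (p = 0.0010); and the
noisily nested disease map yields a high matrix NODF with the
broadest-repertoire disease ranked first (nested rank 0).

Every stage is also exposed as a subcommand (`assemble`, `modules`,
`topology`, `tissues`, `disease`) over the same TSV/GraphML files, so
user-supplied real tables can replace any synthetic input.

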