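# mgomics

Statistics for shotgun-metagenomics count tables and the companion omics
tables that travel with them (metabolite intensities, gene-function
annotations, clinical metadata), designed for case-control and longitudinal
microbiome studies. It is a scriptable library plus a thin `mgomics` command
line, aimed at analysts who have genome-cluster abundances (e.g. CONCOCT
bins), a rooted phylogeny and metadata, and want the standard numerical-
ecology and multi-omics toolbox over plain CSV/TSV/newick files.

## What it computes

* **Alpha diversity** — Shannon entropy `H = -Σ pᵢ ln pᵢ`, Gini-Simpson
  `D = 1 - Σ pᵢ²`, Pielou evenness `J = H / ln S`.
* **Phylogenetic community assembly** — MPD/MNTD with standardized effect
  sizes against a taxon-label-shuffle null; `NRI = -SES(MPD)`,
  `NTI = -SES(MNTD)`, positive values meaning phylogenetic clustering.
* **Ordination & distance tests** — PCA, Bray-Curtis dissimilarity, metric
  MDS (PCoA), single-factor PERMANOVA
  (`pseudo-F = (SS_b/(a-1))/(SS_w/(N-a))`, `R² = SS_b/SS_t`, permutation p),
  and fuzzy set ordination of a continuous covariate (Roberts' single-
  variable formulation, similarity `s = 1 - d/d_max`).
* **Differential abundance** — per-feature Kruskal-Wallis (or Friedman for
  repeated measures), Benjamini-Hochberg correction across features, Dunn's
  pairwise post hoc with tie-corrected z-statistics.
* **Pathway enrichment** — hypergeometric over-representation of KEGG
  orthologs (KOs) in pathways, BH-corrected.
* **Multi-omics integration** — two-block joint decompositions DISCO-SCA,
  JIVE and O2PLS, splitting each block into joint, distinctive and residual
  variation, with ranked joint-loading reports.
* **Synthetic data** — seeded generators for all input kinds with planted,
  known structure (group effects, joint/distinctive components, trees).

## Worked example

`examples/01_diversity_and_differential_abundance.py` simulates a 60-sample,
200-taxon case-control study with five planted differential genome clusters
and runs the full differential-abundance workflow:

```
planted differential taxa: ['C184', 'C3', 'C35', 'C46', 'C56']

Shannon by group: G1=4.653, G2=4.503
Kruskal-Wallis on Shannon: H=20.200, p=6.97e-06

5 taxa at BH padj <= 0.05 (of 200 tested); top hits:
  C56: H=43.6 padj=8.14e-09 log-rel-abundance means [G1: -6.59, G2: -8.94]
  C3: H=38.6 padj=3.73e-08 log-rel-abundance means [G1: -5.08, G2: -7.32]
  ...
recovered 5/5 planted taxa; 0 false positives
```

Each hit reports the omnibus Kruskal-Wallis statistic, the BH-adjusted
p-value across all 200 taxa, and the group means on the analysis scale
(natural log of relative abundance); all five planted taxa are recovered
with no false positives. The other examples cover NRI/NTI
(`02_phylogenetic_community_assembly.py`), Bray-Curtis PCoA + PERMANOVA +
FSO (`03_…`, e.g. `PERMANOVA: pseudo-F=9.13, R2=16.0%, p=0.001`), pathway
enrichment (`04_…`) and DISCO-SCA/JIVE/O2PLS integration (`05_…`).

The same operations are available from the shell, e.g.

```sh
mgomics simulate community --seed 1 --out sim/
mgomics diversity --table sim/counts.tsv --index shannon --out div/
mgomics permanova --table sim/counts.tsv --metadata sim/metadata.tsv \
    --group group --nperm 999 --seed 1 --out pm/
```

Every run writes TSV results plus a `run_log.json` recording version,
parameters and seed, so any run can be replayed from its log.

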