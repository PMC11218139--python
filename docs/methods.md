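# Methods

This note records the statistical definitions the package implements, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical choices that matter for reproducibility.

## Input model and harmonisation

All analyses operate on a samples × features matrix (`FeatureTable`) with
unique string identifiers on both axes and a `transform_tag` recording its
scale (`raw`, `relative`, `log`, `log_relative`, `pareto`, `centered`). Raw
tables must be non-negative and finite; files are CSV or TSV (delimiter by
extension, falling back to sniffing the header line) with the first row and
column as headers. Multi-table analyses first pass through
`harmonize_samples`, which restricts every input to the intersection of
sample ids in lexicographic order and reports what was dropped. Matching is
exact on the id string — no case folding or whitespace stripping — because
silent coercion is a common source of sample mix-ups. Missing metadata
values stay missing: tests drop the affected samples and report them; they
never become zeros.

## Pre-processing

* `relative_abundance` divides each sample row by its total. The compositional
  alternative transforms (CLR/ILR) and rarefaction are out of scope.
* `log_transform` is the natural log with a pseudocount. The default
  pseudocount is half the smallest non-zero entry of the whole table: it is
  scale-aware (works equally for counts and proportions) and keeps zeros
  strictly below every observed value. A fixed pseudocount is available when
  comparability across tables matters.
* `pareto_scale` computes `(x - mean) / sqrt(sd)` per feature with the
  sample (n−1) standard deviation, the metabolomics convention the name
  comes from; it damps large intensities less aggressively than
  unit-variance autoscaling. Constant features become all-zero and are
  reported rather than producing NaNs.
* `aggregate_by_group` collapses contig coverages to genome-cluster
  abundances, by mean (default — a cluster is "expressed in average
  abundance", so clusters with different contig counts remain comparable)
  or sum.
* `block_scale` column-centers a block and divides it by its Frobenius norm.
  Every block entering a joint decomposition then contributes equal total
  sum of squares, so neither feature count nor measurement scale decides
  which block dominates the fit. The scaling record supports the inverse
  transform.

## Diversity

With `p_i` the within-sample proportions over non-zero features:
Shannon `H = -Σ p_i ln p_i` (natural log; `0·ln 0` handled by summing over
non-zero features only), Gini-Simpson `D = 1 - Σ p_i²` (reported so larger =
more diverse; the choice is recorded in output metadata), Pielou
`J = H / ln S` with `S` the observed richness, undefined (NaN) at `S = 1`.
All three are invariant to the sample total, so raw counts and proportions
give identical values.

## Phylogenetic community assembly

MPD is the mean cophenetic distance over unordered pairs of present taxa;
MNTD the mean distance to the nearest other present taxon. Presence is
`value > 0` (unweighted); abundance weighting is deliberately off because
the indices are introduced here as presence-based assembly diagnostics.
The null model shuffles taxon labels on the cophenetic matrix
("taxa.labels" style, the most common choice in the community-phylogenetics
literature), with 999 replicates by default; for a community of size k this
draws uniformly among all k-subsets of the pool. One permutation is shared
by all samples within a replicate. Outputs per sample: observed value, null
mean and sd (sd with n−1 denominator, the Monte-Carlo estimator of the null
population sd), `SES = (obs - mean)/sd`, `NRI/NTI = -SES` (positive =
clustered), and the rank p-value `(#{null ≤ obs} + 1)/(n_null + 1)`, which
is never 0. Degenerate cases are flagged, not guessed: fewer than two
present taxa → `too_few_taxa`; a constant null (e.g. a star tree, or a
community holding the entire pool) → `constant_null` with missing SES.

## Ordination and distance-based tests

* PCA is the SVD of the centered (optionally unit-scaled) matrix; explained
  fractions are eigenvalues of the covariance matrix over their total.
  Community tables are centered only; metabolite tables are expected to be
  Pareto-scaled upstream.
* PCoA applies Gower double-centering to `-d²/2` and eigendecomposes.
  Negative eigenvalues (metric violations, common for Bray-Curtis) are
  reported but excluded from both the scores and the explained-fraction
  denominator ("positive-only"). The tool's MDS is metric PCoA, not NMDS.
* PERMANOVA is single-factor: `SS_t = Σ_{i<j} d²_{ij}/N`,
  `SS_w = Σ_g Σ_{i<j∈g} d²_{ij}/n_g`, `SS_b = SS_t - SS_w`,
  `pseudo-F = (SS_b/(a-1))/(SS_w/(N-a))`, p by random relabeling with the
  observed statistic included (+1/+1), so p has resolution `1/(n_perm+1)`
  and is never 0. On univariate Euclidean data this reduces exactly to
  one-way ANOVA, which the tests exploit as an oracle.
* FSO follows the single-variable formulation: memberships `μ` rescale the
  covariate to [0, 1], similarities are `1 - d/d_max`, the apparent
  membership of a sample is the similarity-weighted mean of the others'
  memberships, and `r = cor(μ, apparent)`. Significance is one-sided
  (observed r against permutations of the covariate), since the question is
  whether the gradient is expressed, not inverted.

Ordination axes and all component loadings use one sign convention — the
largest-|loading| entry of each axis is positive — so repeated runs and
ranked tables are comparable.

## Rank-based testing

Kruskal-Wallis uses joint mid-ranks with the standard tie correction
(all-identical data returns H = 0, p = 1 rather than an error). Friedman
uses within-block mid-ranks in Conover's tie-corrected form, which reduces
to `χ² = 12/(nk(k+1)) Σ R_j² - 3n(k+1)` without ties; incomplete blocks are
dropped and reported. Both use the chi-square approximation (no exact
small-sample tables); group sizes below ~5 make p-values approximate.
Dunn's post hoc compares mean joint ranks with the tie-corrected standard
error and two-sided normal p-values. Multiplicity: BH across features for
the omnibus tests, then BH across pairs within each feature for Dunn —
"corrected" is under-determined in practice, so the method is a parameter
(`bh`, `bonferroni`, `none`) and is recorded in outputs. Dunn post hoc is
computed for independent-design features passing `padj ≤ alpha`. Constant
features are flagged rows with missing p, excluded from the BH family.
Correlations (Pearson, Spearman, Kendall tau-b) use pairwise-complete
deletion and scipy's standard p approximations.

## Pathway enrichment

The counting unit is the KO, not the feature: a genome cluster contributes
the union of its KOs, because pathway membership is defined on orthologs.
The default background universe is every annotated KO appearing in at least
one pathway ("in-pathway"); `all-annotated` widens it to every annotated KO,
which is more conservative. The p-value is the hypergeometric upper tail
`P(X ≥ k)` for `k` selected KOs among `K` pathway members, `n` selected and
`N` universe KOs; one-sided over-representation only, BH across pathways,
rows sorted by p then pathway id.

## Multi-block integration

All three methods consume `block_scale`d blocks sharing the same samples in
the same order and report, per block, the joint / distinctive / residual
split of its total sum of squares.

* **DISCO-SCA.** A rank-R simultaneous component analysis (truncated SVD of
  the column-wise concatenation, R = common + Σ distinctive) followed by an
  orthogonal rotation of the loadings toward the DISCO target: distinctive
  components of one block must have zero loadings in the other, common
  components are free. The rotation minimises the squared loadings on the
  constrained-zero positions over the orthogonal group by pairwise Jacobi
  (Givens) rotations — for each column pair the masked energy is
  `const + a₁cos2θ + a₂sin2θ`, so each step has a closed-form optimum — from
  the identity plus 10 seeded random starts, keeping the best. The rotation
  stays inside the SCA subspace, so the overall fit is exactly preserved.
* **JIVE.** Alternates a rank-r fit of the concatenation minus individual
  structure with per-block rank-rᵢ fits of the block minus its joint slice,
  projected so each individual score subspace is orthogonal to the joint
  one (the shared-mode orthogonality that makes the decomposition
  identifiable). Non-convergence at `max_iter` returns the current state
  with `converged=False`.
* **O2PLS.** Joint weights come from the leading singular triplets of the
  cross-block covariance `XᵀY`. Before the final joint fit, each block's
  structured variation *unrelated* to the other block ("orthogonal"
  components) is estimated from the residual `X - TWᵀ` projected onto the
  joint scores and deflated; this is what separates O2PLS from plain
  cross-covariance SVD and what the planted-orthogonal-variation test
  demonstrates.

Ranks are user-supplied; there is no automatic selection (a scree of SCA
singular values, `sca_scree`, is provided to guide the choice). DISCO-SCA
and O2PLS are two-block; JIVE accepts two or more. `common_scores` columns
are orthonormal in all three methods (for O2PLS the orthonormalised basis of
the joint X-scores; raw `T`/`U` scores are kept in `extras`). Variance
fractions are computed from the norms of the corresponding reconstruction
pieces; for DISCO-SCA the cross-block energy of distinctive components
(zero up to rotation accuracy) is the only part assigned to no bucket, so
the three fractions sum to 1 up to that energy.

## Numerical choices

* Convergence: the DISCO rotation and JIVE alternation use an absolute
  tolerance of 1e-12 (relative to total loading energy for the rotation).
  This is tighter than accuracy alone requires; it buys bit-stable results
  under sample reordering (equivariance to ~1e-9) at negligible cost for
  the intended problem sizes (tens to hundreds of samples, up to a few
  thousand features).
* Permutation p-values always include the observed statistic (+1/+1).
* Ties are broken deterministically everywhere: lexicographic ids in
  harmonisation and ranked-loading tables, stable sorts in enrichment.
* Feature tables are written with 17 significant digits, so write/read
  round-trips are exact for float64.

## Synthetic data: what it does and does not emulate

`simulate_community` draws gamma-mixed Poisson (negative-binomial-like)
counts: lognormal baseline proportions, balanced groups, log-scale offsets
of ±`effect` on the affected taxa (alternating sign, with library sizes
rebalanced so totals stay comparable across groups), and per-cell gamma
overdispersion. Defaults — 60 samples, 200 taxa, 5 affected, effect 2
(≈7.4-fold), dispersion 0.5 — represent a moderately powered two-group
shotgun study. It does **not** emulate compositional closure artefacts at
high effect sizes, taxon-taxon correlation structure, sequencing batch
effects, or zero-inflation beyond what the NB-like model produces; passing
tests therefore show correct statistical behaviour under a clean
overdispersed model, not robustness to every property of real metagenomes.

`simulate_paired_blocks` builds `X_b = sT P_bᵀ + dD_b Q_bᵀ + E_b` with a
shared orthonormal score matrix T, block-specific distinctive scores
orthogonal to it, unit-norm loadings, and i.i.d. Gaussian noise. Score
directions are drawn with zero mean so that per-block column centering
leaves the planted orthogonality intact — without this, the noiseless
cross-block-energy contract of DISCO-SCA is unattainable by construction.
Signal strengths default to 1.0 (joint) and 0.6 (distinctive);
`noise_sd_for_snr` converts a target Frobenius signal-to-noise ratio into
the entrywise noise sd. Real paired omics differ mainly in having many weak
components and non-Gaussian noise.

`simulate_tree` grows a pure-birth (Yule) topology by splitting uniformly
chosen tips, with independent Exp(1) branch lengths, labelled T1..Tn; the
newick string is bit-reproducible per seed.

## Validation problem sizes

The acceptance checks run at sizes chosen to make their statistical
tolerances meaningful while staying desk-scale: 50 datasets for the
PERMANOVA/ANOVA identity and 200 null simulations for its type-I rate
(n_perm = 199); 9999 null replicates against exhaustive 6-taxon subset
enumeration for NRI/NTI; 100 null replicates for FSO calibration; 20
replicates at SNR 10 (40 samples, 30+25 features) for integration recovery;
and 50 power plus 20 null replicates of the full 60 × 200
differential-abundance pipeline. The null-data O2PLS check uses 60 samples,
where the expected spurious leading cross-covariance fraction is safely
below the 0.15 bound (at very small n that fraction is large for purely
combinatorial reasons).

## Known limitations

Single-factor PERMANOVA only (no multi-factor designs, no dispersion test);
metric PCoA rather than NMDS; no constrained ordination or multivariate
regression; chi-square approximations for the rank tests; no automatic rank
selection for the integration methods; two-block DISCO-SCA/O2PLS; KEGG
catalogs must be supplied as mapping tables (no live downloads); exact-match
sample ids.
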