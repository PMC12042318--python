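# Methods

This note documents the statistical models, the synthetic cohort's planted
structure, numerical choices, and the design decisions taken where the
design was genuinely open. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Cohort and study design

The pipeline targets a three-group postmortem design — controls (CON),
major depressive disorder (MDD) and PTSD — sampled in two prefrontal
regions (DLPFC, sgPFC), with DIA proteomics (log10 intensities), RNA-seq
counts and small-RNA counts on the same donors. All differential and
network analyses are region-stratified and contrast CON against one case
group at a time; donors appear once per region, and regions are analysed
separately rather than with repeated-measures models.

## Differential abundance

**Proteins.** Per-feature OLS of log10 intensity on diagnosis + age +
ancestry + sex (ancestry and sex one-hot, reference = most frequent level).
Residual variances are shrunk by empirical Bayes: log s²_g is
moment-matched to a scaled F distribution via digamma/trigamma moments,
with the trigamma inverse solved by Newton iteration; d₀ = ∞ when the
observed spread of log-variances is no wider than χ² sampling alone
explains. Moderated t = β̂/(s̃·√v) on d₀+d_g df. Complete cases per feature;
features with fewer complete cases than rank(X)+1 are flagged untested.
Coefficients are estimated on the log10 scale and reported as log2 fold
changes (×log2 10). One test cross-checks t, p, d₀ and s₀² against
Bioconductor limma on a shared fixture (agreement ~1e-14); the
implementation itself never calls R.

**Counts.** NB2 GLM per feature with log link and log size-factor offset
(median-of-ratios factors rescaled to geometric mean 1). IRLS is batched
across features (stacked normal equations, per-feature convergence at
1e-8, 100-iteration cap; non-converged features get missing p). Dispersion:
method-of-moments on normalized counts, clipped to [1e-8, 50], then refined
by vectorized golden-section ML at the fitted means, then one refit. Wald z
on the diagnosis coefficient, BH FDR. Covariate sets are modality-specific:
RNA adds PMI, age², RIN, RIN²; miRNA uses age, RIN, sex. No claim of parity
with DESeq2 is made (no Cox–Reid adjustment, dispersion trend, LFC
shrinkage, independent filtering or outlier replacement); the contract is
calibration — null type-I error near nominal and the Poisson limit — which
the acceptance suite measures. The Wald test is mildly anticonservative at
these sample sizes (measured ~0.06 at α = 0.05), as Wald tests are.

**BH adjustment** is the step-up procedure with enforced monotonicity;
missing p-values are ignored and propagate.

**RRHO.** Both DE tables are ranked by −log10(p)·sign(log2FC); at each grid
step pair (i, j) the map holds the −log10 upper-tail hypergeometric
probability of the top-i/top-j overlap, signed positive in the concordant
(up/up, down/down) quadrant blocks defined by each list's sign change.
Default step = ⌊√N⌋. p-values are clamped at 1e-50 for display.

## Co-expression modules

Signed adjacency ((1+r)/2)^β with β = 6 (DLPFC) and 4 (sgPFC), or chosen by
the scale-free scan: connectivity is binned into 10 equal-width bins and the
fit index is R² of log10 frequency vs log10 mean connectivity (negated for
rising slopes); the smallest power reaching 0.8 wins, else the configured
default. Topological overlap, then average-linkage clustering of 1−TOM
(scipy's implementation).

**Tree cut.** A single static cut height cannot serve both strong modules
(which separate far below the dendrogram root) and weak ones (which
separate just beneath the noise floor), so clusters of at least the minimum
size (20) are harvested at ascending fractions of the maximum merge height
(0.88–0.98) and accepted when their median within-cluster correlation
passes a cohesion floor (0.2). Noise clumps fail the cohesion test; on pure
noise ≥95% of features stay grey. Accepted clusters are then merged
whenever their eigengenes cluster within 1−r < 0.1 (average linkage),
recomputing eigengenes after each merge round. Labels are deterministic
color names ordered by module size (largest = turquoise).

**Eigengenes** are first right singular vectors of the z-scored module
submatrix, unit-norm, sign-aligned so the mean member correlation is
positive; kME is the feature × eigengene correlation. Module–trait
association is Pearson r of eigengenes against encoded traits (dx 0/1, sex
F=0/M=1, ancestry one-hot, continuous as-is) with BH over the full
module × trait grid (a per-trait scope is a config option). Cross-disorder
preservation: Fisher one-sided overlap of the two assignments per module
pair, Haldane 0.5 on zero cells, BH across pairs, preserved iff FDR < 0.05.

## Networks and key drivers

Mutual information uses the Gaussian-rank estimator: rank-based inverse
normal transform per feature, Pearson r on scores, MI = −½ln(1−r²) (nats),
capped at 5; invariant under monotone transforms. An equal-frequency
binning plug-in estimator is available behind a config key. ARACNE applies
the data-processing inequality with tolerance ε = 0: every triple is
evaluated against the original matrix and removals are applied after the
full pass, so the result is node-order invariant. Key-driver analysis:
Fisher enrichment of the signature within each node's h-hop neighborhood
(h = 2 by default, background = network nodes), BH across nodes, drivers at
FDR < 0.05 ranked by odds ratio then p. Module-local networks are the
subgraph induced by members plus their direct neighbors.

## Enrichment

One Fisher 2×2 engine (one-sided greater; hypergeometric tail; Haldane 0.5
odds ratio on zero cells; BH across sets) backs module/cell-type,
module/trait-list, miRNA/DEP and miRNA/module tests. Note that a one-sided
exact test is conservative on coarse tables: its attained level approaches
the nominal 0.05 only when the expected overlap is large, which is how the
calibration simulations are sized.

**Cell-type specificity (pSI).** For each type t, genes are ranked by the
log-mean difference against every other type; SI is the average rank. The
null shuffles each gene's values across types; permuted SI values are
pooled per type across genes and permutations into one empirical null, so
pSI is strictly monotone in SI and has resolution 1/(B·G) rather than the
1/T floor a per-gene comparison would impose. CSEA then Fisher-tests each
module against each type's pSI ≤ 0.05 gene set.

**Preranked GSEA.** Running-sum enrichment score with hits weighted
|score|^p (p = 1 default) and misses 1/(N−N_H); ties broken by feature id;
gene-label permutation null; p compares |ES| against same-sign permuted
scores; NES divides by the mean same-sign |ES|; BH across sets (a
documented divergence from the original NES-pool FDR). Sets overlapping the
ranking by <3 features are skipped.

**Trait gene lists.** The top 200 genes per trait are intersected with the
gene universe mappable to measured proteins and Fisher-tested against each
module's mapped genes; nominal p < 0.05 is the significance convention for
these lists, with FDR reported alongside.

## miRNA–protein integration

miRNAs with mean raw count > 0.5 are converted to FPKM
(counts·10⁹/(length·library)) and stored as log2(FPKM+1) — the pseudocount
handles zeros. On matched samples (CON+case, one region), every
(protein, miRNA) pair is Pearson-correlated (pairwise-complete for missing
protein cells, ≥3 observations), with two-sided t p-values; edges at
nominal p < 0.05 are deliberately not multiplicity-adjusted — inference
happens at the enrichment layer. An `adjust` option computes
covariate-partialled correlations (df reduced accordingly).

Per miRNA, the tested-protein universe is the denominator for Fisher
enrichment of (a) nominal DEPs and (b) each module's membership among its
significantly connected proteins; the display sign of −log10 p follows the
miRNA's disease log2FC (or, optionally, the mean edge correlation).

**Grouped fold-change regression.** Protein log2FC is regressed on RNA
log2FC separately for miRNA-associated proteins and the rest. Candidate
regulators are differentially expressed miRNAs (nominal p < 0.05) whose
module enrichment survives FDR with negative mean edge correlation —
FDR here because any miRNA whose expression happens to track diagnosis or a
module eigengene acquires correlation edges to that entire module, and a
nominal selection would label nearly every module protein associated.
"Associated" additionally requires predicted-target support (a significant
negative edge from a candidate to one of its database-predicted targets):
in one observational dataset, correlation alone cannot distinguish a true
regulator from an eigengene-tracking bystander, but predictions are
external information. Proteins with unexplained negative candidate edges,
and predicted targets whose edge went undetected, are excluded from the
contrast group as ambiguous rather than counted as clean controls.

## The synthetic cohort generator

Defaults: 19 donors per group × 3 groups × 2 regions; 2,600 proteins, 8,000
genes, 1,365 miRNAs; 8 modules of 20–80 proteins; loadings in 0.4–0.9 with
per-module bands of half-width 0.1 (members of a real module track their
eigengene comparably; wide within-module loading spread would also
fabricate fold-change correlations that are not part of the planted
biology); eigengene disease shift 0.8 SD; 3 regulator miRNAs with 12 strong
targets each; γ = 0.5 log10-intensity units per log2-FPKM unit with
per-target spread U(0.25, 1.75)·γ; regulator upregulation δ = 1.5 log2 in
cases (chosen so planted edges are detectable at the matched-sample sizes
the design yields, n = 38 per region pair); NB dispersions log-normal(−2,
0.5); library-size factors U(0.5, 2); protein residual SD 0.5 log10 units.

Planted structure, by construction:

* Protein i: μ_i + λ_i·e_{m(i)} − Σ_r γ_ir·z_r + ε, with e_m = α_m·1[case]
  + N(0,1) and z_r the centered log2-FPKM of regulator r. The
  regulator-targeted modules carry α = −0.8 in both disorders: upregulated
  miRNAs repressing a disease-downregulated module.
* Each regulator also diffusely represses 30% of its module's non-target
  members at 0.3·γ — network-level regulation beyond direct 3'-UTR targets,
  which is what makes the module-level enrichment signal module-wide rather
  than confined to 12 proteins.
* Matched transcripts of module proteins share the eigengene at coupling
  0.1 on the ln-mean (transcript–protein disease concordance is weak in
  brain cohorts) and carry **zero-centered transcriptional buffering**:
  targets repressed above their regulator's average get a compensatory
  transcript term, below-average targets the opposite
  (κ = 0.4, applied to γ_i − γ̄). The net transcript change across targets
  is exactly zero and individual targets stay below differential-expression
  detection — operationally "transcripts unchanged" — while the
  within-group anticorrelation between RNA and protein fold changes becomes
  a real, recoverable property rather than a sampling accident. Setting
  `transcript_compensation = 0` gives strictly protein-only repression, in
  which case the grouped regression's group-wise correlation has no defined
  sign. Direct miRNA repression never enters the transcript equation.
* Singleton differential features per modality, plus 40 shared
  transcription-driven pairs (gene and protein shift together, protein
  attenuated ×0.8) that anchor the RNA–protein concordance analysis.
* Cell-type reference and trait gene lists are generated to order: marker
  sets with ≥10-fold specificity, and ranked lists whose module overlap is
  drawn to achieve a requested odds ratio in expectation (odds 1 reduces to
  the hypergeometric expectation).

What the generator does **not** emulate: batch/instrument effects, peptide-
level missingness mechanisms beyond an optional MNAR-at-low-intensity
switch (default off), donor correlation across regions (samples are drawn
independently per region), LD or genotype structure behind the trait lists,
and isoform/post-translational complexity. Passing tests therefore
demonstrate that the statistical machinery recovers the planted effects at
realistic sizes and noise — not that it would be similarly powered on any
particular real dataset.

## Simulation sizes and known limitations

Calibration suites pool ≥2,000 null tests per engine; the end-to-end
recovery runs the full default cohort over 10 seeds; module-recovery
simulations use 800 proteins, 4 modules (sizes 30–60, loadings ≥0.6) and 60
single-region samples. One property is measured but not attained: with a
0.8 SD eigengene shift and ~20 samples per group, the disease-associated
module's eigengene–diagnosis correlation (≈0.37) has nominal power well
below what a ≥9/10-seed FDR<0.05 detection rate requires (two-sample d=0.8
power ≈0.87 at α=0.05 before any multiplicity correction), and the
corresponding acceptance test is left failing rather than inflating the
planted effect or relaxing the threshold; the ARI clause of the same
simulation passes at 10/10. Other known limitations: the one-pass
eigengene merge can differ from iterated merging on pathological dendrograms;
the connection-graph layer stores all ~3M tested pairs in memory
(~200 MB at default sizes); and key-driver results depend on the
neighborhood depth h, for which no principled default exists beyond
convention (h = 2).
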