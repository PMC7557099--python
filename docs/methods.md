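# Methods

This note records the models, defaults, and design decisions behind
`pgxstrat`, in the spirit of a statistical software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Cohort model

A cohort is N individuals × V biallelic SNVs. Genotypes are stored as
effect-allele dosages in {0, 1, 2} with missing calls as NaN; all
downstream statistics are oriented by the annotated effect allele, not
by VCF REF/ALT polarity, and flipping the designated effect allele maps
every dosage g → 2 − g and every frequency p → 1 − p (a property the
tests enforce). Effect-allele frequency in a subset is (effect allele
count) / (2 × typed individuals); missing genotypes leave both the
numerator and the denominator (unbiased under missingness at random).
An all-missing stratum is an undefined-frequency signal (an exception),
never 0. Multi-allelic records and indels are excluded on VCF import
with a logged count: the analysis is defined for SNVs. Coordinates are
1-based (VCF convention); variants are keyed by their identifier, and
positions are carried but never used for matching.

The tabular interface is four TSVs (dosage matrix; ancestry fractions;
SIRE labels; variant/PGx metadata). The variant metadata table holds
every variant, with the PGx columns (mode, drug, effect type,
direction) empty for unannotated variants, so a write→read round trip
is the identity for the whole cohort.

## Synthetic admixed cohort

The generator emulates a three-way admixed cohort of the kind studied
in US pharmacogenomic surveys, so every downstream stage can be tested
against planted ground truth.

* **Ancestry.** Each group g draws individual (European, African,
  Native American) fractions from Dirichlet(α_g). Defaults are α
  proportional to the groups' characteristic mean ancestry percentages
  — (99, 0.5, 0.5), (17, 82, 1), (60, 3, 37) — at concentration sum
  ≈ 100, giving a coherent majority group and broader minority-group
  ancestry distributions (the third group has the largest variance, as
  observed in real admixed cohorts).
* **Genotypes.** For each of the two allele copies at each variant, a
  continental origin is drawn from the individual's ancestry fractions
  and the allele is Bernoulli with that continent's ancestral
  frequency. This per-copy admixture model — rather than group-level
  Hardy–Weinberg sampling — is what creates the individual-level
  ancestry–genotype correlation that the regression layer measures.
  The origin is drawn independently per individual × variant × copy;
  drawing it at any coarser granularity introduces spurious
  individual-level covariance across variants that destroys the
  genome-wide structure.
* **Ancestral frequencies.** Per continent, iid Beta(0.8, 0.8) per
  variant, giving a broad spectrum of between-group differentiation
  (group-vs-complement FST roughly in the 0–0.3 range after admixture
  damping).
* **PGx panel.** A configurable number of variants (default 100 of
  1000, ~10%) receives a PGx annotation; half additive, half dominant
  by default (`mode_mix`). A `pgx_divergent_fraction` share of the
  panel (default 0.5) is rejection-sampled until the max−min
  continental frequency gap is at least `min_pgx_gap` (default 0.7).
  The gap default sits in the upper tail of the Beta(0.8, 0.8) draw
  (whose triples already average a gap of ~0.5, so small thresholds
  are no-ops); it makes the planted subpanel clearly more diverged
  than the remainder (mean group-vs-complement FST ≈ 0.12 vs ≈ 0.07
  at the default scale), mirroring the split between significantly
  diverged and background-like PGx variants seen in real panels.
* **Labels and missingness.** SIRE equals the true group, reassigned
  uniformly to another group with probability `mislabel_rate`
  (default 0 — the dial for SIRE/GA discordance experiments);
  genotypes are masked missing with probability `missing_rate`
  (default 0.01, matching a ≤1% missingness filter).
* **Ground truth.** The truth object records group assignments,
  ancestry, ancestral frequencies, the PGx and divergent-PGx indices,
  and closed-form expected group frequencies p_g = Σ_pop ᾱ_g,pop ·
  f_pop (ᾱ the Dirichlet mean), from which expected pairwise FST is
  evaluated as an oracle for the divergence layer.

All draws flow from one `numpy.random.Generator` in a documented order
(PGx subset → divergent subset → frequencies → ancestries → labels →
allele copies → missingness), so identical seeds give bit-identical
cohorts.

What the generator does **not** emulate: linkage disequilibrium,
ancestry tracts along chromosomes, realistic site-frequency spectra,
genotyping error, or correlated continental frequencies (real
continental frequencies are strongly correlated; iid draws make the
average variant far more diverged than a real genome-wide background).
Consequently, passing tests demonstrate that the statistics recover
planted structure under the stated model — not that real cohorts would
show effects of any particular size. In particular, at the default
sample size essentially the whole PGx panel reaches significance in
the divergence scan, which is expected under iid continental draws and
n = 900, not a property of real PGx panels.

## Ancestry grouping

k-means (scikit-learn, k-means++ seeding, tolerance 1e-6, max 300
iterations) is run `restarts` times (default 100). Because cluster
labels are arbitrary per restart, each restart's labels are aligned to
the lowest-inertia restart by a minimum-cost bijection between
centroids (Hungarian assignment on squared distances); each sample then
takes its modal label across restarts, with ties broken in favor of
the best restart, and the fraction of restarts agreeing is reported as
a per-sample stability score. If the modal consensus ever has a worse
within-cluster sum of squares than the best single restart (possible
only in pathological geometries), the best restart is returned
instead, so the returned objective never exceeds that of any restart.
k defaults to 3 to match the three SIRE categories but is a parameter.

Robustness to sample size is assessed by subsampling (without
replacement, over a fraction grid × repetitions), re-clustering, and
aligning each subsample's labels to the full-data grouping by maximal
overlap; the agreement on the subsampled individuals is reported per
fraction.

Concordance between a clustering and SIRE labels pairs clusters with
labels by the bijection maximizing total matches (assignment problem),
making the score invariant to any relabeling. Both conditional views
are reported, since they genuinely differ: the fraction of a cluster
carrying its paired label, and the fraction of a label falling in its
paired cluster.

## Divergence

FST uses the two-population Nei decomposition F_ST = 1 − H̄_S/H_T with
allele-count weights (formulas in the README). By Jensen's inequality
H̄_S ≤ H_T, so the estimator lies in [0, 1]; no small-sample bias
correction is applied, matching the plain heterozygosity decomposition.
A pooled-monomorphic variant (H_T = 0) has undefined FST, propagated as
NaN and excluded from summaries.

The group-vs-complement scan tests each variant × group 2×2
allele-count table with a Pearson chi-square (no continuity
correction), switching to Fisher's exact test when any expected cell is
below 5 — the standard regime split for frequency tables. Tables with
an empty margin get p = 1. The BH family is all (variant × group) tests
in one scan. Dominant-mode PGx variants are still treated on the allele
scale here; the effect mode changes the counting unit only in the risk
layer, keeping the divergence layer purely allele-frequency-based.

## PGx structure

Inter-individual distance is the allele-sharing distance 1 − IBS on
dosage vectors (per co-typed variant, 2 − |g_i − g_j| shared alleles
out of 2), chosen over raw Hamming-type distances because it is bounded
in [0, 1], missing-tolerant (pairwise deletion), and scale-free. The
embedding is classical Torgerson scaling (double-center −½D², top
eigenpairs, coordinates scaled by √eigenvalue, negative eigenvalues
truncated at zero) — i.e. `cmdscale` semantics rather than
stress-minimizing SMACOF, because the downstream k-means needs a
deterministic linear embedding and the distance is near-Euclidean.
Clustering and SIRE correspondence reuse the grouping machinery
verbatim, so the correspondence score inherits invariance to axis sign
flips and relabeling.

## Risk statistics

For each PGx variant and implicated group vs pooled complement
(additive mode: allele counts; dominant mode: carrier/non-carrier
individuals, a carrier having dosage ≥ 1):

* OR is the cross-product ratio with a log-scale Wald CI,
  SE = √(1/P_E + 1/P_N + 1/Q_E + 1/Q_N), z = 1.96 at α = 0.05.
* ARI is the difference in effect proportions ×100, with the standard
  Wald SE for a difference of proportions.
* Accuracy counts TP = effect units in the implicated group,
  FP = effect units elsewhere, FN/TN the non-effect complements; its
  default CI half-width is z·√((Err/(1−Err))/N) with Err the
  misclassification rate (a Wald binomial CI is available by option).
* PPV is the within-group effect fraction (post-test probability),
  prevalence the cohort-wide fraction (pre-test), and information gain
  100·|PPV − prevalence| per 100 patients.

Zero cells make the OR undefined by default; the Haldane–Anscombe 0.5
correction is available behind a flag rather than silently applied.
The "implicated" (reference) group per variant is the group with the
maximal effect frequency; every group's row is also emitted so
per-group distributions (e.g. of information gain) can be formed.

## Regression layer

Ancestry association regresses an ancestry fraction on dosage (OLS
with intercept, t test on the slope, df = n − 2). The SIRE-vs-GA
comparison regresses per-variant frequency differences for a SIRE pair
on those of the corresponding GA pair (pairing from the concordance
bijection; pair orientation fixed lexicographically so Δp signs are
reproducible). Two tests are reported: two-sided for H₀: β = 0 and
lower one-tailed for H₀: β = 1 (alternative β < 1, i.e. GA resolves
more divergence than SIRE), with effect size d = (1 − β)/2 mapping the
attainable slope range [−1, 1] onto [0, 1]. The intercept is included:
excluding it would conflate mean shifts with slope, and the unity-line
comparison concerns slope only. Exactly collinear inputs (zero
residual variance) take limit-case p-values — p = 1 when the null
holds exactly, p = 0 otherwise — so degenerate-but-meaningful inputs
(identical difference vectors) are well-defined.

## Pipeline, determinism, and problem sizes

The `all` driver runs simulate/load → ancestry grouping → divergence
scan → PGx structure → risk table → slope tests, writing each stage's
tables and one `report.json`. Stage seeds are derived from the single
run seed (seed, seed+1, seed+2 for simulation, ancestry clustering,
and embedding clustering), and outputs contain no timestamps, so a
rerun with the same configuration is byte-identical.

Default problem sizes — 300 individuals per group, 1000 variants, 100
PGx, 100 clustering restarts — keep a full pipeline run in the
tens-of-seconds range on one CPU while leaving all planted effects
comfortably detectable; the statistical checks in the test suite use
larger strata (up to 5000 per group) only where a law-of-large-numbers
or coverage statement needs them. The restart count of 100 matches
standard practice for consensus k-means on low-dimensional data.

## Known limitations

* The divergence layer is single-locus; no haplotype or hierarchical
  (AMOVA-style) partitioning.
* The scan's chi-square/Fisher split and the Wald-type CIs are
  asymptotic conventions; very sparse tables are better served by the
  exact path, which the expected-cell rule selects automatically.
* Real-data headline numbers depend on features the generator omits
  (correlated continental frequencies, LD, unbalanced group sizes),
  so synthetic results characterize the estimators, not any real
  cohort.
* VCF import requires GT fields and biallelic SNV records; dosage
  (DS-field) input is not supported.
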