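# Methods

This note records the models, estimators, numerical conventions and
deliberate design choices behind `sweepscan`, and what the simulation-based
validation does and does not demonstrate.

## Scan statistics

**Per-site F_ST.** The default estimator is the direct two-population
form `(pA − pB)² / (pA(1−pA) + pB(1−pB))`, with allele frequencies
computed over non-missing genotypes per population.  This expression is
not bounded by 1: at `pA = 0.9, pB = 0.1` it evaluates to 3.56.  We keep
the form for fidelity to common chip-study practice, clip at 1.0, and
report the clip count in the run log/manifest.  When both populations
are fixed for the same allele the statistic is undefined (excluded from
window means); a fixed difference is defined as 1, the limit of the
expression.  `--fst-estimator hudson` and `--fst-estimator wc`
(Weir–Cockerham, ratio-of-summed-components per window) are provided for
sensitivity analysis; the default window statistic is the unweighted
mean of defined per-site values, matching the per-site-then-window
convention rather than VCFtools' weighted variant.

**Nucleotide diversity.** Per site, `π = 1/(n(n−1)) Σ_{i<j} |g_i−g_j|/2`
over the population's called diploid dosages.  The normalization
`1/(n(n−1))` is half the conventional mean over `C(n,2)` pairs; it is
kept as-is because the downstream log2 ratio is invariant to any
constant factor common to both populations.  The genotype distance
`|g_i − g_j|/2 ∈ {0, ½, 1}` equals the expected allele mismatch when one
allele is drawn from each individual.  Window π sums per-site values and
divides by the window span in bp (truncated windows use their actual
span); sites with fewer than two called genotypes contribute nothing.

**Windows.** 50-kb windows advanced by 25 kb, starting at 0 on every
chromosome; a window is emitted iff its start lies inside the
chromosome, and its end is truncated to the chromosome length.  Window
F_ST is undefined below `min_snps = 3` defined sites — a guard against
single-SNP windows dominating the upper tail.

**The log2 diversity ratio and zero-diversity windows.** The ratio
`log2(π_A/π_B)` is the sweep-direction signal.  A complete sweep drives
the swept population's diversity to exactly zero over whole windows, so
we assign `+inf` when `π_A > 0, π_B = 0` and `−inf` in the mirror case,
treating total diversity loss as the most extreme possible value of the
tail it belongs to; the ratio is undefined (and the window excluded from
ranking) only when both diversities are zero.  Percentile thresholds are
computed over the finite values; infinite values always satisfy the
strict tail inequality.  Without this convention, windows carrying the
strongest possible sweep signal would be discarded by the ranking —
the opposite of the scan's purpose.

**Thresholds.** Genome-wide (not per-chromosome) empirical quantiles
with linear interpolation between order statistics; selection is strict
(`>` / `<`), so ties at the threshold are excluded and a degenerate
constant statistic selects nothing.  Defaults: top 5% of F_ST, upper and
lower 2.5% of the ratio.  Candidate windows are the intersections
(top-F_ST ∩ upper tail → selected in B; top-F_ST ∩ lower tail → selected
in A); overlapping or book-ended candidates of a direction merge into
maximal regions.

## Quality control

Filters run in the order missingness → MAF → HWE on the merged
two-population matrix, and a removed site is attributed to the first
filter that rejects it.  Thresholds are strict readings of their
definitions: missing rate exactly 0.10 and MAF exactly 0.05 are
retained.  MAF is frequency-based over non-missing genotypes (PLINK
semantics).  The HWE exact test conditions on the observed minor-allele
count and enumerates the heterozygote-count distribution
`P(k) ∝ n!/(n_AA! k! n_aa!) · 2^k` in log-space; the p-value sums all
outcomes no more probable than the observed one (plain exact, no mid-p —
the common chip-QC default).  Testing HWE on a merged two-population
sample conflates the Wahlund effect with genotyping error; a
`per_population` mode tests within each population and removes sites
failing in either.

A note on calibration: exact-test p-values are discrete and therefore
super-uniform ("conservative") — valid at every level, but their
empirical distribution deviates from the uniform by roughly the largest
single-outcome probability.  At 144 diploids this Kolmogorov–Smirnov
distance is ≈ 0.18 and would only fall below 0.05 near two thousand
samples (or with the mid-p transform, which we deliberately do not use
for filtering).  The validation suite therefore asserts validity
(`P(p ≤ α) ≤ α` plus sampling slack) rather than closeness to uniform.

## Population structure

**Relationship matrix and PCA.** Genotypes are standardized per
polymorphic site to `z = (g − 2p)/√(2p(1−p))`; missing entries
contribute zero after standardization (mean imputation); `R = ZZᵀ/m`.
PCA is the eigendecomposition of R; coordinates are eigenvectors scaled
by √λ, variance fractions are `λ_i / Σ max(λ_j, 0)`, and each
eigenvector's largest-magnitude entry is made positive so plots are
reproducible.

**Distances and the NJ tree.** The allele-sharing p-distance
`d(i,j) = mean |g_i − g_j|/2` over jointly called sites is computed via
genotype-class indicator matrix products so large cohorts stay inside
BLAS.  Neighbor joining follows Saitou–Nei exactly (join the pair
minimizing `Q(i,j) = (N−2)d(i,j) − r_i − r_j`, three-point branch
lengths); a negative branch length is clamped to zero with the deficit
moved to its sister so the joined pair's path length is preserved.  The
unrooted tree is serialized as newick with a trifurcating root and
17-significant-digit branch lengths, so additive matrices round-trip to
machine precision.

**Ancestry (NMF).** The scaled dosage matrix `X = G/2` is factorized as
`X ≈ QF` with row-stochastic Q (Euclidean simplex projection per row)
and `F ∈ [0,1]`, by alternating ridge-stabilized (λ = 1e-9) least
squares.  Missing entries never enter the loss: they are re-imputed with
the current reconstruction each sweep (an EM treatment).  If a
projection step ever increases the fit loss the previous iterate is
kept and iteration stops, so the logged loss trace is non-increasing by
construction.  Convergence: relative loss change ≤ 1e-6 or 500
iterations (the pipeline driver uses 1e-5/200 — ancestry proportions are
insensitive to the tail of the optimization at cohort scale).

**Choosing K.** Before fitting, 5% of the called entries are held out;
the model is scored by the mean binomial cross-entropy of those entries
under the clipped reconstruction.  The hold-out pattern is drawn from a
seed shared by every candidate K (initializations still differ), making
the comparison across K paired; with independent hold-outs per fit the
between-mask variance swamps the small cross-entropy differences between
adjacent K and model choice becomes unstable.  For each K the minimum
cross-entropy over `seeds_per_K` initializations is kept; the best K
minimizes the table.

## The simulator

The generator emulates a two-population chip study: ~60,000 biallelic
sites placed uniformly over five chicken-scale chromosomes (~300 Mb
total), ancestral frequencies uniform on `[maf_floor, 1 − maf_floor]`
(the floor, default 0.05, stands in for array ascertainment), and
per-population frequencies drawn independently from the Balding–Nichols
distribution `Beta(p(1−F)/F, (1−p)(1−F)/F)` at divergence `F`.
Genotypes are `Binomial(2, f)` draws (HWE) except at a configurable
fraction of sites where the heterozygote class is deflated by an
inbreeding-like factor (default 0.6); calls are erased i.i.d. at the
missing rate (default 0.02).  A sweep spec pulls the swept population's
in-interval frequencies toward the nearest fixation boundary by its
intensity (`f → f + intensity · (round(f) − f)`); intensity 1 yields
exact local monomorphism.  Everything is reproducible from one seed, and
the truth object records ancestral and per-population frequencies, sweep
intervals and the HWE-violating site indices.

What this does **not** model: linkage disequilibrium and haplotype
structure (the windowed frequency statistics do not need them, but
window-to-window correlation of real data is absent), genotyping error,
pedigree/F2 family structure, and sex chromosomes.  Passing recovery
tests on these simulations therefore demonstrates correctness of the
statistics and the selection logic under the stated frequency model —
not the field performance of the scan on a real breed comparison, where
LD, ascertainment and demography all broaden the nulls.

## Pipeline conventions

Stages run simulate/load → QC → structure → scan → annotate → enrich;
each randomized stage draws its seed from a named SHA-256 substream of
the single run seed, so adding a stage never perturbs another's draws,
and reruns are bit-identical (all writers emit deterministic output; the
manifest records SHA-256 checksums).  Ancestry inference runs on a
seeded random subsample of at most 20,000 post-QC sites by default (the
role LD pruning plays in real workflows); the GRM/PCA, tree and scan
always use every site.  When no annotation is supplied with a simulated
run, a deterministic synthetic gene grid (30-kb genes every 60 kb) and
seed-derived synthetic gene sets are generated so the annotation and
enrichment stages remain exercised end to end; both files are labelled
synthetic.  Internal coordinates are 0-based half-open everywhere;
VCF and GFF3 conversion happens only at the I/O boundary; half-calls
are treated as missing.

Enrichment is the upper-tail hypergeometric test of each user-supplied
gene set against the candidate gene list, with the annotation's gene
complement as the default universe and Benjamini–Hochberg FDR across
sets.  No ontology database is bundled: enriched-term identities depend
entirely on the supplied sets.

## Validation problem sizes

The test suite validates the statistics against brute-force oracles on
100 small random instances; the HWE test against exact rational
enumeration for all configurations with n ≤ 10; NJ against 50 random
additive 4–8-taxon matrices (path lengths to 1e-9); scan behavior on
60,000-site, 144+144-sample simulations (sweep recovery ≥ 80% of truth
windows with zero direction errors; null selection fractions within 0.5
percentage points of nominal); structure recovery on a 2,000-site,
50+50-sample simulation at F = 0.3; and whole-pipeline determinism on
the default 288 × 60,000 configuration.

## Known limitations

- The default F_ST form is a per-site ratio clipped at 1; for formal
  inference prefer the Hudson or Weir–Cockerham estimators.
- The NMF ancestry optimizer is a simplified alternating least-squares
  scheme, not the published sNMF algorithm; it preserves the contract
  (row-stochastic Q, held-out cross-entropy for K selection) but Q
  values near 0/1 are sharper than sNMF's regularized estimates.
- Percentile selection is outlier-driven by construction: it always
  selects ~5%/2.5% of windows under the null; the intersection step, not
  the marginal thresholds, provides the (empirical, not probabilistic)
  specificity.
- Multiallelic sites, BCF, and PLINK binary inputs are out of scope;
  convert to biallelic-SNP VCF first.
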