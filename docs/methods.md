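# Methods

## Model and estimation

The phenotype of individual *i* is modeled as the sum of a year-season fixed
effect, three genetic values and a residual:

    y = Xb + a + d + a_h + e,
    a = Wα α₀  (SNP additive),   d = Wδ δ₀  (SNP dominance),
    a_h = Wαh α₀h  (haplotype additive).

Codings (allele frequency p, q = 1 − p, computed once from the full
genotyped sample — relationship matrices in GBLUP cross-validation span
training and validation individuals):

* additive: genotype dosage minus 2p (AA/Aa/aa → 2−2p, 1−2p, −2p), so every
  column is sample-centered;
* dominance: AA/Aa/aa → −2q², 2pq, −2p²; centered and orthogonal to the
  additive column exactly when the sample sits at Hardy–Weinberg genotype
  proportions;
* haplotype: each block is a locus, each distinct phased allele sequence an
  allele *j* with frequency p_j; an individual's entry is (copies of j) −
  2p_j. Within a block the columns sum to zero for every individual (dosages
  sum to 2, centers sum to 2); the linear dependency is harmless for
  relationship-matrix construction and all columns are kept. Within-block
  allele order is descending frequency with lexicographic tie-break, for
  determinism.

With kₓ = tr(WₓWₓ′)/n, the relationship matrices A_g = WαWα′/kα,
D_g = WδWδ′/kδ and A_gh = WαhWαh′/kαh each have trace exactly n, making the
variance components phenotypic-scale and the heritabilities direct ratios.
The effect-level parameterization (effects with variance σ²/k) and the
scaled parameterization (T = W/√k, variance σ²) build identical phenotypic
covariances; the test suite asserts this to 1e-10.

REML maximizes the restricted likelihood of (σ²α, σ²δ, σ²αh, σ²e) with an
EM warm start (3 steps; monotone in the restricted log-likelihood, which is
asserted per step in tests) followed by average-information (Newton-type)
steps with step-halving, flooring negative components at 1e-8 of the
phenotypic variance. Convergence: maximum parameter change below `tol`
(default 1e-6) relative to var(y), or a likelihood stall below
0.01·tol·|logL| after the warm start (components pinned at the floor retain
a nonzero score indefinitely). Oracle-equivalence tests that rely on exact
REML stationarity use tol = 1e-15 on small instances. The generalized
inverse of X′V⁻¹X uses an eigenvalue threshold of 1e-10 times the largest
eigenvalue; fixed-effect levels unobserved in a training set are dropped
from the estimable set and reported.

Predictions use the conditional-expectation (CE) form at the individual
level, û_c = σ²_c K_c[all, train] P y with
P = V⁻¹ − V⁻¹X(X′V⁻¹X)⁻X′V⁻¹: with genome-wide haplotype allele counts far
exceeding n, the effect-level Henderson system is built only as a testing
oracle (`haploblup.mme`), where CE and MME solutions are asserted equal to
1e-8 for predictions, effect BLUPs, reliabilities and per-unit heritability
shares. The reliability of a total genetic value is the variance-ratio form
R²_i = [G Z′PZ G]_ii / [diag G]_ii with G the summed genetic covariance of
the included components (all cross terms); tiny negative radicands beyond
−1e-10 raise, smaller ones clip to zero.

Per-unit heritability shares partition each component heritability by
squared effect: ĥ²_ci = (ê²_i / Σ_j ê²_j) ĥ²_c, with a block's squared
effect being the sum over its allele effects. Shares are non-negative and
sum exactly to the component heritability (asserted to 1e-12). The
MME-based variance split σ̂²_ci = û²_i/[m − tr(C^cc)λ_c] coincides with the
GREML component only at an interior REML stationary point, which is why the
dual-path test requires interior optima; at the σ²→0 boundary,
λ·tr(C^cc) → m and the split degenerates while all effects vanish.

## Cross-validation

Individuals are randomly partitioned into K folds (default fold sizes
differ by at most one; explicit size lists reproduce unbalanced layouts
such as nine folds of 320 plus one of 315). Relationship matrices are built
once on all individuals; within each fold only the validation phenotypes
are masked, variance components and BLUE fixed effects are re-estimated on
the training set, and three accuracies are reported: the observed Pearson
correlation between masked predictions and phenotypes (original, and
corrected by subtracting the training-fold fixed-effect estimates —
validation individuals whose year-season level is absent from training are
excluded from the corrected accuracy only), the mean reliability-based
theoretical accuracy R₀ⱼ, and R₀ⱼₚ = mean over folds of R₀ⱼₖ·√(ĥ²_gk).
Folds with undefined correlations are excluded with a warning, never
zero-filled. One fold plan (per seed) is reused across models for
comparability. The masking contract — perturbing a validation phenotype
never changes that individual's prediction — is asserted directly.

## Blocks

Fixed-distance blocks tile each chromosome from position 0; the trailing
partial window is kept when it has ≥ 2 SNPs; fixed blocks never overlap.
Gene-based blocks take each annotated gene interval: genes shorter than
50 kb are extended by 100 kb at each end (clipped at chromosome bounds);
genes longer than 500 kb are split into ⌈L/500 kb⌉ equal-length pieces
(which land in 200–500 kb whenever possible — "split into equal pieces" is
this package's deterministic reading of a range-valued rule). Gene blocks
may overlap; overlaps are removed only when reporting genome coverage.
Blocks with fewer than 2 SNPs are dropped everywhere. Coordinates are
0-based half-open internally and 1-based inclusive at the GFF3 boundary.

## QC

Phenotype outliers beyond k·SD (default 4; SD with ddof = 1) of the mean
are removed in a single pass — mean and SD are never recomputed after
removal. SNPs are kept when minor allele frequency ≥ 5% and the
Hardy–Weinberg Pearson chi-square (1 df, no continuity correction — at
n ≈ 3000 the asymptotic test is standard) has p > 1e-5, with frequencies
from all genotyped individuals. Thinning selects one SNP per window of 20
consecutive SNPs: the first window takes the SNP nearest its positional
midpoint, each later window the SNP nearest (previous selection + target
spacing) with target spacing = chromosome span / number of complete
windows, ties to the lower index — a concrete, deterministic reading of
"approximately equally spaced", which no formula in the source pipeline
pins down.

## Synthetic data

The generator emulates the *structure* of a single-breed nucleus pig
population, not any particular real dataset (the original data are
private). Haplotypes are mosaics of a founder pool (default 20 founder
haplotypes): each of the 2n population haplotypes copies a founder and
switches templates between adjacent SNPs with probability
1 − exp(−rate·distance), rate 1e-6/bp by default. This yields LD that
decays with distance — the decay ceiling is set by the founder-pool LD
(≈ 1/n_founders in expected r²), so a literally zero switch rate gives
*flat* LD, and the LD-decay property is tested at the default rate — and
few distinct haplotypes per block, matching the regime where haplotype
models are sensible. Founder allele frequencies are drawn inside
[0.05, 0.95] and founder columns are resampled until the realized
population MAF respects the 0.05 floor exactly.

Gene lengths follow a min-shifted exponential (minimum 600 bp, scale 33 kb,
resampled above 1638 kb), putting ≈ 78% of genes under 50 kb, the
preponderance of short genes typical of mammalian annotations and the
regime the extension rule targets.

Phenotypes are assembled exactly from the generative form of the model:
causal SNPs (default: all) receive standard-normal additive and dominance
effects, causal blocks (default: all) one standard-normal effect per
distinct haplotype allele — within-block interaction that SNP additive
coding cannot represent, so positive epistasis heritability is generable —
and each component plus the residual is rescaled so its realized population
variance equals its configured fraction exactly, with total phenotypic
(genetic + residual) variance 1. The fractions are therefore realized
heritabilities, and the default (0.30, 0.05, 0.10, 0.55) defines the
parameter-recovery study conditions at n = 500. Year-season labels are
uniform over 4 levels; fixed-effect values are N(0, 0.5²) unless given.
All randomness derives from one seed via per-operation substreams, so the
full simulation is bit-reproducible.

What the generator does **not** emulate: pedigree/family structure beyond
founder sharing, selection, imputation or phasing error, variable LD along
the genome, minor-allele-frequency spectra from mutation-drift balance, and
non-Gaussian trait distributions. Passing tests therefore certify the
estimation machinery under a correctly specified model, not robustness to
real-data artifacts.

## Problem sizes in the test and acceptance runs

Unit tests run at n = 100 (120 SNPs, one 5-Mb chromosome); the recovery and
null checks at n = 500 (300 SNPs on two 10-Mb chromosomes, 40 blocks of
500 kb) with 20 replicates for recovery; oracle equivalence on 24 instances
of n = 12, m ≤ 60. These sizes were chosen so each suite certifies its
property with comfortable statistical margins while the whole run stays in
the minutes range on one CPU. The acceptance script uses 20 recovery
replicates at n = 500.

## Known limitations

* GREML is dense O(n³) per iteration; the intended scale is a few thousand
  individuals and ≲ 50k SNPs, matching the CE-method argument.
* SNP-additive and haplotype relationship matrices are strongly correlated,
  so single-replicate component estimates in joint models wander (their sum
  is stable); component-level conclusions need replicates.
* Dominance variance near zero is floored, which slightly biases small
  dominance heritabilities upward in expectation.
* ĥ²_E is a difference of estimates and may legitimately be negative; it is
  never clipped.
* The published reference values bundled for the arithmetic checks are
  printed to 3 decimals; recomputed ratios can differ from printed ones by
  one unit in the last digit.
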