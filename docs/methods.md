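# Methods

## Scope and model of the data

The package analyses a fruit-volatile survey of a clonally propagated
perennial crop. Each of ~150 trees is phenotyped by headspace GC-MS in three
technical replicates for ~80 volatile compounds; a subset of varieties is
present as vegetative clones (genetically identical trees, typically one per
farm), and all samples carry genome-wide biallelic SNP genotypes. Three
scientific questions drive the design: is there technical structure to
remove (replicate QC), how is volatile variation organised (PCA, correlation
network), and how much of it is genetic (clone-based randomization test and
broad-sense heritability)?

## Semi-quantification and replicate QC

Concentrations are internal-standard equivalents,
`m_i = (K_i/K_IS)·(A_i/A_IS)·(m_IS/m_p)·100` in µg per 100 g of dried fruit
powder, with the response-factor ratio fixed at 1 — values are comparable
across samples for one volatile, but not rigorous absolute quantities.
Kovats retention indices use the linear temperature-programmed convention
on a C8–C20 alkane ladder; no extrapolation outside the ladder.

Replicate QC is two-staged, keyed on the coefficient of variation across
the three technical replicates of one (sample, volatile):

1. **Single-deviant rule.** If CV > 50%, deviations of the minimum and
   maximum replicate from the median are computed as |x − median|/median.
   If exactly one of them exceeds 55% while the other is below 35%, the
   larger-deviation replicate is excluded. The band [35%, 55%] is
   deliberately left unresolved.
2. **Run arbitration.** For each sample with unresolved triplets, the run
   farthest from the median is tallied over all that sample's CV > 50%
   volatiles; a *strict majority* for one run index excludes that run from
   the unresolved triplets ("one consistently bad injection"). Without a
   strict majority everything is retained.

Numerical conventions: CV uses the sample standard deviation (n − 1); the
deviation thresholds are strict inequalities; the median of three values is
the middle order statistic; fewer than three observed replicates are kept
unconditionally (CV undefined); a triplet whose mean is zero is kept (all
zeros carry no evidence of a deviant). At most one replicate is ever
excluded per cell and decisions are invariant to replicate order. Kept
replicates are averaged arithmetically; the missing-cell fraction is
reported from the actual grid dimensions.

## Transforms and PCA

Per volatile, in order: (i) impute missing cells with the column median of
observed values; (ii) if zeros remain, add the column's minimum non-zero
value (so the log is defined while preserving ranks); (iii) natural log —
the base is irrelevant to every downstream quantity used here (Z-scores,
ranks, correlations); (iv) Z-score with the sample SD. Clamping to [−3, 3]
is applied to clustering/heatmap inputs only, never before PCA, since it
would distort the eigenstructure. A constant column is an error naming the
volatile. The applied shift/mean/SD are recorded so transforms can be
replayed on new data.

PCA is computed by SVD of the column-centred matrix (numerically equivalent
to the eigendecomposition of its covariance, which after Z-scoring is the
correlation matrix). Component signs are fixed by making each component's
largest-magnitude loading positive; min(n − 1, p) components are retained
and variance fractions sum to 1 over them. Extreme-loading selection takes
the k = 15 largest |loading| per chosen axis (union over axes), ties broken
by larger |loading| then lexicographic id.

## Kinship and clone detection

Kinship is the allele-frequency-weighted method-of-moments estimator
`φ(i,j) = Σ_m (g_im − 2p̂_m)(g_jm − 2p̂_m) / (2 Σ_m 2p̂_m(1 − p̂_m))` over
SNPs non-missing in both samples, with p̂ the sample alternate-allele
frequency and monomorphic SNPs excluded. Expectation is 0.5 for clones and
0 for unrelated pairs. Because p̂ is estimated from the same panel, the
clone value is attenuated by O(1/n) — ≈ 0.476 at n = 51, ≈ 0.494 at
n = 201 — far inside the default clone window. A likelihood-based
relatedness model would remove this bias but is unnecessary for clone
detection, the only use in scope.

Clone groups are connected components over pairs with φ in a configurable
window, default [0.4, 0.6] around the clonal expectation ("approximately
0.5" is not a sharp number). Groups of size ≥ 2 are returned; a triple
contributes all three member pairs when pair lists are requested
(`CloneSet.pairs(decompose=True)`), and callers may supply their own pair
lists (e.g. same-name pairs only).

## Clonal randomization test

Observed statistic: mean Euclidean distance between clone-pair profiles on
the log/Z-transformed (clamped) matrix — the same scale as the clustering
analyses, since distances on raw concentrations would be dominated by the
most abundant volatiles. Each of the 10,000 null replicates draws n
pseudo-pairs; by default the 2n samples are distinct (mirroring the
disjointness of real clone pairs; `disjoint=False` draws pairs
independently). The P-value is the proportion of null replicates whose mean
is *strictly less* than the observed mean, with no +1 correction — so P = 0
is a possible and meaningful outcome ("no random pairing was as close").
Under the null the P-value is uniform up to the 1/n_replicates
discreteness; the type-I error at α = 0.05 is verified at 0.05 ± 0.02 over
500 null panels in the acceptance suite.

## Broad-sense heritability

For volatile v and clone pairs with both members observed, a one-way ANOVA
with clone group as factor and k = 2 replicates per group gives MSB
(between) and MSW (within), and `H² = (MSB − MSW)/(MSB + MSW)` — the k = 2
intraclass correlation. The estimator is bounded above by 1 and can be
negative (MSW > MSB), which is reported as computed: on null data negative
estimates are the expected behaviour of the sampling distribution, not an
error. Volatiles with fewer than two usable pairs or zero total variance
are flagged rather than estimated. Two H² tables (e.g. same-name pairs vs
all pairs) are compared by Spearman correlation with an absolute-difference
outlier flag. Parameter recovery (mean within ±0.05 of planted H² ∈
{0.2, 0.5, 0.8} over 200 panels of 200 pairs) is part of the acceptance
suite; with only ~16 pairs, as in a real survey, individual estimates are
noisy and their ranking is more meaningful than their values.

## Correlation network and clustering

Spearman correlations use average ranks (tie-corrected), with two-sided
p-values from the t approximation on n − 2 degrees of freedom — adequate at
n ≈ 148. On matrices with missing cells each pair uses its
pairwise-complete observations; pairs with fewer than `min_pairs`
(default 10) complete rows, or a constant margin, are untestable and
excluded from the Bonferroni family size m (significance threshold α/m,
significant pairs partitioned by sign of ρ).

Volatile clustering is agglomerative on distance 1 − ρ; the linkage method
is a flag, default *average* (a deliberately open choice: published
metabolomics workflows rarely state it, and no option is canonical). Node support is the plain bootstrap probability
(BP): the percentage of `n_boot` (default 1,000) sample-resampled trees
containing the node's exact leaf set. The multiscale "approximately
unbiased" correction is out of scope; BP is known to be conservative for
large clades, so supports here are not comparable to AU p-values. A column
rendered constant by resampling contributes ρ = 0 (distance 1) in that
replicate. The root's support is 100 by construction. Trees are exported as
Newick with support as internal-node labels.

Trait scans (moisture, sugars, color vs volatiles or PC scores) use the same
Spearman machinery with one Bonferroni family over all tested (trait,
target) pairs; categorical traits are rank-transformed via category codes
and flagged, since a linear code ordering is an assumption the caller
should see.

## Synthetic data: what it emulates and what it does not

The generator states a world mirroring the survey: 148 samples from 130
genotypes (16 clone pairs + 1 triple = 35 clonal samples), 80 volatiles,
two farms. Log-concentration is additive,
`log c = baseline_v + G_{variety,v} + farm_s + E_{s,v}`, with clone-mates
sharing G, so concentrations are lognormal and the planted broad-sense
heritability `H² = σ²_G/(σ²_G + σ²_E)` holds exactly on the log scale.
Defaults: baselines Uniform(log 1, log 400) µg/100 g; H² Uniform(0.05,
0.85) (spanning the plausible range for fruit volatiles); total log-scale
variance 0.64 (SD 0.8, a typical sample-to-sample spread for volatile
traits); farm effect 0 by default — the real design spans two farms but
fits no farm model, so the variance split between farm and residual
environment is exposed as a knob (`farm_effect_sd`), not asserted.

Technical replicates multiply the expected concentration by lognormal noise
with CV 15% (mean 1, so replicate averages are unbiased); with probability
2% a sample has one aberrant run scaled by a factor Uniform(3, 6) — the
failure mode the QC's run arbitration targets. Missingness is planted at
the (sample, volatile) level (a compound undetected in a sample loses all
three runs) at rate 3%, so both the replicate table and the assembled
matrix carry ~3% missing cells; independent per-replicate dropout would
almost never yield a missing matrix cell and does not match how
non-detection arises. Genotypes are Hardy–Weinberg with allele frequencies
Uniform(0.05, 0.5), one founder vector per variety (clone-mates identical),
optional per-call error re-drawn from Hardy–Weinberg. Covariate traits load
on a latent factor (the panel-wide mean log concentration, or a named
volatile) with Gaussian noise; sucrose is constructed as total sugars minus
glucose minus fructose so its negative correlation with invert sugars is
structural.

Not emulated: linkage disequilibrium, population structure beyond clones,
inter-volatile correlation beyond the shared farm/latent factors,
biochemical pathway structure, retention-time drift, batch effects, or
fruit developmental stage. A green test on synthetic data therefore
establishes that the estimators recover what was planted under the stated
noise model — not that the biological conclusions of any particular survey
are correct.

## Determinism and numerical conventions

Every stochastic operation takes an explicit seed and uses its own
`numpy.random.Generator`; the pipeline derives per-stage seeds from the
config seed via `SeedSequence`, and two runs with the same config produce
byte-identical artifacts. Degenerate inputs fail loudly and early: empty
panels, non-positive internal-standard areas or powder masses, negative
peak areas, constant columns at the Z-score step, missing values where a
complete matrix is required, no polymorphic SNPs, too few clone pairs.

## Known limitations

- The kinship estimator's O(1/n) attenuation (above) makes it unsuitable
  for precise relatedness beyond clone detection.
- H² from ~16 clone pairs has large sampling variance; negative estimates
  are expected and should be interpreted as "indistinguishable from zero".
- Bootstrap BP support is conservative relative to AU p-values; thresholds
  tuned for pvclust-style AU values do not transfer.
- The t approximation for Spearman p-values degrades below n ≈ 10; an
  exact permutation alternative is not currently wired into the matrix
  scan (pairs below `min_pairs` are simply not tested).
- Semi-quantification with a fixed response ratio supports relative
  comparisons per volatile only; totals across volatiles are not
  meaningful.
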