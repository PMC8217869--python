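# Methods

This note documents the models implemented in `assemblage`, the choices made
where conventions diverge in the literature, and what the synthetic-data
experiments do and do not demonstrate.

## Count tables and rarefaction

The universal input is a taxa × samples matrix of non-negative integer read
counts with unique, case-sensitive, whitespace-trimmed IDs.  Rarefaction
draws a single multivariate-hypergeometric subsample of `depth` reads per
sample (without replacement), with the seed a required, logged parameter.
Averaging over repeated draws is deliberately not done: a normalized survey
is one realization, and downstream permutation machinery supplies the
uncertainty.  Samples below depth are dropped with a warning by default
(raising instead is available), mirroring the practice of setting the depth
at the smallest library worth keeping.  The expectation of a rarefied count
is `count * depth / total`, which the test suite verifies over 1,000 draws.

## Alpha diversity

Shannon `H' = -Σ p ln p` uses natural logarithms; Pielou's evenness divides
by `ln S_obs` and is reported as 0 (with a warning) for single-taxon
samples.  Chao1 is the bias-corrected form `S_obs + F1(F1-1)/(2(F2+1))`,
defined also when no doubletons exist.  ACE uses the standard rare/abundant
threshold of 10 reads (configurable) and falls back to Chao1 with a warning
when every rare taxon is a singleton (coverage undefined).  Both estimators
are delegated to scikit-bio and cross-checked against direct formula
evaluation in the tests.  Per-category summaries report mean ± standard
error by default; a flag switches to standard deviation, since published
tables often leave the "±" unlabelled.

## Group tests

PERMANOVA is the one-way partition of squared Bray–Curtis dissimilarities:
`SS_T = Σ_{i<j} d²/N`, `SS_W = Σ_g Σ_{i<j∈g} d²/n_g`,
`F = (SS_A/(a-1))/(SS_W/(N-a))`, `R² = SS_A/SS_T`.  ANOSIM midranks all
off-diagonal dissimilarities and scales the between/within mean-rank
difference by `M/2`.  Both use label permutations with the
`(1 + #{T_perm ≥ T_obs})/(n_perm + 1)` convention, so p is never zero and
ties (e.g. permutations that reproduce the observed partition) count as
extreme.  Statistics are cross-checked against scikit-bio's implementations;
p-value calibration is verified by simulation (type-I error within
[0.03, 0.07] at α = 0.05).  Only single-factor designs are supported —
multi-factor and nested designs are out of scope.

## Niche breadth classification

Levins' breadth `B_j = 1/Σ_h p_jh²` uses individual samples as resource
states (a flag pools to categories).  The null model must preserve each
taxon's total abundance, each sample's depth, *and* the overall table
sparsity, otherwise rare taxa are trivially called specialists; quasiswap
achieves exactly that: a Patefield draw (sequential multivariate-
hypergeometric tables with the observed margins) followed by 2×2 swap
updates, accepted when they move the number of non-zero cells toward the
observed fill (neutral moves are accepted for mixing), until fill matches.
The iteration budget is 50,000 × fill; exhausting it raises an error
reporting the residual gap.  The swap loop is a numba kernel seeded per
draw.

The 95% null envelope uses order statistics (`method="lower"`/`"higher"`)
rather than interpolated percentiles: for the discrete null distributions of
B this guarantees that at most 5% of null draws fall outside their own
envelope, making the classification conservative under exchangeability (a
property the tests verify by classifying a quasiswap draw against its own
ensemble).

**Known limitation.**  The quasiswap ensemble is (approximately) uniform
over fixed-margin, fixed-fill tables, whereas multinomial read sampling
weights tables by multinomial coefficients that favour even rows.  On a
well-mixed multinomial community the observed B of mid-abundance taxa
therefore tends to sit slightly *above* the null envelope, yielding ~8–10%
spurious generalist calls (we verified identical behaviour in the reference
R implementation of quasiswap on the same tables).  Planted generalists and
specialists are nevertheless recovered with sensitivity 1.0 in the test
conditions; interpret small generalist sets near the envelope with caution.

## Modified stochasticity ratio

For each within-category pair, the observed Bray–Curtis dissimilarity `D` is
compared with its expectation `E` under a stochastic-assembly null:

    MST = D / E                  if D ≤ E
    MST = (1 − D) / (1 − E)      if D > E

MST equals 1 when the observation coincides with the null expectation and
declines toward 0 as pairs become more similar (convergent selection) or
more dissimilar (divergent selection) than chance.  Pairs with degenerate
`E ∈ {0, 1}` are excluded with a flag.  The default null redraws each
sample's taxon set at observed richness, with selection probability
proportional to regional occurrence frequency, then refills the sample's
depth multinomially in proportion to regional mean relative abundance; every
drawn taxon receives at least one read so the richness constraint is exact.
The regional pool is the sample's category (a global pool is available), the
randomization count defaults to 1,000, and a fixed-fixed (quasiswap)
alternative is pluggable.  Category means below 0.5 are called
deterministic-dominated, above 0.5 stochastic-dominated.

Because `D` fluctuates around `E` with non-vanishing relative spread, the
min-ratio form averages noticeably below 1 (≈0.7–0.8) even for data drawn
from the null itself; the regime boundary at 0.5, not the value 1, is the
meaningful reference.  Note also that strongly immigration-coupled neutral
communities (m near 1) hug the metacommunity and can score below the null
expectation; the MST statistic measures departure from its null model, not
neutrality per se.

## Sloan neutral community model

A local community of `N` individuals receives immigrants from a
metacommunity in which taxon `i` has relative abundance `p_i`; at
stationarity the taxon's local relative abundance follows
`Beta(Nmp_i, Nm(1-p_i))`, with `m` the immigration rate.  We estimate `p_i`
as the mean of per-sample relative abundances (pooled counts optional),
`N` as the mean library depth, and the occurrence frequency `f_i` as the
fraction of samples with ≥1 read.

Because presence is defined by reads, the default prediction integrates the
read-sampling layer exactly:

    f̂(p; m) = 1 − E_Beta[(1 − q)^N] = 1 − B(a, b+N)/B(a, b),
    a = Nmp,  b = Nm(1−p),

evaluated via log-gamma functions.  The classic threshold form
`1 − BetaCDF(1/N; a, b)` is available as `detection="threshold"`; on
communities simulated from the model itself it overestimates `m` by roughly
a quarter (it treats sub-threshold taxa as undetectable, while per-read
sampling detects them stochastically), which is why the exact kernel is the
default.  The comparison models use the same zero-read convention:
binomial `1 − (1−p)^N` and Poisson `1 − e^{−Np}`, each with its own R².
The neutral verdict requires `R² > 0` and `R² ≥ R²_pois`; otherwise random
sampling of the source pool explains occupancy at least as well and
neutrality is rejected.

`m` is fitted by bounded least squares on (10⁻⁶, 1] with multistart at
{0.01, 0.1, 0.5}; a fit pinned at a bound is flagged.  The bootstrap
resamples taxa (the regression units) with replacement — 1,000 replicates by
default — giving the percentile CI of `m` and a pointwise band of
predictions (`boot_lower`/`boot_upper`).  The above/within/below taxon
partition instead uses the exact `Binomial(n_samples, f̂)` central 95%
quantiles: this is the distribution of an occupancy estimated from
`n_samples` libraries when the model holds, it is discreteness-aware (a
saturated taxon with `f = 1` and `f̂ ≈ 1` stays within), and on neutral
simulations ≥95% of taxa fall within it.  The bootstrap band, by contrast,
only reflects uncertainty in `m` and shrinks toward zero width with many
taxa, which makes it unsuitable for partitioning.

## Phylogenetic signal

Blomberg's K compares the observed ratio of non-phylogenetic to
phylogenetically corrected mean squared error with its Brownian-motion
expectation on the tree:

    K = [MSE₀/MSE] / [(tr(V) − n/(1ᵀV⁻¹1)) / (n−1)],

with `V` the shared-branch-length covariance matrix, `â` the GLS root state,
`MSE₀ = (x−â)ᵀ(x−â)/(n−1)` and `MSE = (x−â)ᵀV⁻¹(x−â)/(n−1)`.  Significance
comes from permuting trait values across tips; lower MSE than the
permutations indicates signal, `p = (1 + #{MSE_perm ≤ MSE_obs})/(n_perm+1)`.
Under Brownian simulation the mean K centres on 1 (verified to within
3 Monte-Carlo standard errors over 1,000 simulations on a 16-tip tree).

Replicate samples of one host species attach as zero-length polytomy tips;
zero terminal branches are perturbed by 10⁻⁸ of tree height for
invertibility.  Two regimes are worth knowing: replicates carrying *exactly*
the species value produce K > 1 (stronger-than-Brownian similarity), while
even 1% within-species noise on near-zero branches inflates `MSE` by orders
of magnitude and collapses K to ~10⁻⁴ — yet the permutation test still
detects the clustering decisively.  Very small K with very small p on
replicated designs is therefore expected behaviour, not a contradiction.

## Biomarker screen

Lineage features are per-rank sums of OTU counts, each sample normalized to
10⁶ per rank level.  Stage one keeps features with Kruskal–Wallis p ≤ 0.05
(midranks, tie-corrected; constant features get p = 1).  Stage two, over 30
bootstrap subsamples of ⅔ of each class (≥3 samples per class required),
fits a ridge-regularized Fisher discriminant (ε = 10⁻⁶ on the pooled
within-class covariance of standardized features) for the feature's
enriched class (argmax of class means) versus the rest, and scores each
feature as

    effect = ½ (|Δ class means| + |w̃| · |Δ class means|),

with `w̃` the absolute discriminant loading scaled to max 1, both terms on
the per-million scale; the reported score is log₁₀ of the bootstrap-mean
effect, thresholded at 2.0 (a stricter display cutoff such as 4.5 can be
applied downstream).  This is a deliberate simplification of the original
tool's internal arithmetic — equivalence is claimed only at the level of
recovering planted enrichments, never score-for-score.

## Synthetic communities

The generator is the source of ground truth for everything above.
A metacommunity of `S` taxa takes lognormal relative abundances
(σ = 2 by default, the classic long-tailed rank-abundance shape).  Defaults
mirror a scaled-down rarefied amplicon survey: 5 categories × 5 replicates
and 1,000 reads per sample for 500 taxa — about 2 reads per taxon per
sample, the same order as the motivating survey's rarefied tables (1.8 for
16S, 0.5 for ITS, 0.2 for 18S).

- **Neutral regime**: each sample's composition is drawn from
  `Dirichlet(N·m·p)` — marginally exactly the Sloan stationary Beta while
  summing to 1 — then reads are multinomial.  Equivalently, counts are
  Beta-binomial: the stationary law of the discrete neutral process observed
  through sequencing.
- **Niche regime**: per-category selection factors
  `w_c,i ~ LogNormal(0, σ_sel²)` are drawn once per category, compositions
  are `p·w_c` renormalized, reads multinomial.  Replicates within a category
  share `w_c`, so determinism means reproducible category signatures;
  `σ_sel = 0` reduces exactly to multinomial sampling.
- **Mixed regime** blends the two compositions convexly
  (`mix_weight` 1 → neutral); downstream MST rises monotonically along the
  sweep.
- **Planting** overwrites chosen rows: generalists get a near-exactly
  uniform redistribution of their total, specialists a multinomial
  redistribution confined to one category.  Row totals are preserved.
  Targets are drawn from taxa with total ≥ 2 reads/sample on average so
  every planted taxon is classifiable.  Planting scenarios use the
  `σ_sel = 0` (well-mixed multinomial) background so that the only
  deviation from exchangeability is the planted structure.
- **Host trees** are random ultrametric coalescent-style trees; Brownian
  traits come from `MVN(0, σ²V)`; replicates add 1% relative noise;
  `shuffled` mode permutes species values to destroy signal (type-I
  calibration must use unreplicated trees, since replicate clustering is
  itself signal).

What the generator does *not* emulate: sequencing error, chimeras, OTU
clustering artifacts, compositional bias between taxa, spatial or temporal
autocorrelation, and interactions among taxa.  Passing tests show that the
inference stages recover the processes the generator encodes at realistic
depth-to-richness ratios — not that real sponge data satisfy those process
assumptions.

## Pipeline and reproducibility

Every stochastic stage derives its child seed as
`crc32("{master}:{stage}") mod 2³¹`, so adding stages never perturbs earlier
randomness and identical configs produce byte-identical output bundles
(hash-verified in the tests).  The provenance manifest records parameters,
child seeds and SHA-256 hashes of every output; stage failures are isolated
and recorded without aborting independent stages.  Problem sizes used in the
shipped experiments (500 taxa, 25 samples, 200–1,000 randomizations,
10-seed replications) were chosen as the smallest at which the asymptotic
behaviour of each statistic is clearly visible.
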