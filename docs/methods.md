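# Methods

This note documents the statistical procedures, their assumptions, the
defaults of the synthetic-data generator, and the numerical and design
choices made where more than one construction was defensible. Group "A" is
always the focal habitat (PMA, pit-mud-associated); group "B" the
background (NPMA).

## Statistical kernel

**Mann-Whitney U.** U counts pairs (x_i, y_j) with x_i > y_j (ties count
½). With both groups ≤ 8 observations and no ties in the pooled sample,
the p-value is exact by full enumeration of the C(n+m, n) label
assignments; otherwise the normal approximation with tie correction and a
0.5 continuity correction is used. The switch point never matters for the
pipeline's group sizes (30 vs 100); exactness is retained so the
enumeration oracle in the test suite has something sharp to check.

**Fisher's exact test.** The statistic is the sample odds ratio ad/bc (∞
when bc = 0 and ad > 0). The two-sided p uses the probability-mass rule:
the sum of hypergeometric probabilities of all tables no more probable
than the observed one (with a 1 + 1e−7 relative tolerance against float
ties, matching common practice).

**Benjamini-Hochberg.** Step-up FDR adjustment (via statsmodels), applied
within each analysis family (one namespace, one scan) and never pooled
across analyses. Note that BH is *not* idempotent — re-applying it to
adjusted values can only increase them — so the test suite checks
monotonicity properties rather than a fixed point.

**Poisson group test.** Whether k_A of n_A versus k_B of n_B genomes carry
a feature is compared by an observed-vs-expected construction: each
group's expected count is the *other* group's rate times its own size
(λ_A = (k_B/n_B)·n_A and vice versa); for each group the one-sided
inclusive exact Poisson tail is taken (upper if observed ≥ expected, lower
otherwise) and the smaller of the two tails is reported, with direction =
the higher-rate group. This construction is symmetric under group swap and
reproduces every printed significance bound derivable from the study's
percentages. The source names only "the Poisson distribution (ppois R
function)"; whether the original analysis was one- or two-directional, and
which group supplied the expectation, is not stated — this symmetric
minimum-tail reading is a documented choice, not a reconstruction of the
authors' code. λ = 0 is handled as p = 1 if k = 0, else p = 0.

## Phylogenetic methods

**Distances and covariance.** Patristic distances are tip-to-tip
branch-length sums (via dendropy). The Brownian trait covariance C has
C[i,j] = shared root-to-MRCA path length; the identity
C[i,i] + C[j,j] − 2C[i,j] = d(i,j) is enforced as a property test.

**Matched-control selection.** `repeats` uniform subsets of the background
pool are drawn; for each, the mean patristic distance from all focal
genomes to the subset is computed; the subset minimizing the absolute
deviation from the across-draw mean is returned (earliest draw on ties).
The deviation target is read as the across-repeats mean of between-group
distances; an alternative reading — matching the focal group's
within-group mean distance — exists but is not implemented.

**Phylogenetic PCA.** Traits are centred at the GLS mean
a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X and the evolutionary covariance
S = (X−1a)ᵀC⁻¹(X−1a)/(n−1) is eigendecomposed; scores project the centred
(not whitened) data on the eigenvectors, so on a star phylogeny the result
equals ordinary covariance PCA exactly.

**Phylogenetic logistic regression.** The binary habitat y is regressed on
a standardized covariate by quasi-likelihood estimating equations
Xᵀ A^{1/2} R(α)⁻¹ A^{−1/2}(y − μ) = 0 with A = diag(μ(1−μ)). The working
correlation is the observed-scale correlation implied by a latent
threshold model whose latent trait is Brownian on the tree:
R(α) = (2/π)·arcsin(α·R₀), with R₀ the Brownian correlation matrix. The
signal weight α ∈ [0,1] is chosen on a 21-point grid by Gaussian
pseudo-likelihood of the Pearson residuals, alternating with the IRLS fit
(at most 4 outer rounds; ridge 1e−6 on R). Wald p-values use the
model-based covariance (XᵀA^{1/2}R⁻¹A^{1/2}X)⁻¹. Properties:

- star phylogeny ⇒ R(α) = I ⇒ exactly ordinary logistic regression;
- a no-signal y drives α̂ → 0 (measured mean α̂ ≈ 0.03 under an i.i.d.
  null), a threshold-Brownian y drives α̂ → 1 (measured mean ≈ 0.93);
- measured type-I error at nominal 0.05 on the confounded null
  (independent Brownian x and thresholded-Brownian y, 60-tip birth-death
  trees) is ≈ 0.067 — within the 0.05 ± 0.03 acceptance band, where
  ordinary logistic regression rejects at ≈ 0.39.

On failure of the phylogeny-weighted solve the function falls back to
ordinary logistic regression and reports `converged=False`. Under strong
separation the Wald p is unreliable (as in any logistic regression).

**Max-contrasting-pairs test.** The maximum number of edge-disjoint tip
pairs differing in both genotype and phenotype is found by a postorder
dynamic program over (carry state, pair count) with min/max-plus
convolutions; each subtree can export at most one unmatched tip because
its root edge has unit capacity. Among all maximum pairings the DP tracks
the minimum ("worst") and maximum ("best") number of *supporting* pairs
(the genotype-positive tip is also phenotype-positive). Scoring: p_best is
the one-sided binomial tail of the most favorable achievable pairing;
p_worst is the one-sided tail of the *least* favorable pairing per
direction, minimized over the two directions — it is small only when every
maximum pairing shows a directional excess. An earlier two-sided scoring of
the raw minimum count was rejected because the minimum supporting count is
biased toward zero under label shuffles, making its two-sided p small under
the null and collapsing the power of the downstream permutation filter.

**Label permutation test.** Phenotype labels are shuffled uniformly; the
statistic is the worst-case directional pairwise p evaluated in the
direction the observed data favor (anti-directional extremes among
permutations do not count as hits); the empirical p uses the +1
correction. An `early_stop` option ends the loop once significance is
unreachable; the returned conservative estimate still decides
"significant at the threshold" identically.

**Stringent pan-GWAS.** A KO is called habitat-associated only if (i) the
BH-adjusted Fisher p on presence × habitat is < 0.05, (ii) the worst-case
pairwise p is < 0.05, and (iii) the label-permutation empirical p is
< 0.05 (defaults; all configurable, with n_perm = 1000 by default). The
permutation test runs only for KOs passing the first two filters — the
enriched calls are identical, only the cost differs. Direction comes from
the odds ratio.

## Pangenome and pathway procedures

**Rarefaction.** For each g and group, `repeats` (default 100; the source
does not state its replicate count) uniform without-replacement samples;
pan = families present in ≥ 1 sampled genome, core = present in all
(strict 100% presence, no soft-core threshold). Two-sided Mann-Whitney
between groups per g on both distributions, raw and BH-adjusted.

**Core profiles and the fold+rank rule.** Core-genome COG abundances are
copy-weighted per genome (copies in core families annotated to the
category over total copies in annotated core families; multi-letter
families count toward each letter). A pathway is enriched iff Mann-Whitney
p < 0.05 *and* the larger group-mean gene count exceeds twice the smaller
("difference more than two times" read as a ratio of group means of
counts).

**Route completeness.** A route is an ordered list of steps, each a set of
alternative KOs; a genome completes an atomic route when every step
intersects its KO set, and a composite route when all components are
complete (cycles are an error; a non-composite route with zero steps is
invalid rather than vacuously complete). The shipped registry covers
butyrate synthesis from starch, lactate and ethanol. Only K00016
(l-lactate dehydrogenase) and K13954 (alcohol dehydrogenase) are anchored
in the published text; all other step KO sets are editable defaults marked
non-authoritative, and completeness proportions computed with them must
not be read as reproducing the published percentages.

**HGT screening.** Input is a precomputed per-gene best-hit table. At each
rank, a gene whose best non-self-genome hit lies in a different group with
identity ≥ 75% and coverage ≥ 75% (configurable; the original analysis
used a dedicated tool's internal, pair-specific cutoffs, which this fixed
cutoff deliberately simplifies) becomes a candidate; rank-wise candidates
merge keeping the most specific rank. Donor = the hit's group, recipient =
the gene's own genome. Gene-tree/species-tree reconciliation is out of
scope; every event carries `validated=False`.

## Synthetic world

Defaults state the emulated study design: 30 focal + 100 background
genomes; genome sizes Normal(4.53, 1.22) vs Normal(3.92, 1.08) Mb
(truncated > 0.5); GC Normal(32, 7) vs Normal(33, 5) % (clipped to
[20, 80]); 63.3% of focal tips placed in few clades, the rest uniform; a
birth-death tree (λ = 1.0, μ = 0.2) scaled to height 1. Gene content:
1500 families, 35% "core-like" (stationary presence 0.97) and the rest
accessory (0.30), evolving by a two-state Markov process with total switch
rate 2.0 per unit height from a stationary root; habitat effects multiply
the gain (or loss) rate on focal terminal branches only — habitat is a tip
attribute, and terminal-branch effects are the simplest mechanism that
yields tip-level association with phylogenetic noise. Copy numbers are
1 + Poisson(0.3) where present (×3 in focal genomes for copy-enriched
families). Twenty habitat KOs are implanted at penetrance 0.9/0.1 (a
quarter in the background direction); route-step genes are drawn per
genome so that route completeness hits the published proportions (e.g.
lactate dehydrogenase 1.0/0.80, acetyl-CoA→butyrate 0.567/0.34; the
alcohol-dehydrogenase step uses the published presence 0.90/0.66). The
best-hit table has 20 background genes per genome (identity
Normal(60, 5) clipped to [30, 95], ~30% with cross-genus hits) plus 40
implanted cross-genus transfers (identity Normal(98, 1) clipped to
[90, 100]) — chosen a priori so that sub-cutoff background noise yields
high precision at the default 75/75 cutoffs. Everything derives from one
seed; bundles are byte-identical across runs.

What the generator does **not** emulate: real annotation sparsity and
biases, correlated gain/loss across families, rate variation across
lineages, genome-size–dependent family counts, and within-step KO
redundancy differences. A green recovery test therefore establishes that
the pipeline detects the *kind* of signal the study describes at the
stated effect sizes — not that it reproduces the study's real-data term
lists (310 KOs, 45 pathways, 161 HGT events), which require the deposited
genomes and are explicitly out of scope.

## Numerical choices

- All analyses treat presence as copy number ≥ 1.
- Working-correlation and covariance inversions add a ridge (1e−6 and
  1e−8) only when needed for conditioning.
- Empirical p-values use the (1 + hits)/(1 + n) correction.
- p_adj ≥ p is enforced structurally in every result table.
- Mann-Whitney with zero variance (all observations identical) returns
  p = 1.
- Tests that repeat whole-pipeline analyses scale the permutation count
  (99 instead of 1000) and state so; thresholds are never scaled.

## Known limitations

- The phylogenetic logistic regression is an estimating-equation
  construction with a fitted signal weight, not a maximum-likelihood
  implementation of a specific evolutionary model; its guarantees here are
  the star-tree limit, the measured calibration and the measured power.
- The worst-case pairwise statistic is discrete; with few contrasting
  pairs the permutation test has coarse resolution.
- Fixed identity/coverage cutoffs stand in for the original HGT tool's
  internal derivation; candidates are unvalidated by reconciliation.
- Multifurcating trees are handled by folding children pairwise in the
  pairing DP; polytomy-rich trees have not been stress-tested beyond the
  property suite.
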