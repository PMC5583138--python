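# Methods

## Study design the package targets

The analysis model is a paired-compartment amplicon survey of granulating
sequencing batch reactors: several reactors followed from seeding, each
sampled repeatedly in two compartments — the reactor content (granular
phase) and the effluent (suspended phase) — on the same days, yielding
contemporaneous sample pairs. The bundled design is 3 reactors × 2
compartments × 13 sampling days (78 samples, 39 pairs) over a 12-week run,
with weeks 1–6 (days ≤ 42) treated as start-up and weeks 7–12 as steady
state. The phase boundary is a parameter (`startup_end_day`, default 42).

All statistics operate on per-sample relative read abundances (total-sum
scaling). Library sizes differ systematically between compartments, so
nothing downstream ever compares raw counts across samples.

## Retention ratio

For taxon *i* in a pair at day *t*: rho = granular RA / effluent RA.
Properties used as invariants and tests:

- rho is invariant to rescaling either library (composition-based);
- with only two taxa, rho_A > 1 ⇔ rho_B < 1 (closure);
- over all taxa of a pair, Σ_i (effluent RA)_i · rho_i = Σ_i (granular RA)_i = 1.

**Zero handling.** A taxon with zero effluent abundance has an undefined
ratio, flagged `zero_effluent` (or `zero_both`) and excluded from tests —
never interpolated or silently dropped; counts of undefined points are
reported everywhere. Rationale: any pseudocount choice injects a tunable
bias exactly where the data are weakest; exclusion is transparent. A
pseudocount mode (add 0.5 reads to every cell before normalizing) is
available for users who prefer complete series; at depth 20,000 it perturbs
well-observed ratios by roughly 0.5/g + 0.5/e in relative terms, so only
rare taxa move appreciably.

**Steady-state test.** Two-sided one-sample Wilcoxon signed-rank of the
phase's defined ratios against 1. Zero differences are dropped before
ranking, ties get midranks. For n ≤ 25 the null distribution of the
positive-rank sum is computed exactly by convolution over sign assignments
(conditioning on the observed midranks); beyond that, a tie-corrected
normal approximation without continuity correction. The reported statistic
is min(W+, W−); direction (`above_1`/`below_1`) requires both the median on
that side of 1 and p < alpha (default 0.05). The test is run on raw ratios
against 1, which is asymmetric for reciprocal deviations (|0.5−1| < |2−1|);
a log-scale option (log-ratios vs 0) symmetrizes this. Raw scale is the
default because the ratio itself is the reported effect measure; the n = 7
steady-state design makes the minimum attainable two-sided exact p equal
to 2/2^7 ≈ 0.0156, so the exact test is conservative at nominal 0.05.

**Temporal trend.** Pearson r of (day, ratio) over all defined points of
both phases, two-sided p from the t transform on n−2 df; fewer than 3
points or zero variance → flagged not-computable. Significance marks use
strict inequalities (p = 0.05 earns "•", not "*"). No multiple-testing
correction is applied to the reported p-values; a Benjamini–Hochberg column
(`p_bh`) is emitted alongside, clearly an addition to the per-taxon view.

## Community comparisons

Bray–Curtis BC = Σ|x−y| / Σ(x+y) on relative abundances; similarity
reported as (1−BC)×100%. Paired similarity is summarized per reactor as
mean ± sample sd over days; cross-reactor similarity averages all
cross-group sample pairs in a day window (default: the final two weeks).

**NMDS.** Kruskal-style non-metric MDS minimizing stress-1
√(Σ(d−d̂)²/Σd²), where d̂ is the isotonic (pool-adjacent-violators)
regression of configuration distances onto the rank order of the input
dissimilarities. Ties are treated weakly ("primary"): within tied
dissimilarities the fit follows the current distances. Each run alternates
the isotonic fit with a Guttman (SMACOF) update; an update is accepted only
if stress decreases, so the per-run stress trace is monotone by
construction; convergence is a relative stress change below `tol`
(default 1e−7). Because stress-1 is scale-invariant, the configuration is
renormalized each iteration to the size of the dissimilarities — without
this pin the iteration can drift toward the collapsed (all-coincident)
configuration, where stress is 0/0; a fully collapsed configuration is
scored as infinite stress. The returned solution is the best of one
classical-scaling (Torgerson) start plus `n_restarts − 1` seeded random
starts, which also guarantees final stress ≤ the classical start's stress.
An input whose off-diagonal dissimilarities are all equal carries no rank
information and is flagged `degenerate`. No abundance autotransform
(Wisconsin/sqrt) is applied before ordination; callers can transform
upstream if desired.

**Diversity.** Margalef (S−1)/ln N, Shannon H′ = −Σ p ln p (natural log),
Pielou J = H′/ln S over the S non-zero taxa; J is undefined (NaN) for
single-taxon samples. Implementations are the closed forms, cross-checked
in tests against scikit-bio.

## Dominant-genus selection

Genus collapsing sums counts over taxa sharing a Greengenes-style `g__`
label; taxa without a genus assignment keep their OTU label, so
unclassified reads stay visible as their own rows. "Most abundant genera
common to all sample categories" is implemented as: strictly positive mean
relative abundance in every reactor × compartment category (a presence
filter; a minimum-mean threshold is configurable, default 0), ranked by
grand mean abundance over all samples (per-category-minimum ranking
available), ties broken lexicographically for determinism. The cumulative
share of the selected genera (mean ± sd % across samples) is reported.

## Wash-out simulator

A minimal mechanistic model of the observable, not of granule physics. The
reactor community is a composition p(t); the effluent is an
enrichment-biased sample of it:

    e_i(t) = exp(beta · (s_i − s̄_w(t)) · G(t)),  s̄_w = Σ p_i s_i
    q_i(t) = p_i e_i / Σ_j p_j e_j
    p_i(t+1) ∝ p_i exp(g_i − delta · e_i(t))

with surface affinity s_i ∈ [0,1], granulation ramp G(t) (linear between
`granulation_start_day` = 21 and `granulation_end_day` = 49 by default;
logistic available), erosion contrast beta, erosion loss delta, and
per-taxon net growth g_i. Centering on the abundance-weighted mean affinity
keeps community-wide enrichment ≈ 1, so beta sets the surface/core contrast
rather than total wash-out. The true retention ratio is rho_i = (Σ p e)/e_i,
and Σ q_i rho_i = 1 exactly — used as an exact conservation check. Before
granulation (G = 0) every rho is exactly 1: the proportional wash-out limit
in which all flocs settle alike. Observed counts are multinomial draws of
depth D from p and q (Dirichlet-multinomial overdispersion optional,
off by default; real amplicon data are overdispersed, so the multinomial
default represents a best-case noise floor).

Default conditions mirror the emulated design: 30 taxa with lognormal
(σ = 1.2) initial abundances, uniform affinities, N(0, 0.02)/day growth
rates; 13 sampling days (7, 14, ..., 42 weekly during start-up, then 45–84
giving 7 steady-state pairs); depth 20,000 reads/sample; beta = 2.0, 1.5,
1.0 for the three reactors (emulating different loading-rate regimes);
delta = 0.02/day. The three reactors share initial abundances and
affinities but draw independent growth rates, so their communities diverge
over the run the way differently loaded reactors do — paired
granular/effluent similarity stays high within each reactor while
cross-reactor similarity decays. Erosion rates are free parameters with documented
defaults, not estimates of any real system. The taxon specs come from fixed
internal seeds, so the noiseless dynamics (and hence SimTruth) are
identical for every run seed; the run seed governs only the count noise.

What the simulator does **not** emulate: spatial granule structure, granule
breakage, taxon interactions, primer/copy-number bias, chimeras, and (by
default) overdispersion. Passing recovery tests therefore shows the
estimator chain is correct and well-calibrated under the stated noise
model — not that real-data retention calls at these sample sizes reach the
same sensitivity.

## Numerical choices and degenerate inputs

- Counts must be integral; a strict flag aborts on non-integral values
  (default) or rounds with a warning.
- Relative-abundance columns are validated to sum to 1 within 1e−9; truth
  compositions conserve mass within 1e−12.
- Quartiles for the Tukey boxplot summaries use the linear-interpolation
  quantile rule; whiskers sit on the most extreme points within 1.5 IQR.
- Unpaired samples stay in ordination/diversity but are excluded (and
  counted) in retention analyses.
- Exact-p boundary conventions: two-sided p = min(1, 2·min(P(W ≤ w),
  P(W ≥ w))) including the observed point; perfect correlations clamp p to
  the smallest positive float before star assignment.
- Validation experiment sizes (50 replicates for recovery/sensitivity, 20
  replicates ≈ 600 taxa for the neutral false-positive rate) were chosen to
  give stable estimates at interactive runtimes.

## Known limitations

- The Wilcoxon exact null conditions on observed midranks (standard
  practice); with heavy ties the "exact" p is exact only conditionally.
- NMDS restarts trade runtime for stress: very small restart counts can
  return a local optimum (the classical start makes this rare in practice).
- Retention ratios are compositional: a strong enrichment of one taxon
  necessarily depresses the ratios of others (closure); between-taxon
  comparisons of ratio magnitudes inherit this coupling.
- `between_group_similarity` averages pairwise similarities; it is not a
  formal test (no PERMANOVA/ANOSIM here by design).
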