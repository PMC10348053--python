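# Methods

This note documents the statistical procedures `fritrend` implements,
the choices made where the published account of this kind of analysis
leaves details open, and what the synthetic-data tests do and do not
establish.

## Data model and alignment

The atomic observation is one examiner's FRI score (0–3) for one zone
of one permanent tooth at one exam wave. Non-fluoride opacities are
recorded as score 0 with a flag; all analyses here treat them as 0,
the flag is preserved so alternative analyses can exclude those zones.
When duplicate exams exist (a second examiner re-scoring a
participant at a wave), the input must mark exactly one record per
(participant, wave) stream as primary: the choice of analysis record
among examiners is a study-design decision we deliberately externalize
rather than guess. Primary records feed the severity analyses;
all records feed kappa.

Longitudinal summaries use only zones observed at every age being
compared (`all_ages` alignment: 4 waves for early-erupting teeth and
maxillary incisors, 3 for late-erupting teeth; `pairwise` alignment
for adjacent-wave transitions). Missing zones are dropped, never
imputed — an unobserved zone at any wave removes that zone from the
comparison entirely, so denominators are constant across the compared
ages.

## Severity measures

Person-level mean FRI averages all retained zones of a participant in
a tooth group; tooth-level mean FRI averages the 1–4 retained zones of
a tooth. Means are binned as 0, (0, 0.5], (0.5, 1.0], (1.0, 3.0]
(labels 0 / 0.01–0.50 / 0.51–1.00 / 1.01–3.00). The printed
two-decimal labels force the breakpoints but not their openness; the
half-open convention makes every achievable mean fall in exactly one
bin, and a mean counts as zero within 1e−12.

The five-category generalized-fluorosis classification uses per-tooth
maximum scores over available zones: generalized positive if ≥ 50 % of
available teeth reach max ≥ 2; else generalized questionable if ≥ 50 %
reach max ≥ 1; else any positive / any questionable / no fluorosis.
Both 50 % thresholds are inclusive, and "available teeth" means teeth
in the aligned set (constant across waves), not the nominal group
size. The alternative denominator — teeth scored at that wave
regardless of other waves — would let the denominator drift across
waves and break the constant-n table property; it is not implemented.

## Trend inference

Goodman–Kruskal's gamma, γ = (C − D)/(C + D) over concordant and
discordant observation pairs (ties contribute to neither), measures
the ordinal association between exam age and severity category.

*Person level*: the classical asymptotic variance
var(γ̂) = 16 (P+Q)⁻⁴ Σᵢⱼ nᵢⱼ (Q·Aᵢⱼ − P·Bᵢⱼ)², with Aᵢⱼ/Bᵢⱼ the
concordant/discordant partner counts of cell ij and P = Σ nᵢⱼAᵢⱼ = 2C,
Q = 2D. γ̂/se is treated as standard normal (two-sided p). A
2,000-replicate nonparametric bootstrap on multinomial tables (n=500)
agrees with this se within 15 % in the test suite.

*Tooth level*: teeth within a mouth are correlated, so the asymptotic
se is too small. We use a permutation scheme: per null replicate, each
participant independently draws one random permutation of the wave
labels and applies it to all of their teeth. This preserves cluster
composition and within-wave correlation while breaking any
age–severity association, so it is valid under the null of no trend.
The standard deviation of the replicate gammas is the standard error
and γ̂/se is again treated as normal — the null-distribution sd feeds
a z statistic rather than reporting a raw permutation p, matching the
normal-reference reporting convention of the published tables. Default
2,000 replicates (minimum 200), seeded. Neither method accounts for
within-participant correlation *over time*; like the published
analysis, the resulting p-values warrant cautious reading.

Inter-examiner reliability: unweighted Cohen's κ per examiner pair
over co-rated units (each examiner's rating of a unit is the mean-FRI
category computed from that examiner's own zone scores), averaged over
pairs with at least one co-rated unit.

## Transition analysis

Each pairwise-aligned unit (participant or tooth) is categorized at
both ages; cells of the baseline × follow-up table get 95 % intervals
for the within-baseline-stratum transition proportion:

- person level — Wilson score interval, only for cells with ≥ 10
  participants. The eligibility rule is read as a *cell*-count rule
  (the plotted bars it gates represent cells); applying it to the
  baseline stratum instead would add intervals for sparse cells inside
  large strata.
- tooth level — intercept-only binomial-logit model with the
  cluster-sandwich variance A⁻¹BA⁻¹, A = n p̂(1−p̂), B = Σ_g S_g²
  (S_g = cluster sums of score residuals), back-transformed from the
  logit scale. For intercept-only models this is algebraically the GEE
  logistic estimator with independence working correlation; a
  statsmodels GEE fit is the cross-check in the test suite. Cells with
  pooled proportion 0 or 1 have no logit-scale interval and are
  reported without one (point mass).

Decline per baseline stratum is tested with a one-sided Wilcoxon
signed-rank test on the actual mean-FRI differences (follow-up −
baseline), not category changes. Zero differences are dropped
(standard convention; the alternative — Pratt's method — is not
implemented), ties midranked. With ≤ 25 nonzero differences the p is
exact: P(W⁺ ≤ observed) by convolution over the 2ⁿ sign assignments
(midranks doubled to integers); above that, z = T/√(Σ rᵢ²) with
T = Σ signed ranks, which equals the classical tie-corrected normal
approximation, no continuity correction. The cluster-adjusted variant
ranks all observations together and estimates var(T) by Σ_g S_g² over
cluster-level signed-rank sums — valid under intra-cluster correlation
because cluster sums are independent with zero mean under the
symmetric null, and exactly equal to the unclustered z when every
cluster has size 1.

The bleaching/whitening sensitivity analysis compares mean-FRI
differences between users (reported use at least once) and non-users
per baseline stratum with two-sided rank-sum tests: plain at the
person level; at the tooth level a cluster-level version whose
variance m₁m₀ Σ_g C_g² / (m(m−1)) comes from the permutation
distribution of cluster labels over cluster sums of centered ranks
(again reducing exactly to the tie-corrected Mann–Whitney z for
singleton clusters). Sixteen tests per level are run; no multiplicity
correction is applied, only an annotation of the family size. α = 0.05
throughout; all tests two-sided except the decline-directed
signed-rank tests.

## Synthetic cohort generator

The generator is a latent-threshold (ordinal-probit-style) model,
chosen as the simplest mechanism producing correlated ordinal zone
scores with a controllable monotone decline: participant severity
θ ~ N(0, σ_p²), persistent tooth and zone effects u ~ N(0, σ_t²),
e ~ N(0, σ_z²), and the true FRI of a zone at wave w is the ordinal
bin of θ + u + e − w·δ under three increasing cutpoints. The decline δ
acts on the latent scale so that mean-FRI and generalized-category
analyses both respond. Observed scores pass through a row-stochastic
4×4 examiner confusion matrix drawn independently per exam (an
optional `examiner_drift` inflates the off-diagonal mass per wave; it
is off by default because time-varying misclassification is itself a
time effect and would contaminate zero-decline null calibrations).
Structure emulated: 4 waves at ages 9/13/17/23, late-erupting teeth
absent at wave 1, cumulative dropout (independent of severity by
default; a severity-linked option exists for robustness probes), three
examiners with a duplicate-exam subset, participant-level bleaching
labels per interval, and rare non-fluoride opacities (stable
developmental defects, scored 0 at every wave). Output is
byte-reproducible under a fixed seed.

Preset defaults (`preset_ifs_like`): 330 participants (≈ 282 complete
cases after 5 %/wave dropout, the scale of the study this package
targets), σ_p = 1.4, σ_t = 0.45, σ_z = 0.35, cutpoints
(0.75, 1.8, 2.9), δ = 0.42 per interval, 15 % duplicate exams, 25 %
bleaching prevalence, 1 % opacities. These were calibrated once
against the published cohort-scale facts — baseline generalized
prevalence in the 30–55 % range falling to 8–30 % at age 23, person-
level gammas around −0.25 to −0.40, inter-examiner κ decreasing across
waves — and then frozen. Across seeds the preset yields baseline
generalized prevalence ≈ 36 %, age-23 ≈ 11 %, early-erupting person
gamma ≈ −0.32, and mean κ ≈ 0.76/0.60/0.54/0.46 by wave.

What the generator does *not* emulate: real zone-level spatial
correlation beyond the tooth effect, severity-dependent examiner
error, secular changes in scoring protocol, or the exact printed
counts of the study tables (those depend on the unavailable cohort).
Passing tests on synthetic data therefore establish internal
correctness and statistical calibration of the methods, not agreement
with any particular real cohort beyond the published count tables,
which are reproduced exactly where printed.

## Numerical and scaling choices

- Exact signed-rank p-values switch to the normal approximation above
  25 nonzero differences; the exact CDF uses integer convolution on
  doubled midranks.
- Degenerate inputs: gamma is refused when C + D = 0; the clustered
  rank tests require ≥ 2 clusters; all-zero difference sets return a
  flagged no-test result rather than a p-value.
- Calibration tests use 300–500 simulated datasets and permutation
  tests 200–400 replicates; parameter-recovery tests use 100
  replicates of 120-participant cohorts. These sizes give binomial /
  Monte-Carlo standard errors comfortably inside the asserted bands
  while keeping the default suite fast.
- The parameter-recovery check compares the pipeline's detected
  decline against the generator's direction and a null calibration
  (zero δ ⇒ gamma centered at 0). The latent δ itself is not
  identified on the FRI scale — the threshold map is nonlinear — so
  recovery is asserted through the implied observable decline, not
  numeric equality with δ.

## Known limitations

- The permutation scheme for tooth-level gamma is one defensible
  choice among several (cluster bootstrap being the obvious
  alternative); published analyses of this design rarely state theirs.
- Cluster-adjusted rank tests use large-sample normal references;
  with very few clusters (< ~15) their calibration degrades.
- The generalized classifier's "available teeth" denominator follows
  the aligned set; studies defining availability per wave would need
  the alternative denominator discussed above.
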