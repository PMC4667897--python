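# Methods

This note records the statistical models the package implements, the
conventions chosen where the methodology is genuinely open, and what the
synthetic-data generators do and do not emulate.

## Diet indices

Indices are computed over *identifiable* stomach contents only: bait and
unidentifiable chyme are stripped by `filter_contents` before any
arithmetic, and fish whose stomachs contain nothing identifiable drop out
of the %O denominator (they remain in the sample for bookkeeping).
Zero-weight items with positive counts are legal — mass below the 0.01 g
scale resolution — and contribute to %N and %O but not %W. Fine taxa are
condensed to broad categories by a total mapping before index math; the
46-taxon demo map shipped in `configs/demo_category_map.csv` is a
plausible illustration, not an authoritative reconstruction of any
study's grouping.

**Estimators.** The `pooled` estimator computes %N and %W from grand
totals over all stomachs; it is the natural reading of the index
definitions and is what feeds the overlap analysis. The
`mean_of_stomachs` estimator averages per-stomach percent compositions
(reporting SE = sd/√n, no finite-population correction), matching how
diet tables are usually printed. Which estimator produced any particular
published overlap value is generally not recoverable from printed tables,
so both ship and neither is hard-coded into the pipeline contract.

**IRI variant.** The literature typesets IRI both as
`(%N + %W) × %O` (the classical Pinkas form) and, occasionally and
usually erroneously, as `%N × %W × %O`. Reconstructing %IRI ratios from
the printed %N/%W/%O values of the source study's diet table reproduces
the printed %IRI column only under the additive form (Gastropod:Fish for
red snapper reconstructs to 0.3206 vs printed 0.3206; the multiplicative
form gives 0.167). The additive form is therefore the default; the
multiplicative variant remains available by configuration and the
discrepancy is a documented paper-gap finding, exercised by the test
suite.

## Pianka overlap and null models

Pianka's index is scale-invariant in each vector, so %IRI, %N, %W or raw
proportions are interchangeable inputs; the observed matrix is used
exactly as supplied, with no renormalization. Null matrices follow the
standard randomization algorithms: RA1 (uniform resample of all entries),
RA2 (uniform resample of nonzero entries), RA3 (permute each row across
all columns), RA4 (permute nonzero entries among nonzero positions). RA3
with 1000 repetitions is the default, mirroring common practice.
Conventions: p_upper = (#{null ≥ observed} + 1)/(reps + 1) — the add-one
correction prevents p = 0 artifacts; ties count toward the upper
(rejection) tail, which is conservative; both tails are reported; a seed
is mandatory. For two species the statistic is the pairwise index; for
larger matrices it generalizes to the mean pairwise overlap (untested
surface beyond two rows).

## Zero-adjusted Bray–Curtis, PERMANOVA, SIMPER

Dissimilarities are on the 0–100 scale. The zero adjustment appends a
constant dummy variable (default 1, on the transformed scale) to every
sample, so two empty samples are identical instead of undefined. The
square-root transform is applied before the dummy.

PERMANOVA partitions the total SS of the distance matrix through the
Gower-centered inner-product matrix G = −½ J D² J. Model terms are
claimed sequentially (Type I): with cumulative hat matrices H_k over the
ordered terms, SS(term k) = tr((H_k − H_{k−1})G), and pseudo-F uses the
residual mean square. Sequential SS is the honest choice for the
unbalanced site designs this package targets; term order is
caller-controlled and recorded in results. Significance comes from
unrestricted permutation of sample labels for all terms, including
interactions; restricted/residual-permutation schemes for interaction
terms are deliberately out of scope, and interaction p-values should be
read as approximate when main effects are strong. Degenerate inputs:
all-identical samples give SS = 0 and pseudo-F = 0 by convention; aliased
terms (zero incremental rank) are rejected, and the pipeline drops them
with a logged note rather than failing a whole run.

SIMPER averages, over all between-group sample pairs, each variable's
share of the Bray–Curtis numerator, 100·|x_k − y_k| / Σ_l(x_l + y_l), so
contributions sum *exactly* to the mean between-group zero-adjusted
dissimilarity — an identity the tests assert on random fixtures.

## Spatial overlap

A species is present at a site/cruise when any gear detected it (ROV
MaxN > 0 or a positive capture count); absence requires every gear
fished there to report zero. Site/cruise visits with no observation rows
are excluded from denominators — missing effort is not absence. The
pooled ("all cruises combined") co-occurrence percentages use site-cruise
visits as the unit, matching the per-cruise construction. MaxN for
non-detections is 0, not missing. Two depth-bin presets ship: four 20 m
bins (20–100 m) for the community analysis, and a 20–60 / 61–100 m split
for the diet analysis.

## Mesocosm analysis

The trial is the independent unit. Shrimp-per-fish divides a species'
successes by its *designed* fish count (6 alone, 3 mixed); success rate
is successes/attempts, undefined (and excluded from the success-rate
regression) when a species never struck. The default contrast test is
Welch's two-sample t on per-trial shrimp-per-fish — the
fewest-assumptions classical choice when the source analysis is
unnamed — with a two-tailed permutation test on the mean difference
always co-reported (complete enumeration whenever C(n, n_a) ≤ 2×10⁵,
Monte-Carlo with add-one correction otherwise).

The success-rate regression uses species-within-trial observations, the
unit that yields the study's printed residual df (28 points → df 1, 26
under the 8 + 8 + 6-trial design). The feeding-rate model evaluates each
(trial, species) cumulative per-fish consumption on a 1-minute grid over
0–30 min (configurable), squares the response — which linearizes
root-like saturating curves — and fits time + species + time×species by
OLS; pooling trials into one mean curve per species is available behind a
flag. The 1 df interaction F is the squared t of the interaction
coefficient; in saturated (zero-residual) fits it is numerically
meaningless and the coefficient itself should be read instead.

## Synthetic-data generators

The generators exist because the study's raw data were never deposited;
they emulate the *structure* the analyses assume, with defaults anchored
to published summary statistics (labelled emulation targets, not data).

- **Stomachs.** Per fish: an empty-stomach Bernoulli draw (defaults
  0.384/0.403 for RS/VS, the published fractions of stomachs without
  identifiable material); a per-stomach composition from a Dirichlet
  around the covariate-adjusted base (concentration 5 by default, giving
  the strong among-stomach overdispersion evident in printed SEs);
  multinomial item counts (mean 4 items); lognormal item weights
  (log-scale SD 0.5 — items of one category in one stomach are
  similar-sized, and this keeps pooled %W within the documented
  convergence bounds); and one flagged chyme item carrying the configured
  unidentifiable mass fraction (defaults 0.761/0.804). Base compositions
  follow the published all-sites %W for the ten major categories with the
  remainder spread over 18 minor ones; covariate effects are log-scale
  multipliers emulating the reported habitat/season/cohabitation shifts.
- **Surveys.** Abundance per site/cruise/species is negative-binomial
  (k = 2) around reef-type means (RS 2.12/1.02 artificial/natural,
  VS 1.09/1.51) times depth multipliers that average to one. Between
  species, draws are coupled by a Gaussian copula on a shared
  site-quality latent (ρ = 0.5): the copula keeps the negative-binomial
  marginals exact — so stratum-mean recovery is unbiased — while making
  the both-present fraction monotone in ρ. (An earlier multiplicative
  lognormal site factor was rejected: it lowers detection probabilities
  through their concavity and can *decrease* co-occurrence as the shared
  variance grows.) Capture-gear counts are binomial thinnings (p = 0.3)
  of the same abundance draw.
- **Trials.** Attempts arrive per fish as a Poisson process; each
  succeeds with a per-species strike probability (0.55/0.35) unless the
  15-shrimp pool is exhausted or the fish has reached satiation (cap 5).
  The realized total per trial is exactly min(Σ_i min(P_i, cap), pool)
  for iid Poisson potential successes, so the per-fish consumption
  targets (RS 1.66 / VS 0.83 alone; RS 2.39 / VS 0.83 mixed, i.e. the
  published 0.83 and 1.56 shrimp-per-fish contrasts) are converted to
  attack rates by root-solving that truncated expectation — the stated
  targets are the generator's true means, not untruncated nominals. In
  the mixed treatment each species is calibrated against the full pool;
  the residual cross-species truncation at default rates is below ~0.02
  shrimp per fish.

What passing tests on these generators shows — and does not. The
generators reproduce overdispersed compositions, co-occurrence structure,
and event-stream truncation, so they exercise every code path and the
estimators' calibration (type-I error, power, parameter recovery). They
do not emulate taxon-level patchiness, gear selectivity, ROV
attraction/avoidance bias, within-site spatial structure, or satiation
dynamics beyond a hard cap, so agreement on synthetic data does not
validate those aspects of any field inference.

## Pipeline sizes and reproducibility

The `paper_like` configuration runs the full study scale (216 + 154
stomachs, 40 sites × 3 cruises, 8/8/6/2 trials, 1000 null-model reps,
999 PERMANOVA permutations) in well under a minute on one CPU; every
stage seeds its own generator deterministically from the run seed, and
result JSON is byte-stable, so identical config + seed reproduces
identical files (asserted in the acceptance suite). Dates are ISO-8601;
season derives from a configurable month map (February–June = spring,
July–November = summer by default, since cruise labels alone do not fix
the boundary). Cohabitation strata for the diet analysis come from the
survey table when available (a site is sympatric if both species were
ever detected there), else from a per-site override column.

## Known limitations

- Unrestricted permutation for interaction terms (above).
- The null-model engine beyond two species and the multiplicative IRI
  variant are provided but not exercised by the pipeline defaults.
- SIMPER reports contributions on the dissimilarity scale only; the
  group-mean table is on the transformed abundance scale.
- The generators draw covariates independently per fish; real sampling
  clusters fish within site/day hauls, so synthetic PERMANOVA p-values
  are calibrated for exchangeable units only.
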