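# Methods

This note documents the models and procedures implemented in `microtrace`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data validation does and does not
establish.

## Study grid and data model

The sampling design is a fixed grid: locations 1–4, six sites per location
(`left_palm`, `right_palm` — *skin*; `bed_headboard`, `door_knob` —
*household*; `public_handrail`, `subway_handrail` — *public*), and 20 time
slots (days 1–10 × {AM, PM}, slot index `2(day−1) + [period==PM]`). Each
residence has a single occupant, so person identity equals location for
skin samples. Abundances are relative (percent; rows renormalised to 100 on
input), with taxa keyed by MetaPhlAn-style lineage strings parsed for
family and phylum. A missing sample is the absence of a metadata row —
zeros are data, absence is missingness. All I/O is plain TSV.

## Matching

*Reference pools.* One pool per time slot containing every person's skin
samples at that slot; slots where any person lacks a skin sample are
excluded. *Prediction.* For each person, the mean distance between the
query and that person's pool samples (the per-person mean is the default
because a pool holds up to two palms per person; a nearest-single-sample
variant is available, as the published description is ambiguous between the
two). Ties break to the lowest person id and are logged. *Accuracy
accounting.* Every (query, pool) pair is attempted, including zero delay;
delay = 12 h × (query slot − reference slot), negative when the query
precedes the references.

*Distances.* Canberra uses the vegan `vegdist()` dialect — the sum of
`|x−y|/(x+y)` over non-double-zero coordinates divided by the number of
such coordinates — because that is the convention of the R function used in
the field; the unscaled textbook sum is an option. An all-zero pair is an
error ("no shared support"). Bray–Curtis is the standard ratio and is
cross-checked against `scipy.spatial.distance.braycurtis` in the tests.

*Statistics.* Spearman's ρ relates accuracy to absolute delay, pooling ±
delays. Accuracy comparisons use plain Pearson chi-squared on the 2×2
correct/incorrect table (no continuity correction by default — large-n
comparisons; a corrected option exists). When neither group has any outcome
variation the chi-squared limit 0 (p = 1) is reported rather than an error.
One caveat on the accuracy chi-squared tests: attempts are not independent
— every query sample is matched against every pool, so one query
contributes up to 20 correlated outcomes. Splits that separate whole query
samples (e.g. AM vs PM *queries*) are therefore anti-conservative at the
attempt level, while splits that pair the same queries across groups (AM vs
PM *references*) hold their level; the calibration tests cover the latter.
PERMANOVA on Bray–Curtis distances uses Anderson's sums-of-squares
pseudo-F computed directly from the distance matrix, with label
permutations and the +1 p-value convention `p = (1+#{F≥F_obs})/(1+N)`,
which guarantees p > 0; the statistic is verified against scikit-bio's
implementation in the tests. The Dunn-style indicator source profile is a
configurable family→source map (the family lists are external inputs).

## Diurnality

*Series preparation.* The 20-slot series of one species at one (site,
location). Species present (abundance > 0) at fewer than 4 slots are
excluded — the presence filter counts nonzero slots, not merely observed
slots, as "not present" most plausibly means zero abundance. Leading and
trailing gaps are trimmed; internal gaps are filled by seasonal-aware
interpolation (subtract per-period means, linearly interpolate the
residuals, re-add), which reproduces a noiseless alternating pattern
exactly. The exact internals of the R imputation routine the approach
mirrors are unspecified, so this documented recipe stands in for it.

*Decomposition.* Classical additive moving-average decomposition at
frequency 2: trend = centred 3-term average with weights (¼, ½, ¼),
undefined at the series ends; seasonal figure = per-position mean of the
detrended series, centred to sum to zero over the period, tiled; random =
remainder. Additive (not multiplicative) because that is the default of the
classical routine and nothing in the procedure description indicates
otherwise.

*Seasonality strength.* `F_S = max(0, 1 − Var(R)/Var(S+R))`, sample
variances (n−1) over the slots where the trend (hence all components) is
defined — a pairwise-complete choice, documented here because whether the
original computation included the end slots is not stated. `Var(S+R) = 0`
defines `F_S = 0`. F_S is invariant to adding a constant and is 0 for a
pure linear ramp.

*Permutation test.* The (interpolated) values are permuted uniformly over
slots — post-interpolation, so the statistic's support is identical between
observed and null — and `p = #{F_S,perm > F_S,obs}/N` with strict
inequality and no +1 correction, exactly the plain-proportion definition
(a +1-corrected option exists). With N = 199 the test is exact at the null:
rejection at p < 0.05 occurs when the observed statistic ranks in the top
10 of 200 exchangeable values, giving type-I error 0.05 (verified by
simulation in the acceptance suite). N = 999 is the analysis default.

*Alternative test.* The paired AM-vs-PM comparison is the Wilcoxon
signed-rank test on per-day (AM, PM) pairs, two-sided, exact for ≤ 25
pairs; all-zero differences return p = 1 with a degeneracy warning.

*Re-analyses.* Negative-control removal drops listed species everywhere,
renormalises and re-runs detection, reporting removed / lost-significance /
retained counts. The compositional probe removes one species at one (site,
location), renormalises and re-runs detection there; a two-species closure
construction in the tests shows a genuinely diurnal dominant species
inducing a significant antiphase pattern in constant species that vanishes
after removal. The abundance comparison (diurnal vs non-diurnal
combinations, zeros excluded) uses Mann-Whitney plus Spearman of abundance
against F_S.

## Dispersal networks

Species are aggregated to families; each of the six per-site series is
`log2(abundance + ε)` with ε = half the table's smallest nonzero abundance
(the zero-handling of the original pipeline is unstated; a pseudo-count of
this size is below every observed value). "i5" is read as interval
(equal-width) discretisation into 5 bins spanning [min, max], maximum in
the top bin, constant series to the middle bin. Slots with missing samples
are interpolated for binning-range purposes but transitions spanning them
are dropped from scoring — imputed dynamics are never scored. The global
(all-sites) transition mask keeps scores comparable across structures.

Scoring is BDeu (Dirichlet-multinomial marginal likelihood) with
equivalent sample size 1, a documented stand-in for the Java tool default
the original analysis used, whose exact prior is not recoverable; BIC is
available and the choice is recorded on each model. One known BDeu(ESS=1)
property matters at this data size: with 19 transitions, a 5-parent
configuration space (5⁵ cells) fragments every observation into a
singleton, scoring exactly −ln 5 per observation, which can exceed the
marginal likelihood of balanced counts under the empty model. The search is
nonetheless sparse in practice because hill climbing only traverses
single-edge moves, and a single uninformative edge reliably lowers the
score; the unconditional many-parent penalty holds under BIC.

Search is multi-restart greedy hill climbing over single-edge additions and
deletions (lag-1 edges only, so no acyclicity constraint; self-edges are
allowed, capturing persistence), accepting the first improving move in a
seed-shuffled order, restarting from the empty network, keeping the best
score — a deterministic replacement for the original tool's simulated
annealing machinery, adequate for 6-node networks. At most 5 parents per
child. Edge summaries count (parent class, child class) pairs, and
Kruskal–Wallis tests compare per-node parent-role (and child-role) edge
counts across the three site classes.

## Synthetic generator

Per (location, site-class), species log-baselines are N(0, 1); signature
species (disjoint random sets, 5 per location by default) are ×10 on the
occupant's skin. The public pool is one compartment shared across locations
at baseline, per-location resampled at a configurable daily turnover rate
(default 0 — the pool is fixed); the two public sites are noisy replicates
of it. Diurnal species (8 per site/location by default) have expectation
×amplitude (default 3) in their peak period at their site only. Dispersal
acts on expectations, before noise, so planted effects are exact: at PM,
skin ← (1−0.3)·skin + 0.3·public; every slot, household ←
(1−0.3)·household + 0.3·skin(t−1); at AM, skin is pulled toward its
personal baseline with weight 0.8 ("normalisation"). Household states are
initialised one mixing step toward the occupant's skin, since household
surfaces are reservoirs of the occupant's microbiome accumulated before any
survey begins. Noise is multiplicative log-normal (σ = 0.3) — chosen over
Dirichlet resampling because it preserves the rare-taxon structure Canberra
matching depends on — followed by closure to 100 % and independent 5 %
sample dropout. The same seed yields a bit-identical table.

No quantitative dispersal or turnover rates are available to emulate; the
defaults above are plausible magnitudes fixed once, not estimates.

### Scenario configurations

Named scenarios fix the conditions under which each planted effect is
recoverable in isolation; they are study conditions, not tuning knobs:

- `diurnal_recovery_config`: amplitude 3, noise 0.2, dispersal and
  normalisation off — the PM public→skin mixing itself creates genuine
  AM/PM structure in every skin species, which would contaminate the
  false-positive measurement among non-planted species. Even so, closure of
  the planted species induces some genuine antiphase signal in the rest, so
  false-positive calibration is asserted on the no-planted-effect scenario.
- `matching_recovery_config`: signature boost 10, zero noise and dropout —
  the regime where household matching is constructively guaranteed.
- `delay_decay_config`: public turnover 0.3 — public queries lose accuracy
  with delay because the pool their local skin mixed with has turned over.
- `dispersal_recovery_config`: public→skin mix 0.5, noise 0.1, turnover
  0.3 — a lag-1 public→skin edge is only informative when the public pool
  varies over time, hence the nonzero turnover.
- `independent_sites_config`: no coupling, no planted effects — the null
  for network sparsity.
- `planted_coupling_series`: a direct six-site family series with an exact
  lag-1 public→skin dependence (skin(t) = (1−m)·baseline + m·public(t−1)),
  the minimal construction for edge-recovery measurement, separate from the
  full generator whose within-slot PM mixing is only approximately lag-1.

## Problem sizes and numerical choices

The tests and the acceptance script run the full default grid (4 locations
× 6 sites × 20 slots, 150 species, ≈ 460 samples after dropout), 999
permutations for analysis runs and 199 for the 200-replicate calibration
studies (where the exact-null property makes 199 sufficient), 200
replicates for both type-I calibrations, 25 seeded runs for edge recovery
and 120 (location, family) networks for the pooled direction comparison.
Tolerances: 1e−12 on hand-computed distance values, 1e−10 on
decomposition-oracle agreement, 1e−9 on conservation identities; calibrated
rejection rates are accepted within the exact binomial 95 % interval.

## What passing tests show — and don't

The generator plants effects on the expectation layer of a stylised model:
log-normal noise, a single shared public compartment, stationary baselines,
no sequencing error, no taxonomic misassignment, no correlation structure
among species beyond closure and the planted couplings. Recovery therefore
demonstrates that the estimators detect the structures they target at
realistic magnitudes, and the calibration studies show the tests hold their
nominal levels on exchangeable nulls. Passing does not establish
performance on real metagenomic profiles, where compositional correlation,
taxonomic artefacts and non-stationary behaviour are richer; the headline
numbers of any real survey (absolute accuracies, counts of diurnal species,
edge totals) depend on those data and are not reproduced here.

## Known limitations

- The matching "smallest mean distance" reading (per-person mean vs nearest
  sample) is ambiguous in the published description; both are implemented,
  neither asserted as the original intent.
- The permutation p-value without +1 correction can be exactly 0.
- BDeu(ESS=1) is a stand-in for an unrecoverable default prior; network
  scores are comparable within, not across, scoring metrics.
- Multiple-testing correction is deliberately not applied by default in
  diurnal detection (raw α = 0.05 mirrors the analysis the package
  re-implements); an option exists.
- LOESS smoothing, SourceTracker's Gibbs sampler and figure rendering are
  out of scope.
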