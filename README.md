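# microtrace

Forensic microbiome analysis asks whether the microbial trace a person
leaves on a surface can identify them. `microtrace` implements the core
analytical machinery for twice-daily built-environment swab surveys —
people's palms, household surfaces (bed headboard, door knob) and nearby
public handrails sampled every morning and evening over ten days — and a
synthetic-data generator that emulates that design with known ground truth,
so every method can be validated by parameter recovery.

The package is aimed at microbiome researchers working on source tracking,
trace persistence and community time series. It provides four analyses:

1. **Microbiota matching.** A surface sample (*query*) is matched against a
   *reference pool* — all skin samples of all participants at one time
   point. For each person, the mean distance between query and that
   person's skin samples is computed; the argmin is the predicted match,
   correct when that person lives at the query's location. Distances follow
   the vegan `vegdist()` dialects: Bray–Curtis
   `d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)` and Canberra
   `d(x,y) = (1/NZ) Σ_{xᵢ+yᵢ>0} |xᵢ−yᵢ|/(xᵢ+yᵢ)`, which up-weights the
   rare taxa that make skin communities individual. Matching every
   (query, pool) pair resolves accuracy by *sampling delay* (±12 h steps)
   and by time of day, with Spearman, chi-squared and PERMANOVA statistics.

2. **Diurnal species detection.** Each (species, site, location) abundance
   series over the 20 slots is decomposed additively by moving averages
   into trend `T_t`, seasonal `S_t` (period = 1 day) and random `R_t`
   components. The seasonality strength

   `F_S = max(0, 1 − Var(R_t) / Var(S_t + R_t))`

   is tested against 999 random permutations of the series
   (`p = #{F_S,perm > F_S,obs} / 999`). Robustness re-analyses cover
   negative-control species removal, compositional (closure) artefacts via
   single-species removal and renormalization, a paired signed-rank
   alternative test, and the diurnal-vs-non-diurnal abundance comparison.

3. **Dispersal networks.** Per (location, family), the six per-site
   family-abundance series (log2 with pseudo-count, 5-bin equal-width
   discretisation) feed a lag-1 dynamic Bayesian network search —
   multi-restart greedy hill climbing under the BDeu score (equivalent
   sample size 1; BIC optional), at most 5 parents per node. An edge
   `public_handrail → left_palm` means the handrail's abundance predicts
   the palm's one time step (~12 h) later, read as microbial dispersal.
   Edge roles are summarised per site class with Kruskal–Wallis tests.

4. **Synthetic study generator.** Plants person-specific signature taxa
   (boosted on the occupant's skin), diurnal species with assigned peak
   periods, public→skin (PM) and skin→household (lag-1) dispersal with
   overnight "normalisation" of skin toward its personal baseline,
   log-normal noise, compositional closure to 100 % and missing samples —
   all recorded in a `GroundTruth` object for recovery tests.

## Worked example

```python
from microtrace import SyntheticConfig, generate
from microtrace.matching import evaluate_matching, overall_accuracy
from microtrace.diurnal import detect_diurnal, site_class_summary

table, metadata, truth = generate(SyntheticConfig(seed=1))
curve, results = evaluate_matching(table, metadata, metric="canberra")
print(f"household-query accuracy: {overall_accuracy(results, 'household'):.1f}%")
print(f"public-query accuracy:    {overall_accuracy(results, 'public'):.1f}%")

catalog = detect_diurnal(table, metadata, n_permutations=199, seed=1)
print(site_class_summary(catalog)[["site_class", "proportion_significant"]])
```

prints

```
household-query accuracy: 100.0%
public-query accuracy:    24.3%
site_class  proportion_significant
household   0.133
public      0.187
skin        0.486
```

Household surfaces, continually re-seeded from one occupant's boosted
signature taxa, identify their owner in every attempt, while public
handrails — shared pools with no person-specific signal — sit near the 25 %
chance level for four candidates. Diurnal structure is strongest on skin,
where the planted day/night species sit on top of the daily
dispersal/normalisation cycle. The `examples/` directory holds one short
script per capability (simulation, matching, diurnality and closure
artefacts, dispersal networks, full pipeline).

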