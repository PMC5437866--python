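# surveyerr

Characterisation of false-positive errors in repeated botanical site
surveys.

When many independent observers survey the same site, their species lists
disagree: species that are present get overlooked (false negatives), and
species that are absent get recorded anyway (false positives — misidentified
or misreported taxa). `surveyerr` is a pipeline for quantifying the
false-positive side of this problem from repeated-survey data with a trusted
site reference list, and for evaluating the classic remedy of raising the
acceptance threshold by combining surveys.

It is written for ecologists and biodiversity-informatics practitioners who
have (a) long-format survey records, (b) per-site accepted species lists,
(c) per-species regional attributes (genus, genus size, occupancy), and
optionally (d) a dated phylogeny covering the flora.

## What it computes

**Record classification.** Every record is normalised and classified against
the site reference and a regional checklist into four categories: correct
species (*true positive*), valid species not present at the site (*false
positive*), genus-only (*cautious*, half marks at most once per genus), and
names matching no valid taxon (*mythical*).

**Detection probabilities.** For each species at a site,
p = detections / surveys — a raw ratio, computed for accepted and for
false-positive species alike so the two distributions can be compared.

**Bootstrap survey combination.** The acceptance threshold is raised by
combining k surveys under a rule (present in all k, in ≥ m of k, or in any).
Because lists differ, the average TP/FP/FN of a k-survey combination is
estimated from 10,000 random draws of k distinct surveys. Sensitivity is
TP/(TP+FN). Specificity is TN/(TN+FP) with the true-negative pool defined as
the site's cumulative false-positive species list minus the combination's
mean FP — an explicitly arbitrary but internally consistent denominator.

**Phylogenetic signal (D statistic).** False-positive status is a binary
trait on the tips of a phylogeny. The observed sum of sister-clade
differences d_obs (nodal values by branch-length-weighted averaging) is
scaled between a tip-permutation calibration and a Brownian-threshold
calibration:

    D = (d_obs − mean d_Brownian) / (mean d_random − mean d_Brownian)

D ≈ 1 means errors are phylogenetically random; D ≈ 0 means they cluster
like a Brownian trait; values outside [0, 1] are legal and reported as-is.

**Rarity model.** Species-level false-positive status (1/0) is modelled with
a Bernoulli GLM, logit link, against regional 4 km² occupancy, per site; the
intercept is back-transformed with the inverse logit and the slope to an
odds factor per unit occupancy, with a central-third goodness-of-fit probe.

**Synthetic world.** A generative model of the whole setting — regional
flora with genus structure and occupancy, sites of ~100 species, observers
with varying skill and false-positive propensity (~3–4% of records),
rarity- and genus-size-biased errors, cautious and mythical records, Yule
trees and binary traits — with full ground truth, so every estimator in the
pipeline can be validated against known parameters.

## Worked example

```python
import numpy as np
from surveyerr import synthetic_world as sw, records_io as rio, detection_stats as ds
from surveyerr import survey_combiner as sc, rarity_model as rm, phylo_signal as ps

world = sw.generate_world(sw.WorldConfig(seed=0))
surveys = sw.simulate_dataset(world, surveys_per_site=20, seed=1)
checklist, genus_index = world.checklist()
classified = [rio.classify_survey(s, world.reference(s.site_id), checklist, genus_index)
              for s in surveys]
by_site = {}
for s in classified:
    by_site.setdefault(s.site_id, []).append(s)
refs = {site: rio.build_site_reference(site, world.sites[site], svs)
        for site, svs in by_site.items()}

rate = np.mean([ds.observer_fp_rate(s) for s in classified])
print(f"mean false-positive rate per survey: {100 * rate:.1f}%")

svs, ref = by_site["site01"], refs["site01"]
rule = sc.AcceptanceRule("all_of_k")
fp1 = sc.bootstrap_combination(svs, ref, 1, rule, 10_000, seed=2).mean_fp
fp2 = sc.bootstrap_combination(svs, ref, 2, rule, 10_000, seed=2).mean_fp
print(f"mean FP per survey: {fp1:.2f}; per 2-survey combination: {fp2:.3f} "
      f"({100 * fp2 / fp1:.0f}% of a single survey)")

tab = rm.fp_binary_table(svs, ref, world.attributes())
fit = rm.fit_fp_vs_occupancy(tab, "site01")
print(f"site01 logit fit: intercept (inverse-logit) = {fit.intercept_bt:.3f}, "
      f"odds factor per unit occupancy = {fit.slope_bt:.2e}")

tree = sw.species_tree(world, seed=3)
tp, fp = set(), set()
for s in svs:
    tp |= s.species_set(("true_positive",))
    fp |= s.species_set(("false_positive",))
trait = {t: 1 for t in fp} | {t: 0 for t in tp - fp}
pruned, _ = ps.prune(tree, sorted(trait))
res = ps.d_statistic(pruned, trait, n_perm=1000, seed=4)
print(f"site01 D = {res.D:.3f} (p_random = {res.p_random:.2f}, "
      f"p_brownian = {res.p_brownian:.2f}, n = {pruned.n_tips})")
```

Output:

```
mean false-positive rate per survey: 4.1%
mean FP per survey: 1.31; per 2-survey combination: 0.005 (0% of a single survey)
site01 logit fit: intercept (inverse-logit) = 0.649, odds factor per unit occupancy = 7.63e-04
site01 D = 1.078 (p_random = 0.65, p_brownian = 0.00, n = 118)
```

Reading this: observers fabricate about 4% of their records; requiring a
species to appear in both of two combined surveys removes essentially all
false positives (at a cost in false negatives, which the threshold sweep
quantifies); the odds of a false positive fall steeply with regional
occupancy (rare species are the risky ones, with an estimated FP probability
of 0.65 for a species effectively absent from the region); and D near 1 says
the errors show no phylogenetic pattern — exactly the structure this world
was generated with.

The same analyses are available from the shell:

```sh
surveyerr simulate --out-dir fixtures --seed 0
surveyerr classify --surveys fixtures/surveys.csv --reference fixtures/reference.csv \
    --attributes fixtures/attributes.csv --out classified.csv
surveyerr combine --classified classified.csv --reference fixtures/reference.csv \
    --site site01 --k-max 5 --nboot 10000 --seed 42 --out sweep.csv
surveyerr run --config run.yaml          # the full pipeline + JSON manifest
```

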