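# Methods

This note documents the statistical procedures implemented in `surveyerr`,
the choices made where the design was genuinely open, and what the
synthetic-data validation does and does not establish.

## Record classification

A record is a written taxon name in one observer's survey of one site.
Normalisation case-folds the genus, collapses whitespace, strips authorship
strings (any capitalised or punctuated token after the epithet), drops
hybrid signs, and truncates infraspecific epithets to the parent binomial
(analysis is at species level throughout). Matching is exact: there is no
fuzzy matching, on the view that the unmatched set *is* the "mythical"
category; a user-supplied synonym table is the only rescue mechanism.

Categories: a valid species on the site's accepted list is a true positive;
a valid regional species not on it is a false positive (the "unreasonable /
known incorrect" flavour survives only as an optional flag — every analysis
treats the class as one); a genus-only name is cautious; an unmatched name
is mythical. One convention worth stating: cautious requires *both* genus
rank and a genus-index match, so a genus-rank token absent from the genus
index is mythical (rank as written, matched name absent). Classification is
total — every record gets exactly one category — and within a survey
duplicate species records collapse to one.

Survey scoring is (true positives + 0.5 per distinct cautious genus −
w × false positives) / gold-standard total. The penalty weight w defaults to
0 and the false-positive count is reported separately, because the official
grading scheme's deduction per error is not public; w is a config parameter.

## Detection probabilities and cross-site summaries

Detection probability is detections / surveys at the site — a raw ratio,
deliberately not a latent-state occupancy model, computed for every species
either accepted or recorded at the site, with false-positive species
flagged. An observer's FP rate is FP / (TP + FP); cautious and mythical
records are excluded from the denominator (and from every downstream
species-level statistic).

Sites differ in composition and habitat, so they are treated as independent
replicates: each correlation analysis computes one coefficient per site and
summarises them as mean ± t(1−α/2, n−1) · sd/√n. Pearson's r is the default
(a config switch selects Spearman); sites with a constant variable are
excluded with a warning. Four pair extractions feed this summary: FP vs
correct per observer, genus FP total vs genus size, cautious count vs genus
size, and cautious vs FP per observer.

## Bootstrap survey combination and the confusion calculus

A combination of k surveys accepts a species under one of three rules:
present in all k, in at least m of k, or in any (union). Cautious records
never count toward agreement. Means of TP/FP/FN are estimated over 10,000
resamples; each resample draws k *distinct* surveys uniformly without
replacement (a survey combined with itself is meaningless for an agreement
rule), with replacement across resamples. The accepted-set nesting
all-of-k ⊆ at-least-m ⊆ union holds per resample, so the mean FP chain is
monotone whenever the rules share a resample stream; a root seed spawns an
independent, reproducible substream per (k, rule) sweep cell. For pools of
up to a few dozen surveys an exhaustive enumerator over all C(S, k)
combinations is provided; the bootstrap is checked against it.

True negatives have no natural denominator in an open flora. The package
follows the convention of using the site's cumulative false-positive pool —
every species ever recorded there in error, a set of regionally plausible
absentees — so tn = |fp_pool| − mean FP, sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP). The absolute specificity depends on this
admittedly arbitrary pool; comparisons across thresholds do not. The pool is
computed from *all* surveys at the site regardless of which are resampled,
which also guarantees mean FP ≤ |fp_pool| (violations raise an integrity
error rather than clamping).

## D statistic

Binary-trait phylogenetic signal is measured by the scaled sum of
sister-clade differences. The observed d is computed by a single
Felsenstein pruning pass: tips carry their states; an internal node's value
is the average of its daughters weighted by the reciprocals of their
*extended* branch lengths (each daughter's length augmented by the parallel
combination of its own daughters' lengths, the standard contrast
correction); each node contributes the absolute difference of its two
daughter values, generalised at polytomies to the mean absolute pairwise
daughter difference. Zero-length branches are floored at 1e-8 of tree
height so the weights stay finite.

Calibration uses n_perm (default 1000) tip permutations with prevalence
fixed, and n_perm Brownian simulations (root state 0, variance ∝ branch
length) dichotomised at the order statistic matching the observed
prevalence, ties broken by draw order. Then
D = (d_obs − mean d_B)/(mean d_R − mean d_B). The construction is
self-calibrating: whatever the averaging scheme, a randomly permuted trait
has expectation 1 and a Brownian-threshold trait expectation 0, which the
test suite verifies to ±0.1 over 200 replicates on 200-tip trees; a 4-tip
hand-worked example pins the averaging scheme itself. D is never clamped —
overdispersed traits legitimately exceed 1. p_random is the fraction of
permutation d values ≤ d_obs (small for clumped traits); p_brownian the
fraction of Brownian d values ≥ d_obs (small for random-like traits).
Fewer than 100 calibration draws triggers a warning; a constant trait, or a
tree where the two calibration means coincide, is an error.

Pruning to the surveyed species keeps patristic distances intact
(unbranched nodes collapsed, lengths summed) and *reports* names missing
from the tree rather than dropping them; reconciling survey taxonomy with
tree taxonomy is the caller's decision. For genus-level (cautious) signal,
the trait marks a configurable genus-representative tip set where the genus
received at least one cautious record, since no single canonical choice
exists.

## Rarity model

Per-species FP counts are dominated by zeros and ones, so the response is
binary: species recorded at the site are scored 1 (false positive) or 0
(true positive) and modelled with a Bernoulli GLM, logit link, against
regional 4 km² occupancy, fitted by IRLS per site, never pooled. The
intercept back-transforms through the inverse logit — interpretable as the
FP probability of a species effectively absent from the region — and the
slope through the exponential, an odds factor per unit occupancy. The
occupancy covariate is a proportion in [0, 1]; because published
coefficient magnitudes are sensitive to this scaling, the scale used is
recorded on every fit and configurable. Wald intervals are reported;
standard errors above 50 (or non-finite) flag probable complete separation
instead of failing. Goodness of fit is probed on the central third of the
occupancy-sorted species: observed FP proportion ± binomial SE against the
model prediction at the subgroup's mean occupancy.

## Synthetic world

The generator is first-class, tested code, and the test-bed for the whole
pipeline. It emulates: a regional flora of 1000 species in 200 genera
(geometric genus sizes, p = 0.2, adjusted to conserve the total); regional
occupancy Beta(0.8, 2.5) (right-skewed — most species uncommon); sites of
100 species drawn occupancy-weighted without replacement; observers with
skill Beta(4, 2) (the fraction of detected species they can name) and
per-observer FP intensity Gamma(1.5, λ/1.5).

Two defaults are calibrated rather than free. The realized per-species
detection probability is detectability × mean skill × species-rank
retention ≈ 0.63 × detectability, so detectability is Beta(1, 0.9), which
puts ≈75% of realized detection probabilities below 0.5 while spanning
0–1. λ = 1.2 expected FP records per survey yields ≈3–4% false-positive
records against the ≈33 correct records per survey the other defaults
imply. Both were solved in closed form from the target magnitudes.

Each survey detects every present species independently with probability
detectability × skill; draws Poisson(λ_obs) false positives from the
regional pool outside the site with weight ∝ (1−occupancy)^γ ×
genus_size^δ (defaults γ = 1, δ = 0.5); degrades would-be species records
to genus with probability 0.05; and corrupts FP names to invalid
genus–epithet combinations with probability 0.01. FP selection is
phylogeny-agnostic by default — the null against which a D ≈ 1 finding is
the expected outcome; trees (pure-birth, unit depth) are simulated
independently of the error process.

What the generator does *not* emulate: spatial structure within sites,
seasonal or habitat-dependent detectability, observer learning across
surveys, correlated errors between observers (e.g. shared look-alike
confusions), and imperfect reference lists. Passing tests therefore show
that the estimators recover the parameters of *this* error structure; they
do not certify behaviour under reference-list error or non-independent
observers, which real campaigns may exhibit.

## Problem sizes and numerical choices

The test suite and the acceptance script run at: 10,000 bootstrap
resamples (enumeration-equivalence checks on 6-survey pools, tolerance 3
Monte-Carlo SEs); 200 replicate traits × 1000 calibration draws on 200-tip
trees for the D calibration; 200 replicate logit fits at n = 250 for
parameter recovery (coverage ≥ 90% of nominal 95% Wald intervals, and
agreement with an independent BFGS maximum-likelihood solver to 1e-6); and
a six-site, 20-surveys-per-site world for end-to-end recovery. These sizes
keep every check comfortably inside a coffee break on one CPU while leaving
Monte-Carlo error well below the tolerances tested.

All randomness flows through `numpy.random.Generator` seeded explicitly;
sweep cells and pipeline stages derive independent child streams from a
single root seed via `SeedSequence`, so any cell reruns bit-identically in
isolation. File I/O uses pandas for delimited tables and dendropy for
Newick.

## Known limitations

- Exact name matching means misspellings without synonym entries inflate
  the mythical category; that mirrors how unmatched names behave in real
  digitisation, but users with dirty data should supply a synonym table.
- The specificity's true-negative pool is a convention, not an estimate;
  only threshold comparisons are meaningful.
- The D statistic's Brownian calibration assumes the supplied branch
  lengths are meaningful (time- or rate-proportional); topology-only trees
  will distort the Brownian mean.
- Per-site logistic fits with few false positives can be separated or
  unstable; the separation flag should be checked before interpreting CIs.
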