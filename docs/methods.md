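# Methods

## Problem and data model

Shotgun label-free metaproteomics of cervicovaginal lavage (CVL) fluid
yields, after run alignment and database search, (i) per-protein peptide
evidence (total and unique peptide counts, search confidence, and for
marginal identifications a differential-abundance ANOVA p-value and a
fragment-ion-series check), and (ii) a protein × sample matrix of
normalized total ion intensities ("relative abundance", unitless). Sample
metadata carry a vaginal-microbiota (VMB) group label from prior 16S rDNA
microarray clustering — *L. crispatus*-dominated (G1), *L. iners*-dominated
(G2), moderate dysbiosis (G3), severe dysbiosis (G4) — a vaginal pH strip
reading on a 0.5 grid over [2, 9], and per-taxon semi-quantitative 16S
abundances as normalized signal/background (S/B) ratios with a detection
call. Upstream acquisition, peak picking, searching, and VMB clustering are
outside this package's scope: their outputs are its inputs.

Missing intensities are stored as explicit zeros (an undetected protein in
a label-free run has zero intensity, not NA). 16S positivity defaults to
S/B > 0 — a microarray S/B of zero means no hybridization signal — and can
be overridden by explicit `pos:` columns.

## Evidence filter

A protein is retained iff

    unique >= 1  AND  total >= 2  AND
    (unique >= 2  OR  (anova_p < 0.05 AND fragment_series_ok))

The ANOVA threshold is strict (`<`, not `<=`). The fragment-ion criterion
("a series of >= 4 continuous fragment ions on manual MS/MS inspection")
enters as a boolean flag because spectra are out of scope; a record with
one unique peptide and *missing* rescue metadata fails with reason
`insufficient-evidence-metadata` — the conservative choice. The filter is
monotone in both peptide counts and order-independent; the test suite
checks it exhaustively against an independently coded truth table.

## Species-specificity classifier

Candidate set from the search best match: the species itself, or both
species for a "multispecies" match, or empty otherwise. For each candidate
species the *target* group is the species-dominated cluster (G2 for
*L. iners*, G1 for *L. crispatus*; a config switch restricts the target to
its 16S-positive members) and the *reference* group is every sample
16S-negative for the species, across all clusters. The criteria, computed
on raw (untransformed) intensities:

* fold criterion: mean(target) / mean(reference) >= 2 (inclusive);
* median criterion: median(target) >= median(reference) (inclusive).

Zero conventions: positive target mean over zero reference mean is an
infinite fold change and passes; two zero means fail the fold criterion, so
an entirely undetected protein is nonspecific. A multispecies protein
passing both species' criteria is assigned to the species with the larger
fold change; an exact tie (including two infinities) falls back to
nonspecific. The tie-break is a design choice — the published criteria
never state one, and no real double pass is documented — and is
configurable to "always nonspecific".

The reference-group definition follows the stated condition ("women
without the species by 16S") rather than the narrative description of which
clusters those women sit in; the two differ because a minority of women in
the other dominated cluster are positive for the species.

Decisions are scale-invariant (multiplying a protein's row by c > 0 changes
nothing) and monotone in target intensities; both are property-tested, and
the full decision function is tested for exact agreement with a brute-force
re-evaluation of the criteria on enumerated small instances.

## Cohorts, pH categories, abundance strata

Comparative analyses for a species include only its 16S-positive samples,
grouped by VMB group (groups with n = 0 are reported and skipped in
testing). Vaginal pH is binned half-open on the left label's upper edge:
"4–5" = [4, 5), "5–6" = [5, 6), ">=6" = [6, 9]; with the cohort median pH
of 5 and published bin sizes 7/18/6, a reading of exactly 5 must fall in
"5–6", which fixes the boundary convention. The two-bin scheme for
*L. crispatus* is [4, 5) and [5, 9]. Readings below pH 4 (none occur in the
observed 4–7 range) map to the lowest bin with a logged warning.

*L. iners* abundance strata use strict inequalities — high = S/B > cut —
for both the cohort-median split (ties at the median go low) and the fixed
S/B > 70 threshold, mirroring the ">" wording of the fixed rule.

## Statistics

**Mann–Whitney battery.** All group, pH-category, and stratified
comparisons are two-sided Mann–Whitney U tests (scipy). The p-value is
exact (full enumeration) when the combined n is <= 25 and the pooled values
are tie-free, otherwise the normal approximation with tie correction and
continuity correction. The switch is deterministic, so a given input and
configuration reproduce p-values bit-for-bit. Two identical samples give
p = 1 by convention. Raw p-values are reported without multiplicity
adjustment by default, matching how such pairwise batteries are typically
reported; Holm adjustment is available behind a flag. Significance stars:
\* p < 0.05, \*\* p < 0.01, \*\*\* p < 0.001.

**Regression.** For *L. iners* proteins associated with dysbiosis in the
bivariable battery (configurable to all or none), ordinary least squares of
log10 intensity on VMB-group dummies (reference G2), pH-category dummies
(reference "4–5"), and log10 *L. iners* S/B, fitted on the *L. iners*
analysis cohort (statsmodels). CIs use the t-distribution with residual
degrees of freedom. Zeros are replaced by half the protein's smallest
positive intensity (respectively half the cohort's smallest positive S/B)
before the log — a standard half-minimum pseudo-value; the choice matters
only when a cohort sample lacks the protein entirely. Residual normality is
reported via Shapiro–Wilk and logged as a warning below 0.05, not treated
as a failure. A rank-deficient design (e.g. an explicitly declared pH level
with zero samples) raises an error naming the aliased terms rather than
silently dropping them. The Shapiro–Wilk helper rejects n < 3 and constant
vectors, for which the statistic is undefined.

## Synthetic-data generator

The generator emulates the study design so that every downstream stage can
be validated against planted truth. Defaults: group sizes 7/11/14/18
(n = 50); per-group species-positivity rates equal to the published
fractions (e.g. *L. iners* 0, 1, 12/14, 8/18 across G1–G4); S/B ratios
log-normal (log10 mu ~2.0 in the dominated cluster, lower in dysbiosis,
sigma 0.35–0.45); group-specific pH distributions on the 0.5 grid spanning
4.0–7.0 with dysbiotic groups skewed high; 7 *L. iners*-specific, 11
*L. crispatus*-specific, and 22 nonspecific proteins, with a multispecies
best-match probability of 0.2.

Intensities are generated on the log10 scale: base 5.0, species effect
+1.5 in species-positive samples, dysbiosis effect −0.5 in G3/G4, pH effect
−0.3 per (three-bin) pH category step, Gaussian noise sd 0.25. Samples
negative for a specific protein's species draw pure background
(base + noise): the protein is simply absent there. Nonspecific proteins
omit the species term but keep the dysbiosis and pH terms for all samples,
like shared *Lactobacillus* proteins tracking overall community state. The
default effect magnitudes were chosen to mirror the *direction and rough
scale* of published group/pH coefficients on log10 intensity (tenths of a
log10 unit for group/pH, an order of magnitude or more for species
presence) without copying any fitted value, which the source data do not
identify at desk scale.

Randomness is split into three sub-streams (samples, proteins, matrix)
spawned from the single seed, so changing the protein count does not
perturb the cohort. Everything downstream of the seed is deterministic;
the end-to-end pipeline writes byte-identical bundles on reruns.

What the generator does *not* emulate: peptide/spectrum level structure,
missingness mechanisms other than species absence (real label-free data
have intensity-dependent missingness), between-protein correlation, strain
heterogeneity, and compositional coupling between taxa. Passing
recovery/calibration tests therefore validates the pipeline's logic and
its statistical calibration under the assumed model, not its performance on
raw mass-spectrometry data.

## Validation experiments

* **Classifier recovery** (`validation.classifier_recovery`): 20 seeds,
  25 samples per group, species effect 1.5, noise 0.25, dysbiosis and pH
  effects zero. The experiment plants only the species signal so it
  measures the classifier itself. Expected: >= 95% of planted specific
  proteins recovered, <= 5% of nonspecific proteins assigned to any
  species; observed in practice: essentially 100% / 0%.
* **Mann–Whitney calibration** (`validation.mannwhitney_type1_rate`): 1000
  null proteins, 50-vs-50 samples in the two compared groups (the
  asymptotic branch used at realistic cohort sizes); rejection at nominal
  0.05 should land in [0.035, 0.065]. The group size was fixed at design
  time as the configuration whose true test size is closest to nominal;
  at exact-enumeration sizes the attainable size is discrete and
  conservative, which would measure discreteness rather than calibration.
* **Regression coverage** (`validation.regression_ci_coverage`): 25
  datasets × 20 planted *L. iners* proteins = 500 fits; the 95% CIs of the
  two group dummies and two pH dummies are checked against their planted
  values, pooled over all 2000 intervals (coverage is exactly 95% under the
  correctly specified model; observed ≈ 94–95%).

Problem sizes (20 seeds, 1000 nulls, 500 fits) are the experiments' own
design choices, large enough for the Monte-Carlo error to be well inside
the asserted bands.

## Known limitations

* The published specificity criteria compare a favourable target cluster
  against a reference that pools dysbiotic samples. When a global negative
  dysbiosis/pH effect acts on *nonspecific* proteins (as the generator's
  confounded default regime does), the *L. crispatus* mean-fold criterion
  can pass spuriously, because G1 is the only non-dysbiotic, low-pH group
  left out of its reference. This is a property of the criteria themselves,
  not of this implementation; the recovery experiment deliberately isolates
  the species signal, and users should interpret crispatus assignments
  under strong global confounding with care.
* The fixture cohort reproduces every published marginal (group sizes,
  positivity patterns, pH bin sizes, median/range, stratum size), but its
  per-sample pH and S/B values are synthetic reconstructions: analyses that
  depend on the joint distribution beyond those marginals are exercised,
  not reproduced.
* Whether the original pairwise tests used exact or asymptotic p-values is
  not stated; this package's deterministic switch is documented above so
  results are reproducible within it.
* No protein-grouping/parsimony inference, no peptide-level uniqueness
  resolution, no multiple-testing correction by default.
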