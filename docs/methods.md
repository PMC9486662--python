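# Methods

`hapticrec` implements an admission-time procedure for predicting whether
apperceptive tactile agnosia after a first ischemic sensori-motor stroke
will persist or resolve, together with white-matter disconnection analytics
for binary lesion masks and an analysis of interhemispheric haptic
transfer. Because no patient-level data are distributed, the package ships
a synthetic-cohort generator that emulates the study conditions; every
stage of the pipeline is exercised end to end on generated data.

## Study design being modelled

Thirty-six patients with first sensori-motor stroke are classified by their
tactile object recognition (TOR; objects correctly identified out of 30 by
the affected hand) nine months after stroke: TOR-normal (TN, n = 22),
recovered impairment (RTI, n = 7, ≥ 50% correct at nine months) and
persistent impairment (PTI, n = 7, < 50%). At admission the two impaired
subgroups are not separable on any single measure. The procedure asks
whether a *pattern* over admission measures — age, lesion volume, NIHSS,
cutaneous pressure perception threshold (PPT), micro- and macrogeometrical
discrimination (MIC, MAC), picking-small-objects time (PSO) and TOR —
predicts the nine-month class.

## Behavioral preparation

Behavioral measures are z-scored against gender- and hand-matched healthy
controls; the patient's affected hand is matched to the corresponding
control hand. Measures where larger raw values mean worse performance (PSO
seconds, PPT threshold) are sign-flipped so that more negative z always
means more impaired. PPT is compared on the log10 scale because
monofilaments are graded logarithmically; a linear comparison would let the
four-decade PPT range swamp every other measure. Age and lesion volume are
z-scored within the 14 impaired patients (the PCA sample; configurable);
NIHSS enters raw, its magnitude being already z-like. Patients with plegic
fingers cannot perform the timed PSO test at admission; their missing value
is imputed with the slowest time observed in their subgroup — a
conservative lower bound on how slow they would have been (an alternative
`trajectory_intercept` strategy is reserved for longitudinal trajectory
data and falls back with a warning).

## The PCA cascade

Each stage fits a PCA on the mean-centred (not re-scaled) z-matrix of the
14 impaired patients. Components are admitted up to 80% cumulative
explained variance. An admitted component is *salient* when its patient
scores correlate with nine-month TOR at p < 0.05 (Pearson by default,
Spearman by option). Among salient components, the one whose scores best
discriminate RTI from PTI (largest Kruskal-Wallis χ²) carries the stage —
discrimination is the procedure's purpose, and the correlation gate alone
often admits both a general-severity component and the discriminating one.

Measures carrying *dominant* expression coefficients are retained for the
next stage. Dominance is |coefficient| ≥ 0.6 × the component's largest
|coefficient| (configurable); retention pools the dominant measures of all
admitted salient components. When dominance cannot shrink the measure set,
or would shrink it below three, the stage falls back to the top three
measures ranked by |coefficient| pooled over the salient components. The
cascade stops at three measures (or when no component is salient —
flagged inconclusive).

Micro- and macrogeometrical discrimination probe one construct at two
spatial scales, so a three-measure pattern admits at most one of them:
candidate patterns containing both have either task swapped for the
next-dominant measure, candidates containing one are compared against the
swap, and the candidate with the larger terminal Kruskal-Wallis χ² wins.
Ties prefer the macro (shape) task, the construct closest to object
recognition. Component signs are fixed so the TOR coefficient is
non-negative, making recovered patients score higher.

The terminal stage yields a patient-score threshold: the midpoint of the
gap when the groups separate perfectly, otherwise the Youden-optimal
threshold on the original scores.

## Permutation validation and ROC

The observed values of the three terminal measures are recombined within
each impaired subgroup as a full Cartesian product (7³ = 343 simulated
triples per subgroup). Triples whose squared Mahalanobis distance to the
TN subgroup's mean (TN sample covariance, n−1 estimator) falls outside the
range spanned by the subgroup's original patients are discarded — original
patients are accepted by construction. Accepted triples are projected onto
the salient component; the combined simulated-score distributions yield an
ROC curve ("score ≥ threshold → recovered"), its trapezoidal AUC (equal to
the Mann-Whitney U statistic over n₁n₂ — tested), and the Youden-optimal
operating point (ties broken toward the smaller false-positive rate), with
balanced accuracy (TPR + 1 − FPR)/2.

## Lesion and tract analytics

All volumes share one isotropic grid (0-based indices, RAS axes); no
registration is performed. Conjunction maps count voxels lesioned in at
least ⌈fraction·n⌉ patients (71.4% of 21 patients → 15). Masks may be
smoothed with an isotropic Gaussian read as FWHM in mm. For a
probabilistic tract map, the *probability of disconnection* is the maximum
tract value under the lesion (> 0.5 flags disconnection) and the
*proportion* is the lesioned fraction of the tract's full positive extent
(threshold configurable). Disconnectome maps binarize each healthy
control's visitation map at half its own maximum; a control whose
territory intersects the lesion votes for that territory, and the map
value is the fraction of voting controls. Voxelwise lesion-behavior
mapping tests, inside a region of interest, every voxel lesioned in 2 to
n−1 patients with the Liebermeister quasi-exact measure (one-sided toward
lesion–impairment association, z-transformed); the family-wise threshold
is the 1−α quantile of the maximum-z distribution over outcome-label
permutations, with the fixed historical threshold z > 3.98 available.

## Small-sample statistics

Self-contained implementations (cross-checked against scipy where it
offers the same test): tie-corrected Kruskal-Wallis H; Mann-Whitney U with
a signed normal-approximation z (tie-corrected by default, no continuity
correction; the plain approximation is available because historically
reported z values for floor-tied score sequences match it); Friedman
χ² with within-subject average ranks and tie correction; pooled-variance
(default) and Welch t-tests and one-way ANOVA recomputed from published
(mean, SD, n) summaries; the Liebermeister measure (both concordant cells
incremented before the one-sided hypergeometric tail, plain Fisher p
always reported alongside); Bonferroni correction (p·m clipped at 1).

## Matching-task transfer analysis

Four sequences (uH:uH, aH:aH, aH:uH, uH:aH — presentation then matching
hand) at three visits, 10 objects each. Per group × visit: medians/ranges,
Mann-Whitney of each sequence against the affected-hand aH:aH reference
(Bonferroni, m = 3), and Friedman over sequences per visit and over visits
per sequence. Directionality: difference scores of the alternated-hand
sequences against aH:aH with two-sided sign tests; the group flag calls a
transfer direction restored when its last-visit median reaches the
unaffected-hand level within two objects — both directions restored is
bidirectional, only unaffected-to-affected is unidirectional.

## The synthetic cohort generator

**Marginals.** Each subgroup × measure score follows a split truncated
normal: the published subgroup median is the location, the published range
the support, and each half-range spans 3 SDs of its half-normal
(`marginal_spread`), concentrating mass near the median. When the median
sits on a bound (e.g. PTI MAC median 0), that half hugs the bound in a
narrow band rather than collapsing to an exact point mass, so
within-subgroup ranks survive; TOR counts are still rounded to integers
and floor ties occur as in real data. The roughness task (MIC) spans its
range more fully (spread override 1.5), and TOR at admission uses spread
1.8 so the impaired subgroups' admission ranges overlap, as published.

**Dependence.** A Gaussian copula couples measures within each patient
through two latent factors: sensori-motor severity `s` (loads PSO 0.90,
PPT 0.92, NIHSS 0.92, lesion volume 0.60) and tactile-discrimination
deficit `v` (loads MAC 0.90, TOR 0.75, nine-month TOR 0.80, MIC 0.31, and
PSO −0.25: at fixed severity, the agnosic phenotype has relatively
preserved motor speed but poor discrimination). Age is independent. These
loadings, together with the control-reference spreads below, were fixed
once at design time by simulating cohorts until the generated z-matrices
showed the intended structure — a high-variance severity axis that
separates the outcome groups only weakly, and an outcome-linked
discrimination direction — and are not tuned per run.

**Control reference.** Healthy controls (default 20, both hands, gender
split) are summarized per measure × gender × hand. MAC controls are tight
(SD 0.04) so cell means stay in the published 0.92–0.97 discrimination
band; MIC controls are deliberately wider (SD 0.22) than the published
healthy band so that roughness z-scores do not dominate the shape task —
a generator design choice, not an empirical claim about controls. PSO and
PPT control levels derive from the TOR-normal column of the published
tables (no healthy values are published for them); PPT is parameterized on
log10 g/mm². Non-dominant hands are slightly slower and weaker. Cells
with fewer than two same-gender controls fall back to the whole control
sample so SDs stay positive.

**Lesions and tracts.** The toy atlas holds three tubular probabilistic
tracts on the configured grid (default 48³ at 2 mm): an anterior arcuate
fasciculus arcing through the right hemisphere, an SLF III interlacing
with it (≈ 30% shared voxels at the default grid), and a corpus callosum
crossing the midline; plus cortical patches (PFt, OP1, Area 4p) marking
lesion cores. Per patient, a fractional-overlap target with the anterior
arcuate tract is drawn from the subgroup's truncated normal
(means/SDs 0.68/0.21, 0.27/0.24, 0.10/0.15) and the draws are recentred so
the subgroup sample mean equals the configured mean; the mask claims
exactly that many tract voxels around a random on-tract seed, then adds a
dilation rim and the subgroup's cortical patches strictly outside the
tract, so the achieved overlap is exact to one voxel. Corpus-callosum
overlap is not separately targeted. Visitation maps for disconnectome
construction are per-control jittered copies of the atlas.

**What the generator does not emulate.** Real lesion geometry and
neuroanatomy; measurement error in the behavioral scores beyond the
published ranges; correlations between behavioral severity and lesion
topography (behavioral and lesion generators share only the subgroup
labels); item-level object responses. Passing tests therefore demonstrate
that the pipeline recovers structure planted to the published group
moments — not clinical validity on real cohorts.

## Numerical choices

- PCA via SVD of the centred matrix; components beyond the data rank carry
  zero variance and flag the result rank-deficient.
- Mahalanobis filtering requires a numerically invertible TN covariance
  (condition number ≤ 1e12) and at least four TN rows.
- ROC thresholds sweep the unique scores with anchors at (0,0) and (1,1);
  AUC by trapezoid after sorting by FPR then TPR.
- Liebermeister p-values are clipped to [1e-300, 1−1e-16] before the
  normal quantile so z stays finite.
- Seeds: every generator draws from independent streams spawned from the
  config seed, so changing one product (e.g. the number of controls) never
  perturbs another.

## Known limitations

With n = 7 per impaired subgroup and the published, strongly overlapping
group ranges, the cascade's terminal measure set is itself a random
variable: across seeds roughly two-thirds of synthetic cohorts terminate
at the MAC/PSO/TOR pattern, the remainder ending at a neighbouring pattern
(the MIC variant, a clinical covariate in third place, or an inconclusive
stage). The permutation-validated discrimination is much more stable: the
optimal-point balanced accuracy exceeds 0.80 in over 90% of cohorts. On
the default cohort the discriminating component is usually the *first*
principal component of the terminal PCA — with group shifts this large
relative to within-group spread, severity and discrimination directions
fuse; in the original sample they separated and the second component
carried the pattern.
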