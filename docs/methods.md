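# Methods

This note documents the models, conventions and numerical choices behind
`svrlsm`, and what its synthetic validation does and does not establish.

## The analysis model

The package relates behavior in two verbal working-memory domains to the
spatial pattern of brain lesions across a patient cohort.

**Behavioral variables.** Phonological working memory (PWM) is indexed
by forward digit span: the longest list length at which both of two
lists are repeated correctly, plus 0.5 for each isolated correct list at
longer lengths (so perfect performance at length 2 plus one correct list
at length 3 scores 2.5). Orthographic working memory (OWM) is indexed
through spelling, scored at the letter level: a response's accuracy is
`1 − d / max(|target|, |response|)` with `d` the Damerau–Levenshtein
distance (unit-cost substitutions, insertions, deletions and adjacent
transpositions, freely composable — the Lowrance–Wagner unrestricted
distance, chosen because it equals the minimum length of an edit script
under exactly those operations). COAT → COET scores 0.75; COAT → CUAD
scores 0.50; a transposition counts as a single letter error, consistent
with graphemic-buffer error taxonomies.

**Deficit typing.** Spelling deficits are typed from two 2×2 chi-square
tests on letters correct vs incorrect (no continuity correction, which
would make a flat table's p of exactly 1.0 unreachable): a frequency
split (low < 15 vs high > 60 occurrences per million) and a length split
(4–5 vs 7–8 letters). Words outside both bins of a split (6-letter or
mid-frequency words) are excluded from that test, matching graded
spelling-battery design. Frequency sensitivity and/or phonologically
plausible errors (supplied as a flag; no algorithmic detector is
attempted) mark an orthographic long-term-memory (OLTM) deficit; length
sensitivity marks an OWM deficit. When trial-level data are available,
an effect only counts in the deficit-consistent direction (low-frequency
or long words *worse*); when typing from printed p-values alone the
guard cannot be applied. The packaged 37-participant behavioral table
contains six rows whose printed deficit label disagrees with a pure
α = 0.05 rule on the printed p-values; `table3_discordances()` lists
them rather than relabeling, since the published labels reflect
adjudications not recoverable from the summary statistics.

**The categorical OWM variable.** Selective OWM participants are coded
−1, selective OLTM participants +1; the variable is demeaned over the
coded participants; dual-deficit participants are then set to 0. The
demeaning scope (coded participants only, the default, versus the whole
cohort with duals provisionally at 0) is configurable because the order
of the two operations is genuinely ambiguous; the default follows the
reading in which dual-deficit cases carry no value at the demeaning
step. Participants with no spelling deficit are excluded from this
analysis by construction.

**Lesion matrix.** Masks must share one grid and affine; a mismatch is
an error, never a silent resample (spatial normalization is upstream of
this package). Voxels lesioned in at least `min_overlap = 4`
participants form the design matrix; an optional user-supplied analysis
mask (e.g., gray matter) restricts the voxel set, applied before the
overlap criterion by default (the operations commute on the surviving
voxels, so the order only affects bookkeeping).

**SVR-LSM.** An epsilon-SVR models the (residualized) behavioral score
as a function of all included voxels at once. Voxel importance is the
back-projection of the dual solution, β_j = Σ_i α_i x_ij over support
vectors — for a linear kernel exactly the primal weight vector, for the
RBF kernel the standard multivariate lesion-mapping readout (exact
feature-space gradients are not computed). Defaults follow the
established SVR-LSM toolbox lineage: RBF kernel, C = 30, γ = 5,
ε = 0.1, solver tolerance 1e-3; all configurable and recorded in the
run's provenance JSON. Nuisance covariates — age, gender (a binary
indicator treated like any covariate), lesion volume in cc, plus the
domain-specific long-term-memory control (PPVT percentile for the PWM
analysis) — are z-normalized (population SD, per the "divided by the
group standard deviation" convention; sample SD available) and
regressed out of the behavioral score by OLS before fitting. Two
alternatives exist behind flags, both off by default: regressing
covariates out of every voxel column, and dTLVC (unit-norm scaling of
each lesion row). The fit is deterministic: libsvm's epsilon-SVR
involves no randomness.

**Orientation.** Each analysis declares a deficit direction. Digit span
and the OWM code both have "lower = worse" (selective OWM is the
negative pole), so scores are negated before fitting; a larger β then
always means a stronger lesion–deficit association, and significance is
assessed one-tailed in that direction. A two-tailed |β| option exists.
The choice is recorded in provenance.

**Inference.** The behavioral residuals are permuted across
participants (the lesion data, hence the kernel Gram matrix, is fixed —
computed once, which is what makes 5,000 refits cheap), the SVR is
refitted per permutation, and the 1st, 10th, 100th and 1,000th highest
β are recorded. The observed map is thresholded at the empirical
order-statistic quantile: the ceil((1−α)·n_perm)-th smallest null
sample, with strict inequality, so ties break conservatively. The
rank-1 (maximum statistic) null controls the family-wise error rate at
α; larger ranks give progressively lenient thresholds whose significant
sets are nested by construction. Permuting residuals (rather than raw
scores with per-permutation re-residualization, available behind a
flag) is the default; under the null hypothesis of no lesion–behavior
association the residuals are exchangeable. Clusters are connected
components of the significant set under 26-connectivity by default (6
and 18 available), reported with voxel count, mm³ volume, world-space
centroid and peak β, sorted by volume. Atlas labels are an optional
lookup in any user-supplied integer-labeled volume on the cohort grid;
no atlas ships with the package.

## The synthetic cohort generator

No raw lesion masks or item-level behavioral data are publicly
deposited for cohorts of this kind, so the package ships a generator
whose defaults define its study conditions: 37 participants on a
40×48×40 grid of 2 mm voxels (≈77k voxels, small enough that a full
permutation analysis runs in minutes; 1 mm grids work but are not the
default).

*Lesions* are unions of 1–3 spherical blobs with lognormal radii
(median ≈ 11 mm, clipped to 6–30 mm), Gaussian-smoothed (4 mm) and
re-thresholded for irregular borders, confined to the left half-grid.
Blob centers draw from one of two Gaussian "vascular territory" centers
of mass (posterior, covering critical regions A and C; anterior,
covering region B), emulating the clustered, volume-heterogeneous
distribution of middle-cerebral-artery stroke; volumes span well over a
five-fold range.

*Ground truth* is three disjoint spherical regions: A (8 mm radius)
drives digit span, B (8 mm) drives word-length sensitivity in spelling,
C (8 mm) drives word-frequency sensitivity. Region loads are the
lesioned fraction of each region.

*Behavior*: digit span = 7.0 − 6.0·load_A + age and gender terms +
N(0, 0.5), clipped to [0, 9], quantized to half points and realized as
an administration consistent with the two-lists-per-length stopping
rule (the baseline and loss are sized so that heavily lesioned
participants reach the severe spans of 0–2.5 seen in chronic aphasia,
from an unimpaired baseline near 7). Spelling uses a packaged 80-item
pseudo-word list (consonant–vowel frames, fully crossing the length
bins 4/5/7/8 with low/high frequency; synthesized once from a fixed
seed and shipped as CSV to avoid reproducing any published battery).
The per-letter error probability is 0.03 at baseline, + 0.35·load_B for
long words, + 0.35·load_C for low-frequency words, capped at 0.85;
errors are realized as substitutions (60%), deletions (20%) and
adjacent transpositions (20%), echoing graphemic-buffer error
mixtures. Because territory membership, blob spread and region overlap
interact, the generated cohorts contain OWM-selective, OLTM-selective,
dual-deficit and unimpaired spellers in paper-like mixtures — the
deficit taxonomy is emergent, not assigned. Phonologically plausible
errors are not simulated; the flag exists for classifier tests, and the
synthetic OLTM signature uses frequency sensitivity only.

Everything is reproducible from (config, seed): one `numpy` Generator
drives lesion and behavior sampling, and the analysis pipeline derives
per-analysis permutation seeds deterministically from the run seed.

## What the validation shows — and does not

The test suite establishes, at desk scale: exact reproduction of the
defining scoring examples and the cohort coding counts; equality of the
linear-kernel β map with an independently solved QP (SLSQP on the dual,
1e-4, using solver tolerance 1e-8 so solver slack does not dominate);
family-wise error calibration within the binomial 95% band around
α = 0.05 under null cohorts (200 replicates × 500 permutations);
recovery of each planted region by its own analysis (median Dice ≥ 0.3
at the strict threshold over 20 seeds; observed ≈ 0.5–0.6 for the span
analysis and ≈ 0.4 for the categorical OWM analysis) with negligible
cross-region leakage and strictly disjoint strict-rank significant
sets — the property-level analogue of a phonological/orthographic
dissociation; and threshold nesting across ranks on every run.
Acceptance-level recovery runs use 1,000 permutations; the pipeline
default remains 5,000.

These results validate the machinery, not the neuroscience: synthetic
lesions are spherical unions rather than vascular territories with
white-matter involvement, behavioral noise is Gaussian and
item-homogeneous, spelling errors are positionally independent, and the
planted regions are compact spheres. Passing tests therefore show the
pipeline recovers structure *of the kind the model assumes*; they do
not certify localization accuracy on real cohorts, where effect sizes
are smaller and lesion–anatomy correlations stronger.

## Known limitations

- Restricted cohort sizes: with n ≈ 37, the SVR's RBF kernel on raw
  binary vectors is near-diagonal, so the β map behaves like a
  lesion-weighted score sum; this matches the established toolbox
  behavior but limits genuinely multivariate attribution.
- The categorical OWM variable discards within-type severity; its
  analysis is intrinsically lower-powered than the continuous span
  analysis, visible in its lower recovery Dice.
- `ppe_present` is an input, not a detection; typing from summary
  p-values cannot apply the directionality guard.
- No spatial normalization, lesion tracing, or atlas distribution;
  masks must arrive registered, and cluster labeling requires a
  user-supplied labeled volume.
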