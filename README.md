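# svrlsm — multivariate lesion-symptom mapping of verbal working memory

`svrlsm` is a Python package for relating behavioral deficits to the
spatial pattern of brain lesions in patient cohorts, built around the
question of whether phonological and orthographic working memory have
distinct neural substrates. It takes binary lesion masks (NIfTI, on a
shared grid) and raw behavioral records — digit-span administrations and
trial-level spelling responses — and produces FWER-thresholded voxelwise
association maps and cluster tables for two analyses:

- **PWM** (phonological working memory): forward digit span, scored as
  the longest list length with both lists correct plus 0.5 per isolated
  correct list at longer lengths, with a picture-vocabulary covariate
  controlling phonological long-term memory;
- **OWM** (orthographic working memory): a categorical variable coding
  selective orthographic-WM deficits (−1) against selective
  orthographic-long-term-memory deficits (+1), demeaned, with dual
  deficits at 0. Deficits are typed from letter-level spelling accuracy
  (Damerau–Levenshtein distance normalized by word length) via
  chi-square tests of word-frequency and word-length sensitivity.

The core statistic is support vector regression LSM: behavior (with
age, gender and lesion volume z-normalized and regressed out) is
modeled by an epsilon-SVR over all included voxels at once (voxels
lesioned in ≥ 4 participants), and voxel importance is read out as
β_j = Σ_i α_i x_ij, the dual solution back-projected onto voxel space.
Significance is permutation-based with family-wise error control: the
behavioral scores are permuted 5,000 times, null distributions of the
1st/10th/100th/1,000th highest β are built, and the observed map is
thresholded at the empirical 95th-percentile order statistic of each.

Because raw patient data of this kind are not publicly deposited, the
package includes a first-class synthetic cohort generator (clustered
left-hemisphere lesions, two disjoint planted critical regions driving
span and spelling-length deficits, a third driving frequency
sensitivity, trial-level spelling errors) so every pipeline stage is
testable against ground truth. See `docs/methods.md` for the full model
description.

## Worked example

```python
from svrlsm import (RunConfig, SyntheticConfig, run_analysis,
                    letter_accuracy, digit_span, DigitSpanRecord)

letter_accuracy("COAT", "COET")                      # 0.75
digit_span(DigitSpanRecord({2: (2, 2), 3: (2, 1), 4: (2, 0)}))  # 2.5

config = RunConfig(synthetic=SyntheticConfig(seed=1),
                   n_perm=1000, seed=1, output_dir="demo-run")
results = run_analysis(config, which="both")
for name in ("pwm", "owm"):
    strict = results[name]["thresholds"][1]
    print(name, strict.n_significant, len(results[name]["clusters"]))
print(results["overlap"]["1"])
```

prints

```
pwm 438 1
owm 421 1
{'a_only': 438, 'b_only': 421, 'both': 0, 'a_total': 438, 'b_total': 421}
```

The span analysis flags 438 voxels (one cluster, 3504 mm³ at 2 mm
voxels) at the maximum-statistic threshold, the orthographic analysis
421 voxels (one 3368 mm³ cluster), and the two significant sets share
no voxel — each analysis recovers its own planted region, the
synthetic analogue of a phonological/orthographic dissociation.
`demo-run/` then contains the β maps and per-rank thresholded maps as
NIfTI, cluster CSVs, the per-rank overlap report, the permutation
nulls, and a provenance JSON recording every setting.

The same pipeline runs from the shell:

```sh
svrlsm simulate --seed 1 --out cohort/      # write a synthetic cohort
svrlsm behave --cohort cohort/              # score + classify deficits
svrlsm map --config run.yaml                # both analyses end to end
svrlsm report --run demo-run/               # cluster tables + overlap
```

For real data, point `cohort_dir` at a directory with `masks/*.nii.gz`,
`behavior.csv` (participant_id, age, gender, ppvt_percentile, ...),
`digit_span.csv`, `spelling.csv` and optionally `ppe.csv`.

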