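# scanharm

Harmonization of scanner-biased morphometric feature tables (ROI volumes
normalized by total intracranial volume), with two complementary routes:

1. **Batch harmonization** (`scanharm.combat`): empirical-Bayes
   location/scale correction applied stepwise — sex effects, then age
   effects (integer age as the batch), then scanner effects — recording
   per-step and cumulative corrections per subject × ROI. Requires a
   statistically representative sample per scanner.
2. **Unseen-scanner harmonization** (`scanharm.learner`): a per-ROI
   random-forest model that predicts those corrections from per-image
   quality metrics (IQMs) plus age, sex and the raw relative volume, on a
   standardized principal-component basis retaining 99% of the variance.
   Because the inputs are intrinsic to a single image, it can harmonize a
   single scan from a scanner never seen during fitting. Subjects outside
   the training feature envelope are flagged but still predicted.

Supporting modules: `tables` (CSV/TSV cohort tables, FreeSurfer
`aseg.stats` parsing, versioned model bundles), `qc` (age window, quality
probability cutoffs, per-scanner iterative outlier removal, minimum
scanner size), `evaluation` (pairwise two-sample Kolmogorov–Smirnov
matrices, correction-strength and per-covariate contribution summaries),
`synthetic` (multi-scanner cohort simulator with ground-truth scanner
effects driven by a latent quality variable that also drives the IQMs).

## CLI

```sh
scanharm simulate --seed 1 --out-dir out/sim
scanharm qc       --table out/sim/cohort.tsv --iqm-cols iqm_01,... --out-dir out/qc
scanharm combat   --table out/qc/cohort_qc.tsv --iqm-cols ... --steps sex,age,scanner --out-dir out/combat
scanharm train    --table out/qc/cohort_qc.tsv --corrections out/combat/corrections_cumulative.tsv \
                  --iqm-cols ... --seed 1 --out-dir out/train
scanharm apply    --model out/train/harmony_model --table new_subjects.tsv --iqm-cols ... --out-dir out/apply
scanharm evaluate --table out/apply/cohort_harmonized.tsv --out-dir out/eval
scanharm run      --seed 1 --out-dir out/full   # simulated end-to-end pipeline
```

Each stage writes a JSON manifest next to its outputs; fitted models are
saved as directories with a human-readable `manifest.json` plus a payload.

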