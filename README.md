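# mamvol

Multi-atlas mammillary-body (MB) volumetry and normative growth models
for neonatal and pediatric T1-weighted MRI.

The mammillary bodies are paired hypothalamic nuclei of the extended
hippocampal–diencephalic memory circuit. They are frequently damaged in
neonatal hypoxic-ischemic encephalopathy and in thiamine deficiency,
but because each MB is only tens of mm³, deciding whether a measured
volume is abnormal requires both an accurate automated segmentation and
a normative reference for the subject's age. `mamvol` provides both, as
a library and a CLI, for clinicians and imaging researchers building or
applying normative MB references:

* **Segmentation** — subjects are resampled to a 0.5 × 0.5 × 0.5 mm
  grid; each of five atlas scans with expert MB labels is registered to
  the subject (a 9-parameter linear stage driven by quadrature-filter
  local phase, then a variational deformable stage minimizing
  `E(u) = Σ (F − M∘(id+u))² + α Σ ‖∇u‖²`); the propagated labels are
  fused by a strict per-voxel majority vote, and left/right volumes are
  read off as label count × voxel volume.
* **Normative models** — paired left–right laterality analysis and the
  linear map `Left = a + b·Right`; neonatal growth (total volume vs
  postmenstrual age in weeks, sex, optional prematurity covariates);
  quadratic growth for 6–24 years,
  `V(age) = β₀ + β₁·age + β₂·age²` (raw mm³ or divided by intracranial
  volume), with the growth peak at `−β₁/(2β₂)`; and normative z-scores
  `z = (observed − predicted)/σ_resid` for new subjects.
* **Synthetic data** — head phantoms with analytic ground-truth MB
  labels, perturbed atlas sets, and cohort tables drawn from published
  normative equations, so the entire pipeline is testable with no image
  downloads.

## Worked example

Simulate a 6–24-year cohort from the published quadratic growth model,
fit the model back, and z-score a new observation:

```
$ mamvol cohort --mode child --n 250 --seed 1 --out cohort.csv
wrote 250-subject child cohort (seed 1) to cohort.csv

$ mamvol fit --cohort cohort.csv --model growth --out fit.json
$ python -c "import json; f=json.load(open('fit.json')); print(f['fit']['terms'], f['peak_age_years'])"
{'age': 7.6673732796, 'age2': -0.2233336096, 'intercept': 58.5377266748} 17.1657

$ mamvol zscore --fit fit.json --age 10 --volume 95
{"z": -1.354142, "percentile": 8.7845}
```

The fitted coefficients scatter around the generating values
(68.61, 6.53, −0.19) according to the cohort's residual noise; the
growth peak lands in the late teens. The z-score output says a total MB
volume of 95 mm³ at age 10 sits 1.35 residual SDs below the cohort
curve, at the 8.8th percentile — within the normal range, but in its
lower tail.

The imaging side runs the same way from the shell:

```
$ mamvol atlas --out atlases/ --k 5 --seed 7
$ mamvol phantom --out subject/ --seed 99
$ mamvol segment --subject subject/phantom_t1.nii.gz --atlas-dir atlases/ --out result/
phantom_t1: left 25.50 mm3, right 23.50 mm3 (5 atlases; qc: ok)
```

`mamvol demo --out demo/` runs everything (atlas building, three
held-out segmentations with Dice/volume-error against ground truth,
cohort simulation and all four model fits) and writes a reproducible
`report.json`/`report.md`.

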