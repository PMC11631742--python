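# sarcogait

Sarcopenia-vs-normal gait classification from two modalities:

- **Skeleton sequences** — 32-joint 3D gait recordings at 30 fps are reduced
  to 25 analysis joints, normalized per frame by the sacrum-to-shoulder-center
  (trunk) distance, expanded into multi-branch features (position, joint
  velocity, bone orientation), and classified with a spatiotemporal
  graph-convolutional network (spatial skeletal edges + temporal convolutions,
  learned per-joint attention).
- **Plantar foot pressure** — pressure-plate frame series are averaged over
  time into a single-channel image (optionally flip/rotate augmented) and
  classified with a ResNet-18-shaped residual CNN trained from scratch.

Participants are labeled by the sex-specific grip-strength rule (sarcopenia
iff strictly below 26 kg for men / 18 kg for women). Evaluation is
subject-level, class-stratified 4-fold cross-validation with a per-class 20%
validation holdout inside each round; the four fold accuracies are averaged.

A synthetic cohort generator (stylized sinusoidal kinematic walker plus
Gaussian-blob footprint synthesizer, with sarcopenia priors shifted toward
shorter/uneven strides, reduced range of motion, slower speed and reduced
forefoot pressure) makes the entire pipeline testable without any download.

The neural networks are implemented on numpy with
[autograd](https://github.com/HIPS/autograd) — no GPU framework required.

## CLI

```bash
# write a synthetic dataset directory (cohort CSV, skeleton CSVs, pressure arrays)
sarcogait synth --spec spec.yaml --out data/ --seed 1

# feature arrays from a dataset directory
sarcogait preprocess --data data/ --modality skeleton --out feats.npz

# single-model training -> checkpoint
sarcogait train --data data/ --modality pressure --seed 1 --out model.npz

# subject-stratified 4-fold cross-validation
sarcogait evaluate --data data/ --modality skeleton --seed 1 --out results.json

# summarize results files
sarcogait report --results results.json

# whole pipeline (synthesize -> preprocess -> train -> evaluate) from one config
sarcogait run --config config.yaml --seed 1 --out runs/exp1
```

`sarcogait run` accepts a YAML config (see `sarcogait.pipeline.default_config`
for the schema and desk-scale defaults); every stage's randomness is derived
from the single global seed by hashing the stage name, and a `manifest.json`
records config snapshot, seeds, timings and outputs. Re-running with an
unchanged config reuses existing results.

## Layout

```
src/sarcogait/
  cohort_labeling.py         # participant records, grip-strength labeling, cohort CSV
  skeleton_processing.py     # sequences, joint selection, trunk normalization, features
  footpressure_processing.py # series -> average image, augmentation, IO
  models/                    # adjacency, ST-GCN, residual CNN, autograd layers, training
  evaluation.py              # folds, validation split, train/eval protocol, averaging
  synthetic_data.py          # kinematic walker, pressure synthesizer, cohort generator
  pipeline.py                # orchestration, config, manifest, dataset IO
  cli.py                     # click CLI
tests/                       # unit + property tests, tests/test_acceptance.py
scripts/acceptance.py        # acceptance report
```

Notes: boundary grip-strength values exactly at 26/18 kg are labeled
*normal* (the rule is a strict less-than). The synthetic walker is a
controllable statistical model, not a biomechanically validated simulator.
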