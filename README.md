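# eegstages

Analysis pipeline for studying how brain activity evolves across the
stages of a multi-week learning curriculum, recorded with a 14-channel
consumer EEG headset (Emotiv EPOC+ style montage, 128 Hz sampling).

The scientific setting: students work through an 11-session online
course split into three learning stages (sessions 1–3 basic knowledge,
4–6 core knowledge, 7–11 application), each session containing three
task types — watching a lecture, running a virtual lab and taking a
quiz. `eegstages` turns the raw multichannel recordings of such a study
into quality-controlled segments, spectral and connectivity features,
non-parametric stage/task comparisons, and machine-learning
discrimination of the three learning stages. Because curriculum EEG of
this kind is rarely shareable, the package also contains a first-class
synthetic-session generator that emulates the recording setup and the
stage/task-dependent oscillatory structure, so the entire pipeline is
testable end to end.

## What the pipeline computes

* **Quality control** — zero-phase 1 Hz high-pass + 50 Hz notch
  filtering; discard of the first 30 s; slicing into non-overlapping
  10 s windows with linear detrending; the 3σ outlier rule
  `|y − mean| > 3·std` with half-lead rejection, nearest-neighbour
  outlier correction, and 150 µV amplitude rejection.
* **Spectral features** — Welch PSD (2 s Hamming windows, 50 %
  overlap) and relative band power in six bands (δ, θ, α, low-β,
  high-β, γ) over the 1–45 Hz analysis range: 14 channels × 6 bands =
  84 features per segment.
* **Components** — group task-related component analysis (gTRCA):
  spatial filters `w` solving `S w = λ Q w`, where `S` sums cross-trial
  covariances and `Q` pools within-trial covariances, yielding
  maximally trial-reproducible components and their forward-model
  scalp patterns.
* **Connectivity** — Stam's phase-lag index
  `PLI = |⟨sign(Δφ(t))⟩|` per channel pair; strongest long-range links
  within a PLI window; weighted global/local efficiency
  (Latora–Marchiori); and an information-transfer matrix
  `MI(q,s) = H(q) + H(s) − H(q,s)` in bits from histogram entropies of
  delay-embedded channel states.
* **Statistics** — two-sided Wilcoxon rank-sum tests for all
  stage-within-task and task-within-stage contrasts (exact enumeration
  for small tie-free groups), with Cohen's `d` and post-hoc power from
  the noncentral *t* distribution.
* **Classification** — MRMR feature ranking and a five-model suite
  (RBF-SVM, KNN, decision tree, QDA, MLP) evaluated with a held-out
  test split plus stratified 10-fold cross-validation.

## Worked example

```python
import numpy as np
from eegstages import (SynthConfig, SessionMeta, generate_session,
                       preprocess, features_table, pli_matrix, efficiency)

cfg = SynthConfig(duration=95.0, meta=SessionMeta("S01", 2, "lab"), seed=7)
rec = generate_session(cfg)              # 14 x 12160 samples at 128 Hz
segments, report = preprocess(rec)
print(report)
# {'kept': 0, 'kept_corrected': 6, 'discarded_outliers': 0,
#  'discarded_amplitude': 0, 'total': 6, 'kept_total': 6}

feats = features_table(segments)
print(feats.shape)                        # (6, 103): labels + 84 + 14 amp
print(round(feats["O1_alpha"].mean(), 3))
# 0.272  -> ~27% of O1 power sits in 8-12 Hz for this stage-1 lab session

pli = pli_matrix(segments[0])
print(round(efficiency(pli).global_efficiency, 3))
# 0.067  -> weakly coupled network: no phase coupling was injected
```

A 95 s session yields six 10 s segments (the first 30 s are discarded);
all six pass QC after nearest-neighbour correction of isolated outlier
samples. Each kept segment becomes one 84-feature sample for the
stage classifier.

The same flow is available from the shell:

```sh
eegstages -c config.yml -r run/ simulate
eegstages -c config.yml -r run/ preprocess
eegstages -c config.yml -r run/ features
eegstages -c config.yml -r run/ classify
eegstages -c config.yml -r run/ report
```

Each step writes into `run/` and records itself in `run/manifest.json`
under the configuration hash, so artifacts are traceable.

## Layout

| module | role |
| --- | --- |
| `eegstages.core` | montage, recording, segment containers |
| `eegstages.synth` | synthetic sessions, artifacts, stage datasets |
| `eegstages.qc` | filtering, slicing, outlier & amplitude rules |
| `eegstages.spectral` | Welch PSD, relative band power, 84-feature vectors |
| `eegstages.components` | gTRCA spatial components |
| `eegstages.connectivity` | PLI, graph efficiency, MI transfer matrices |
| `eegstages.stats` | rank-sum contrasts, effect size, post-hoc power |
| `eegstages.stageclf` | MRMR ranking, model suite, reports |
| `eegstages.cli` | YAML-configured pipeline orchestration |

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
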