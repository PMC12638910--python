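# Methods

This note documents the models, defaults and design decisions behind
`eegstages`, in the order data flows through the pipeline. It states
no empirical result that the test suite or `scripts/acceptance.py` do
not themselves compute.

## Recording model and montage

The pipeline targets 14-channel consumer EEG (AF3, F7, F3, FC5, T7,
P7, O1, O2, P8, T8, FC6, F4, F8, AF4; CMS/DRL referencing accepted
as-is) sampled at 128 Hz, voltages in µV. Electrode coordinates are a
2-D template of the 10–20 system (outer-ring electrodes on the 10 %
circle at 36° spacing, inner electrodes at common template values);
they are used only for the long-range edge rule and for plotting, so
template accuracy suffices. The montage has no midline electrodes,
giving a clean 7/7 hemisphere split.

Learning stage is a deterministic function of the session index —
sessions 1–3 → stage 1, 4–6 → stage 2, 7–11 → stage 3 — and is never
stored independently, which makes label/metadata drift impossible.

## Synthetic sessions

The generator is the package's study stand-in, not a fixture: every
downstream stage is exercised against it.

**Signal model.** Each channel is a sum of one amplitude-modulated
sinusoid per frequency band plus 1/f-shaped Gaussian noise. Oscillator
frequencies are drawn uniformly from the inner 70 % of their band so
spectral content never straddles a band edge; modulation (depth 0.2,
0.05–0.3 Hz) adds within-segment nonstationarity. Baseline peak
amplitudes are δ 12, θ 9, α 10, low-β 6, high-β 5, γ 3 µV with
noise SD 10 µV — proportions loosely matching adult resting scalp EEG.
This model was chosen over a biophysical forward simulation because
the downstream features are purely spectral and the sinusoid-plus-noise
model gives exact control over band content and analytic targets.

**Stage/task structure.** Stage effects are multiplicative band
amplitude trends: alpha rises from stage 1 in lecture and quiz, falls
across stages in the lab; low-β falls in the lab; high-β rises in lab
and quiz; a whole-head gain grows across stages for lecture and
shrinks for lab/quiz. Slopes are 0.15 (band) and 0.08 (gain) per unit
`effect_size` per stage step. Only trend *directions* are anchored in
what is reported for curricula of this kind; no quantitative per-band
effect sizes are available, so the magnitudes are the package's own
calibration, fixed once. `effect_size = 0` makes all stages draw from
the identical generative law, which is what the chance-level and
type-I calibration checks rely on.

**Coupling.** A coupling entry places one shared band-limited
oscillator on two channels with a fixed phase lag, mixed with an
independent oscillator by `strength`: strength 1 yields a constant
nonzero lag and hence an analytic phase-lag index of exactly 1.

**Artifacts.** Four kinds, all recorded in a per-recording ledger of
(kind, channel, sample span, amplitude) so QC decisions can be traced
to ground truth: single-sample spikes (100 µV); dense alternating
spike bursts (150 µV, 7 s, one lead — designed to break the half-lead
outlier rule); linear drift (80 µV, removed by the high-pass, so QC
should keep it); and whole-head ~3 Hz excursions (220 µV — above the
150 µV rejection limit but *below* the pooled 3σ outlier threshold,
so they reach the amplitude rule rather than being "corrected" away).
Waveforms are pure functions of their ledger entries, so a ledger
round-trip reconstructs what was injected.

**What the generator does not emulate:** eye-blink/EMG waveform
morphology, inter-channel volume-conduction mixing, electrode pops,
impedance drift, and subject-level random effects beyond lognormal
amplitude jitter. Passing tests therefore demonstrate correctness of
the pipeline's *mechanics* and calibration under the stated spectral
model, not robustness to every real-world artifact class.

## Quality control

Order of operations: zero-phase 4th-order Butterworth 1 Hz high-pass,
then a 50 Hz IIR notch (Q = 30), both forward-backward so no phase lag
distorts cross-channel phase measures; discard of the first 30 s;
non-overlapping 10 s windows (trailing remainder dropped); linear
detrend per channel; then the per-window rules:

1. a sample is an outlier when `|y − mean| > 3·std`;
2. any lead with outliers in strictly more than half of its samples
   discards the window;
3. otherwise outliers are replaced by the nearest non-outlier sample
   of the same lead (distance ties resolve to the earlier sample);
4. any remaining sample with `|v| > 150 µV` discards the window.

Two choices deserve justification:

* **Pooled outlier statistics.** `mean`/`std` are computed over the
  whole 10-s window pooled across all 14 leads, not per lead. Per-lead
  statistics make rule 2 unreachable: by Chebyshev's inequality at
  most 1/9 of a lead's samples can exceed three of *that lead's own*
  standard deviations, so "more than half" could never trigger.
  Pooling anchors the threshold to the head-wide noise level, under
  which a single saturated lead is detectable. `count_outliers`
  accepts explicit statistics, so the per-lead convention remains
  available.
* **Amplitude check after correction.** An isolated 200 µV spike that
  the outlier rule corrects below 150 µV yields `kept_corrected`, not
  a discard; only amplitude excursions that survive correction (i.e.
  are not outliers under the pooled rule) reject the window. The
  opposite order would make the amplitude rule fire on exactly the
  transients interpolation exists to fix.

Independent-component artifact removal is deliberately not in the
default chain: with 14 channels and no principled component-selection
rule, silent ICA would be an unauditable degree of freedom. A hook
between filtering and slicing accommodates callers that have one.

## Spectral features

Welch PSD with 2 s Hamming windows and 50 % overlap — nine averaged
windows per segment, 0.5 Hz resolution at 128 Hz, a standard
variance/resolution compromise. Band edges (configurable): δ [1, 4),
θ [4, 8), α [8, 12), low-β [12, 16), high-β [16, 25), γ [25, 45) Hz.
These follow common consumer-EEG conventions; they are an assumption,
not a physical constant. Relative power divides band power by total
power over the 1–45 Hz analysis range (content outside it is filter
artifact); with the default bands tiling that range, the six values
per channel sum to one — which also means the 84 features carry 14
exact linear constraints (relevant to classifier conditioning, below).
Features are ordered channel-major (`AF3_delta … AF4_gamma`) and are
scale invariant by construction.

"Average amplitude" for topographic summaries is the mean absolute
voltage per channel: after high-pass filtering the raw mean is ~0, so
a magnitude statistic is the only meaningful reading; RMS is offered
as the alternative.

## gTRCA components

Task-related component analysis maximizes inter-trial reproducibility
of a spatially filtered signal: with per-trial covariances pooled into
`Q` and summed cross-trial covariances in `S`, filters solve
`S w = λ Q w`. The group variant is implemented as subject-pooled
covariance summation — trials from all subjects enter one `S`/`Q`
pair — rather than the full hierarchical extension of the original
method, which is out of scope here. `S` is computed via
`Cov(Σᵢ Xᵢ) − Q` (one matrix product instead of K²), symmetrized.
The eigensolve is ridge-regularized with `1e-6 · trace(Q)/C` diagonal
loading, logged when `Q` is ill-conditioned. For K identical trials
the leading eigenvalue attains its maximum K − 1, a useful analytic
check. Filters are unit-norm; topographies are forward-model patterns
`Q w`, normalized, with the sign fixed so the largest-magnitude
pattern entry is positive. Unequal trial lengths truncate to the
common minimum. One component is extracted by default (only the
leading topography is typically mapped); white-noise inputs produce
patterns that are unstable across seeds, which is expected — the
surrogate comparison, not the pattern, is the meaningful null check.

## Connectivity

**PLI.** Instantaneous phase is the angle of the analytic signal after
zero-phase band-pass filtering (full analysis band 1–45 Hz by default;
per-band supported). `PLI(i,j) = |⟨sign(sin(φᵢ − φⱼ))⟩|` with 5 % of
samples trimmed at each end to avoid filter/Hilbert transients. The
sign of an exactly zero phase difference contributes 0, so identical
signals give PLI 0 — the measure's defining robustness to
volume-conducted zero-lag coupling. Condition-level matrices pool
segments by the mean.

**Long-range links.** "Long-range" is defined as electrode pairs whose
template 10–20 distance exceeds the median inter-electrode distance
(an inter-hemispheric-only rule is available). The strongest-link
report takes the k = 10 largest PLI values inside [0.5, 0.7] among
long-range pairs, with deterministic (index-ordered) tie-breaking.

**Efficiency.** Weighted Latora–Marchiori on the unthresholded PLI
graph, edge length 1/weight: global efficiency is the mean inverse
shortest-path length over pairs; local efficiency averages the global
efficiency of each node's neighbour-induced subgraph (nodes with < 2
neighbours contribute 0; disconnected pairs contribute 0). The
unthresholded graph was chosen because efficiency values of interest
are continuous; a binarized variant would add an arbitrary threshold.
Correctness is checked against exhaustive simple-path enumeration on
all graphs up to 7 nodes.

**Information transfer.** `MI(q,s) = H(q) + H(s) − H(q,s)` in bits
(log₂). Channels are delay-embedded (m = 3, τ = 4 samples ≈ 31 ms at
128 Hz); the state series is the leading embedding coordinate
discretized into 16 equal-width bins over the channel's own range.
Using the scalar leading coordinate rather than the full m-dimensional
product state keeps the joint histogram (256 cells) well populated at
the ~1270 states a 10 s window provides; a full 16³-state joint would
be hopelessly biased at this length. All settings are configurable
and should be treated as estimator choices. The Miller–Madow
correction (on by default) adds `(K_occupied − 1)/(2N ln 2)` bits to
each entropy term, which cancels the independence bias of the plug-in
MI; estimates are clipped at zero. The measure is symmetric —
source/receiver language notwithstanding, no directionality is
recoverable from this quantity, and none is claimed.

## Statistics

All contrasts use the two-sided Wilcoxon rank-sum test: exact null
enumeration when both groups have ≤ 10 tie-free observations,
otherwise the tie- and continuity-corrected normal approximation.
Effect size is Cohen's d with pooled SD — a parametric summary
attached to a rank test, kept because it is the convention of post-hoc
power calculators — with the rank-biserial correlation reported
alongside as the rank-native measure. Post-hoc power is that of the
two-sided two-sample t test at the observed d, from the noncentral t
distribution with noncentrality `|d|·√(n₁n₂/(n₁+n₂))`; at d = 0 it
returns α, as it should.

Comparisons pool segments across subjects by default (a subject-mean
mode is the conservative alternative; pooling treats segments as
exchangeable and will overstate evidence when between-subject variance
dominates). No multiple-testing correction is applied by default —
stars mark raw p-values, matching the reporting convention the
pipeline mirrors — with Benjamini–Hochberg available behind a flag.
Hemisphere subsets: left {AF3, F7, F3, FC5, T7, P7, O1}, right
{AF4, F8, F4, FC6, T8, P8, O2}.

## Stage classification

Each kept segment is one sample of 84 relative-power features. The
evaluation protocol holds out a stratified 20 % test set first, runs
stratified 10-fold cross-validation (9:1 per fold) on the remaining
pool, then refits on the whole pool and scores the untouched test set
once; fold/test disjointness is asserted programmatically. The 80/20
provenance of the test set is an explicit assumption — the protocol
the pipeline mirrors names a test set without sizing it. Splitting is
segment-level by default, matching pooled-segment evaluation; the
grouped (session-level) mode is the leakage-safe alternative and the
right choice whenever conclusions should generalize to unseen
sessions.

Model hyperparameters (fixed, no search): RBF-SVM (C = 1, one-vs-one,
standardized features), KNN (k = 10, Euclidean, standardized),
decision tree (Gini, depth ≤ 20), quadratic discriminant analysis,
and an MLP (one hidden layer of 100 ReLU units, early stopping).
Standardization is fit on training folds only. QDA uses the eigen
solver with shrinkage 0.1: the per-channel band sums make class
covariances structurally rank-deficient, so an unshrunk QDA is not
well-posed on these features.

MRMR ranking discretizes each feature into 4 equal-frequency bins and
greedily maximizes MI with the stage label minus mean MI with the
already-selected set (the difference criterion), ties breaking toward
the lower feature index. Rankings are labelled `channel_band`
(e.g. `O1_alpha`).

## Problem sizes in the checks

The acceptance checks run at sizes chosen to make their statistical
bands meaningful on a single core: 200 artifact-labelled segments for
the QC round-trip; 100 noise seeds for the PLI null; 200–500 random
graphs (≤ 7 nodes) for the efficiency oracle; all tie-free group-size
pairs with n₁ + n₂ ≤ 12 for rank-sum exactness; 50 seeds for gTRCA
(20 trials, 512 samples, SNR 0 dB) and for MRMR recovery (180-sample
datasets, occipital-alpha plant at effect size 2); 3 750 samples
(750 held out) for classifier calibration; and 1 000 independent
two-group null contrasts (20 segments per group) for type-I
calibration.

## Known limitations

* The generator's stage effects are direction-calibrated only; real
  effect magnitudes, inter-subject variability and nonstationarity
  across a semester are not modelled.
* Segment-level splitting and segment pooling overstate effective
  sample size relative to subject-level inference; the grouped modes
  exist for that reason but are not the defaults.
* The MI estimator's embedding/binning settings are assumptions; MI
  values should be compared only within a fixed estimator
  configuration.
* Band edges, the long-range rule and the 80/20 test protocol are
  documented conventions, not derived quantities.
* EDF export is not implemented (CSV + JSON sidecar is the native
  interchange format; EDF reading is available via the optional `mne`
  dependency).
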