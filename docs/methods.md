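# Methods

## Signal model and detection algorithm

A 12-lead ECG record is a set of per-lead sample arrays in millivolts
at a fixed sampling rate (default 500 Hz for 11 s, i.e. 5500 samples
per lead, matching the acquisition convention of a common clinical
recorder). Detection is purely amplitude-based and runs per lead with
no filtering or baseline correction:

1. **Preliminary R scan.** Left-to-right, accept the first sample that
   exceeds the minimum peak amplitude `mpa` and is a strict local
   maximum; then skip a refractory interval of `miR` samples and
   repeat. Defaults: `mpa = 0.025 mV`, `miR = 300` samples (0.6 s at
   500 Hz, one beat at the fastest normal heart rate). The scan is
   greedy — the *first* qualifying point wins, not the largest in a
   window — which is also how the independent test oracle is defined
   (enumerate all strict local maxima above `mpa`, then greedily
   enforce the spacing).
2. **S valley.** Minimum of the window (R, R + 0.12 s], truncated at
   the record end; earliest index on ties.
3. **Tall-T correction.** If the minimum of the 0.25 s window before a
   preliminary R is deeper than its S valley, the preliminary "R" was
   most likely a T apex: the valley moves to that backward minimum and
   the R peak is re-anchored as the maximum of the 0.12 s *before* the
   new valley. A true R precedes its S in a QRS complex, so the
   backward reading is the default; a forward variant
   (`DetectorParams.step7_direction = "forward"`) is kept for fidelity
   experiments, with a fresh forward S search restoring the S-after-R
   ordering when it is used.

Window lengths in samples use half-up rounding of duration × fs
(0.12 s → 60 and 0.25 s → 125 samples at 500 Hz). Strict inequalities
mean plateau samples are not peaks; a flat-topped R is accepted at the
last sample where the signal turns downward. Beats are sorted,
deduplicated (two preliminary peaks can correct to the same R), and
records with fewer than 3 beats in a lead are flagged, since medians
and segmentation need at least one interior beat.

### Known failure modes (by design, not repaired)

The scan accepts the first local maximum above 0.025 mV. Real P waves
(0.1–0.25 mV) exceed that floor, and once the scan accepts a P the
refractory interval suppresses the following R. Likewise baseline
noise above ~0.01 mV RMS produces qualifying local maxima that capture
the scan. These are properties of the published procedure that this
package reproduces faithfully; one unit test documents the P-capture
mode explicitly. The algorithm is only guaranteed for heart rates in
60–100 bpm (the refractory equals the 100 bpm RR interval).

## Features

Per lead, the first and last detected cycles are dropped (commonly
incomplete or noisy) and the medians of the remaining R amplitudes and
S magnitudes give the 24 case features. S features are magnitudes: the
valley depth below baseline, floored at 0 when the valley sits above
baseline; raw signal zero is the baseline since the procedure applies
no isoelectric correction. R features are raw medians and may be
negative in leads with inverted polarity such as aVR.

Beat segmentation anchors rows on the interior R peaks of a reference
lead (default II, the conventional rhythm lead): a record with n
reference beats yields exactly n − 2 rows. Other leads contribute the
amplitudes of their own beat nearest each anchor (one-to-one greedy
matching within 0.15 s, a configurable tolerance chosen to be below
half the shortest normal RR interval); a lead with no matching beat
falls back to its case medians. Each row inherits the case label. The
per-beat-with-fallback definition is this package's own; an
alternative (reusing case medians for all non-reference leads) would
only reduce row-to-row variance.

Z-score normalisation uses the population (n-denominator) standard
deviation, clamps sds below 1e-12 to 1 (constant columns map to
zeros), and is always fitted on training rows only to avoid leakage;
whether the original protocol fitted on all data is unknowable, so the
leakage-free choice is the default.

## Voltage criteria

The seven criteria and thresholds (mV), with printed strictness:

| criterion | rule |
|---|---|
| Cornell | SV3 + RaVL > 2.8 (m) / 2.0 (f) |
| Sokolow–Lyon | SV1 + max(RV5, RV6) ≥ 3.5 |
| Peguero | deepest S in any lead + SV4 ≥ 2.8 (m) / 2.3 (f) |
| Framingham | any of: RaVL > 1.1; max(RV4,RV5,RV6) > 2.5; max(SV1..SV3) > 2.5; max(SV1,SV2)+max(RV5,RV6) > 3.5; RI+SIII > 2.5 |
| Gubner | RI + SIII ≥ 2.2 |
| 12-lead sum | Σ leads max(R, S) ≥ 17.9 |
| Lewis | (RI + SIII) − (RIII + SI) > 1.7 |

All thresholds live in one configuration table so cohort-specific
recalibration never touches code. The deepest S in Peguero may be SV4
itself (then counted twice, per the rule's wording). Framingham's
result reports the largest clause margin and records which clauses
fired. The 12-lead sum uses compensated summation so the uniform
boundary case lands exactly on the threshold.

## Classifiers and evaluation protocol

- **Decision tree**: entropy splits; node impurity is the binary
  entropy −p·log₂p − q·log₂q (0 for a pure node, 1 for an even split).
  Depths 1–25 are scored by mean tenfold stratified-CV accuracy on the
  training data; the best depth wins, smallest on ties (parsimony),
  and the final tree is refit on all training rows.
- **k-means**: k = 2 (binary task), k-means++ initialisation, Lloyd
  iterations to convergence, each cluster mapped to its majority
  training label, prediction by nearest centroid.
- **Back-propagation network**: 24 inputs → one hidden layer of 26
  logistic units → one sigmoid output thresholded at 0.5; z-scored
  inputs; 400 epochs of mini-batch (32) plain gradient descent at
  learning rate 0.01 with seeded Glorot-style initialisation. The
  architecture and epoch count follow the protocol; activation,
  optimiser, batch size and learning rate are this package's choices
  where the protocol is silent, and all are configurable via
  `BpnConfig`.

These are standard estimators and are implemented on scikit-learn
(`DecisionTreeClassifier`, `KMeans`, `MLPClassifier`) behind the
package's model classes; every stochastic fit is seeded and reproduces
bit-identical reports from (data, seed).

Evaluation balances the cohort (all minority cases plus a seeded
equal-size sample of the majority), splits 7:3, and reports confusion
counts with LVH positive plus accuracy, precision, sensitivity and
specificity; zero-denominator ratios are NaN, never 0. For beat-level
tables the split is **grouped by subject** by default so no subject
contributes rows to both sides — an ungrouped mode exists for
comparison, and the choice materially affects beat-level headline
numbers (ungrouped splits let the classifier memorise subjects).

## Feature importance

The per-feature one-way ANOVA F-statistic over the two classes is
implemented directly from its definition (between-group over
within-group variance); an independent library ANOVA serves as the
test oracle at 1e-10 relative tolerance. Infinite F (zero
within-group variance with separated means) is signalled explicitly.
The elimination curve fixes one train/test split and the initial
training-data ranking, then drops the weakest feature one at a time
from 24 down to 1, retraining at each step; an optional mode re-ranks
after each removal.

## Synthetic data

`synth_record` renders each lead as a sum of per-beat Gaussian bumps
(P, Q, R, S, T) at RR-spaced apex times, optionally with seeded RR
jitter, white noise and sinusoidal baseline wander. Ground truth (apex
and valley indices and amplitudes) is read off the noiseless signal,
so detector tests can demand exact recovery. Templates must fit inside
one RR interval or the generator refuses. A record whose first apex
precedes sample 0 starts with a bare T wave — the scenario that locks
the preliminary scan onto T apices and exercises the correction step.

Generator conditions (fixed once, as study conditions):

- default P amplitude 0.01 mV — below the 0.025 mV detection floor,
  because the published scan cannot coexist with a P wave above it
  (see failure modes); `p_amp` is configurable to document that
  sensitivity;
- Q depth at most 60% of S depth (capped at 0.06 mV) — the backward
  correction assumes S is the deepest QRS point;
- cohort baseline noise 0.005 mV RMS, consistent with a filtered
  diagnostic-grade acquisition and safely below the detection floor;
- cohort heart rates 60–95 bpm with 5 ms RR jitter, so the template
  span fits the shortest RR and the refractory never swallows a beat;
- cohort composition defaults to 173 LVH / 779 controls with a 90%
  male cohort, mirroring the target study population; LVH cases draw
  elevated mean amplitudes (+0.7 to +1.2 mV) on SV1, SV3, RaVL, RV5,
  RV6 — the amplitudes the criteria monitor — with 0.12 mV per-subject
  spread on every feature.

`synth_feature_table` skips the signal layer entirely: standard-normal
features with a configurable mean shift (default 3 sd on 6 of the 24
features, 400 rows per class) for classifier calibration experiments.

What passing tests do and do not show: the generator's beats are
stylised (no QRS notching, no ST shifts, no wander or arrhythmia by
default, P below the floor), so green tests certify the *mechanics* of
the pipeline — exact detection arithmetic, feature bookkeeping,
threshold strictness, protocol wiring — not clinical performance on
real ECG. The published clinical headline numbers depend on a
non-public hospital cohort and are out of scope here.

## Numerical choices

- Ties in argmin/argmax resolve to the earliest index (deterministic,
  scan-order consistent).
- Window sample counts: half-up rounding of duration × fs.
- Even-count medians average the two middle values (NumPy default).
- CSV round trips are bit-exact: floats are written with 17
  significant digits and parsed with round-trip precision.
- Problem sizes in the test suite (1000-signal oracle sweeps,
  100-record correction sweep, 60-subject end-to-end cohort,
  400-per-class recovery tables) are the package's desk-scale defaults
  and run in well under a minute each.

## Limitations

- The detector inherits every fragility of the published scan (P
  capture, noise capture, fixed refractory); it is a faithful
  implementation, not a robust QRS detector — use a bandpass +
  derivative detector for real data.
- WFDB input requires the optional `wfdb` package; CSV is the tested
  path. DICOM-ECG, SCP-ECG and HL7 aECG are out of scope.
- The k-means classifier is included for protocol completeness; it is
  not expected to perform well (cluster structure need not align with
  labels).
- Criteria not in the set of seven (Romhilt-Estes, Cornell product)
  are not implemented.
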