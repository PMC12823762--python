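# Methods

This note documents the analysis pipeline's models, conventions and
numerical choices, and — separately — what the synthetic-data generator
does and does not emulate. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model and ingest

The canonical record is a `SleepStudy`: up to four channels (SpO2 %, HR
bpm, RR breaths/min, NF in arbitrary transducer units) on a common 1 Hz
grid, SpO2 mandatory. Down-sampling to 1 Hz uses 1-second bin means for
every channel — robust to oximeter beat-to-beat jitter; upsampling (or a
non-integer ratio) falls back to linear interpolation and is flagged in
provenance. Channels of unequal post-resampling length are truncated to
the shortest, recorded in provenance.

EDF support is a deliberately minimal classic-EDF reader/writer
(`sleepnet/edf.py`): ASCII header, 1 s records, 16-bit samples, fixed
generous physical ranges so quantisation error stays below half a digital
step (≤ 0.0008% SpO2). EDF labels map to canonical channels only through
an explicit, case-insensitive `channel_map` — no label guessing. The test
suite cross-checks the writer against MNE's independent EDF reader.

## Artifact rules and inclusion

Three plausibility predicates, applied per channel: RR > 30 breaths/min,
HR < 40 bpm, SpO2 < 50% are treated as capture errors. Failing samples are
replaced by the median of the *valid* samples of that channel — the median
of valid samples always satisfies the predicate, which makes cleaning
idempotent (the alternative reading, median of all raw samples, does not
have this property). A channel with no valid samples is an error, not a
guess.

A study is excluded when any of: recording < 4 h (total recording time,
not artifact-free time); central events > 20% of scored events (skipped
with a note when the metadata is absent); any channel's artifact fraction
≥ 10%, inclusive at exactly 0.10. Every failed rule is enumerated in the
verdict.

T90 is computed after cleaning, as 100 × #(SpO2 strictly < 90)/N.
Summaries use the arithmetic mean and the n−1 sample SD.

## Respiratory rate from nasal flow

Breaths are flow peaks with a 1.5 s refractory interval and prominence
≥ 20% of the flow's interquartile range; peak times are refined by
parabolic interpolation of the three samples around each peak, the
instantaneous rate 60/interval is sampled-and-held onto the 1 s grid and
clipped to [0, 60] breaths/min. Derivation works best on the native-rate
flow (the simulator keeps its 4 Hz trace for this purpose). On simulated
nights the mean absolute error outside event windows is below 1 breath/min
(asserted in the tests); the refractory interval and prominence are
exposed as arguments for other transducers.

## Sample Entropy

`SampEn(m, r) = −ln(A/B)` with m = 2 and r = 0.2 × SD of the individual
cleaned channel (n−1 SD; the SD-relative tolerance makes the statistic
exactly affine-invariant). Both template counts run over the N−m
templates that possess an (m+1)-extension; self-matches are excluded;
natural logarithm; Chebyshev distance. One value per night — no
windowing. Degenerate cases are explicit: zero-variance series → 0
("perfectly regular", flagged); zero template matches → NaN (undefined,
never silently substituted; cohort aggregation must skip flagged rows).
The O(N²) counting loop is numba-compiled (≈1 s for an 8 h night); its
equality with a vectorised brute-force oracle (and with R `pracma`) is
part of the test suite.

## Transfer Entropy

`TE(X→Y) = I(Y_{t+τ}; X_t | Y_t)` with τ = 5 s, single-sample
conditioning (not 5 s block averages — the scalar-lag reading), plug-in
entropies on symbolised amplitudes, log base 2 (bits). Symbolisation uses
3 equal-probability bins whose edges are midpoints of the order statistics
flanking each cut; a tied run spanning a cut goes wholly to the side that
better balances occupancy. This keeps the estimate exactly invariant under
strictly monotone transforms, and behaves sensibly on heavily quantised
channels (integer SpO2). A constant channel yields TE = 0 with a flag.

The plug-in estimator's positive bias is handled by surrogates: 19
circular time-shifts of the source by a uniform offset ≥ 60 s; the
corrected value is the raw TE minus the surrogate mean, floored at 0, with
a one-sided rank p (resolution 1/20). The full network covers the 12
ordered off-diagonal pairs of {SpO2, HR, RR, NF}; self-edges are not
transfer and are left undefined. Cohort edge comparisons use the
two-sided Mann–Whitney rank-sum test at α = 0.05 per edge, without
multiplicity correction, on the surrogate-corrected values.

## ROC, thresholds, classifier

The empirical ROC enumerates all distinct score cuts under the
"positive iff score ≥ cut" convention; AUC is the Mann–Whitney rank
statistic with half-credit ties. Constrained threshold selection takes
exactly one bound (minimum sensitivity or minimum specificity), maximises
the other coordinate over feasible cuts, and breaks remaining ties toward
the higher cut; infeasible constraints raise with the best attainable
value. The four-phenotype rule stratifies on T90 ≥ 30% first, then applies
the SampEn SpO2 cut of that stratum (0.1456 / 0.3504); all boundaries are
inclusive (≥), uniformly. The mild vs moderate/severe OSA contrast is the
same `roc_auc` with a different labelling, not separate code.

## Synthetic cohort generator

The generator produces the four phenotype groups the classifier targets,
with ground-truth event logs. Design choices:

- **Events** arrive by a hard-core renewal process: exponential waiting
  times after each event's refractory window (duration + 10 s gap), with
  the exponential mean reduced by the mean busy time so the *realised*
  events/hour tracks the configured rate (plain Poisson thinning loses
  ~25% of events at OSA rates and breaks that contract). Durations are
  uniform on 20–60 s, desaturation depths uniform on 4–20%.
- **SpO2** = baseline + slow drift (three random-phase oscillations,
  20–90 min periods) − event deficits (linear fall over the first 40% of
  the event, exponential resaturation with τ = 15 s) + Gaussian sensor
  noise, then a 4 s moving average (oximeter beat-averaging) and rounding
  to integer % (device quantisation), clipped to [50, 100].
- **NF** is a 4 Hz breathing oscillation whose amplitude drops by 70%
  during events; the 1 Hz channel is the per-second mean rectified flow.
  **RR** is the oscillation's instantaneous rate (slowing 55% during
  events). **HR** is baseline + AR(1) variability + a sympathetic surge
  arriving 5 s after event onset (τ = 12 s decay). Obstruction therefore
  *leads* the oxygen response, which is what makes the directed
  information structure (NF/RR/HR → SpO2) non-trivial and recoverable.
- **Artifacts** (SpO2 < 50, HR < 40, RR > 30) are injected at a 0.5%
  default rate so the cleaning rules are exercised.
- **Phenotype presets** pin event rate and baseline to the clinical group
  definitions (normal 1.5/h at 95%; OSA 25/h at 94%; sustained hypoxaemia
  at 85% baseline with 50/h vs 10/h across the severe-OSA boundary), and
  are **calibrated**: sensor-noise SD (0.50–0.72, scaling with
  event/arousal burden) and drift amplitude were tuned once, by grid
  search, so that default 8 h cohorts land near the clinical reference
  group means of SpO2 Sample Entropy (≈0.13 / 0.28 / 0.41 / 0.23) with
  the clinical ordering NORMAL < HYPOXIA_LOW_AHI < OSA <
  HYPOXIA_HIGH_AHI. This is calibration of the simulator, not validation
  of the method. Hypoxic phenotypes are checked post-hoc for T90 ≥ 30%
  and regenerated under an offset seed in the rare violating case.

What the generator does **not** emulate: sleep architecture (REM/NREM),
central apnoeas, motion artifact structure, oximeter-specific averaging
beyond the simple moving window, autonomic HR–RR coupling independent of
events, or realistic T90 for hypoxic patients (simulated hypoxic nights
sit near T90 ≈ 100% versus ~75–80% clinically, because the baseline is
held below 90% all night). Passing tests therefore demonstrate that the
estimators recover the *constructed* couplings and orderings at realistic
signal-to-noise, not that the classifier generalises to patient data.

## Problem sizes and numerical conventions

Cohort-level checks run at n = 20 studies/group (n = 15/group for the
network comparison) on 8 h nights; the severity sweep spans 0–60 events/h
over 50 seeded nights; estimator checks use n = 20 000 (analytic TE
channel), n = 10 000 (independence null) and 100 runs at n = 5000
(directionality). Unit tests use 0.2–2 h nights. All randomness flows
from explicit integer seeds (`numpy.random.default_rng`); the TE
surrogate RNG is seeded through `TEParams.seed`. Ties in ROC scores get
half credit; the threshold tie-break is deterministic (higher cut);
quantile-bin ties follow the balanced-occupancy rule above.

## Known limitations

- The plug-in TE estimator is biased for short records; the surrogate
  correction removes the null-level bias but TE magnitudes remain
  estimator-specific and are meant for within-study and rank-based
  cohort comparisons, not absolute interpretation.
- SampEn on heavily quantised, smoothed oximetry depends on the device's
  averaging window; cross-device comparability is not addressed.
- The classifier thresholds are fixed defaults; re-deriving them on a new
  cohort requires the `roc_auc`/`select_threshold` path and a labelled
  training set.
- EDF support covers classic EDF only (no EDF+ annotations, no
  discontinuous records).
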