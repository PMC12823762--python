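# sleepnet

Network-physiology analysis of overnight cardiorespiratory polygraphy for
sleep-disordered breathing (SDB).

Overnight pulse oximetry is cheap, portable and well tolerated, but in
routine practice the SpO2 trace is reduced to static summaries (mean
saturation, desaturation index, time below 90%). Those summaries discard the
*dynamics* of the signal — and it is the dynamics that separate the
obstructive sleep apnoea (OSA) pattern of rapid intermittent desaturation
from the flatter, sicker pattern of sustained nocturnal hypoxaemia.
`sleepnet` implements the complexity-based alternative for researchers
working on oximetry-first diagnostic pathways:

- **artifact cleaning** of the four 1 Hz polygraphy channels — SpO2, heart
  rate (HR), respiratory rate (RR), nasal flow (NF) — with study-level
  inclusion rules;
- **Sample Entropy** (SampEn) profiling of each channel's overnight series;
- **Transfer Entropy** (TE) mapping of directed information flow over the
  4×4 channel network at a 5 s lag;
- a **two-threshold, four-phenotype classifier** operating on
  (T90, SampEn SpO2) alone — i.e. on quantities available from a single
  oximetry channel;
- a **seeded synthetic cohort generator** that emulates the four clinical
  phenotypes at the signal level, so the whole pipeline is testable without
  patient data.

## The statistics at the core

**Sample Entropy** (Richman–Moorman). For a series of length *N*, template
length *m* = 2 and tolerance *r* = 0.2·SD:

    SampEn(m, r) = −ln(A / B)

where *B* counts pairs of length-*m* templates within Chebyshev distance
*r*, *A* counts the same pairs extended to length *m*+1, and self-matches
are excluded. Low SampEn means a regular, predictable trace; frequent
desaturation events raise it. The implementation is an exact O(N²) template
count (numba-compiled), verified against an independent brute-force oracle
to 1e-12 and against `pracma::sample_entropy` in R.

**Transfer Entropy.** For source *X* and target *Y* at lag τ = 5 s:

    TE(X→Y) = I(Y_{t+τ} ; X_t | Y_t)

estimated by plug-in entropies on 3-symbol equal-probability (quantile)
bins, in bits. Quantile binning makes the estimate invariant under any
strictly monotone rescaling of either signal. Finite-sample bias is removed
by subtracting the mean TE of circular time-shift surrogates of the source
(19 by default), floored at zero.

**Phenotype classifier.** With T90 = % of the night with SpO2 < 90%:

| T90 | SampEn SpO2 | label |
|---|---|---|
| < 30% | < 0.1456 | `NORMAL` |
| < 30% | ≥ 0.1456 | `OSA` |
| ≥ 30% | < 0.3504 | `HYPOXIA_LOW_AHI` (sustained hypoxaemia, AHI < 30/h) |
| ≥ 30% | ≥ 0.3504 | `HYPOXIA_HIGH_AHI` (sustained hypoxaemia, AHI ≥ 30/h) |

The default entropy cuts were chosen by constrained ROC optimisation on a
training cohort (full sensitivity for the OSA cut; high specificity for the
severe-hypoxaemia cut); `select_threshold` reproduces that construction on
any cohort.

## Worked example

```python
import sleepnet as sn

# one synthetic 8 h night with the OSA phenotype
study = sn.simulate_study(sn.phenotype_config("OSA", seed=5))

cleaned, report = sn.clean_study(study)
print(report.artifact_fractions())
# {'SPO2': 0.0043, 'HR': 0.0049, 'RR': 0.0060, 'NF': 0.0}

prof = sn.profile_study(cleaned)
print(round(prof.sampen_spo2, 4), round(prof.t90, 2))
# 0.2465 15.14

print(sn.classify_study(prof).label)
# OSA

net = sn.build_te_network(cleaned)
print(round(net.edge("RR", "SPO2").te_corrected, 4))
# 0.06
```

Reading: ~0.4% of SpO2 samples violated the plausibility rules and were
median-replaced (well under the 10% exclusion bound); the night spends 15%
below 90% saturation (below the 30% sustained-hypoxaemia gate) while its
SpO2 Sample Entropy 0.2465 exceeds the 0.1456 OSA cut, so the study is
labelled OSA; and the corrected 0.06 bits from RR into SpO2 reflects the
simulated respiratory events driving the desaturations.

The same flow from a shell, simulating a four-phenotype cohort and
analysing it end-to-end (per-group mean ± SD table, decisions CSV, TE
network JSON):

```sh
sleepnet demo --seed 100 --n 2 --duration-h 4 --out demo-out
# ... summary table ...
# classifier agreement with ground truth: 7/8
```

`sleepnet --help` lists the single-stage commands
(`simulate`, `ingest`, `clean`, `profile`, `te`, `classify`, `run`).

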