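"""Artifact cleaning, respiratory-rate derivation and oximetry summaries.

The artifact rules are simple physiological plausibility thresholds:
respiratory rate above 30 breaths/min, heart rate below 40 bpm and
SpO2 below 50% are treated as capture errors and replaced by the median
of the valid samples of that channel.  The per-channel artifact fraction
feeds the study-level inclusion decision (any channel at or above 10%
excludes the study).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.signal import find_peaks

from .signals_io import HR, NF, RR, SPO2, ChannelSeries, SleepStudy


@dataclass(frozen=True)
class ArtifactRule:
    """Plausibility predicate for one channel; failing samples are replaced."""

    channel: str
    is_valid: Callable[[np.ndarray], np.ndarray]
    description: str


DEFAULT_RULES: dict[str, ArtifactRule] = {
    RR: ArtifactRule(RR, lambda v: v <= 30, "RR > 30 breaths/min"),
    HR: ArtifactRule(HR, lambda v: v >= 40, "HR < 40 bpm"),
    SPO2: ArtifactRule(SPO2, lambda v: v >= 50, "SpO2 < 50%"),
}


@dataclass
class ChannelCleaningReport:
    channel: str
    artifact_count: int
    artifact_fraction: float
    replaced_indices: np.ndarray
    replacement_value: float | None
    rule: str


@dataclass
class CleaningReport:
    """Per-channel artifact accounting plus the study-level verdict."""

    per_channel: dict[str, ChannelCleaningReport] = field(default_factory=dict)

    def artifact_fractions(self) -> dict[str, float]:
        return {name: r.artifact_fraction for name, r in self.per_channel.items()}

    @property
    def include(self) -> bool:
        return all(f < 0.10 for f in self.artifact_fractions().values())

    def to_dict(self) -> dict:
        return {
            name: {
                "artifact_count": int(r.artifact_count),
                "artifact_fraction": float(r.artifact_fraction),
                "replaced_indices": [int(i) for i in r.replaced_indices],
                "replacement_value": None if r.replacement_value is None
                else float(r.replacement_value),
                "rule": r.rule,
            }
            for name, r in self.per_channel.items()
        }


def clean_channel(ch: ChannelSeries, rule: ArtifactRule) -> tuple[ChannelSeries, ChannelCleaningReport]:
    """Replace rule-violating samples by the median of the valid ones.

    Because the replacement value is computed from valid samples only, it
    always satisfies the predicate, making cleaning idempotent.
    """
    if rule.channel != ch.name:
        raise ValueError(f"rule for {rule.channel} applied to channel {ch.name}")
    valid = np.asarray(rule.is_valid(ch.values), dtype=bool)
    bad = ~valid
    count = int(bad.sum())
    if count == len(ch):
        raise ValueError(f"channel {ch.name} entirely artifactual; no valid median")
    if count == 0:
        report = ChannelCleaningReport(ch.name, 0, 0.0, np.empty(0, dtype=int),
                                       None, rule.description)
        return ch, report
    median = float(np.median(ch.values[valid]))
    cleaned = ch.values.copy()
    cleaned[bad] = median
    out = ChannelSeries(ch.name, cleaned, ch.rate_hz, ch.unit, ch.t0,
                        {**ch.provenance, "cleaned": rule.description})
    report = ChannelCleaningReport(ch.name, count, count / len(ch),
                                   np.flatnonzero(bad), median, rule.description)
    return out, report


def clean_study(study: SleepStudy,
                rules: dict[str, ArtifactRule] | None = None) -> tuple[SleepStudy, CleaningReport]:
    """Apply every matching artifact rule; channels without a rule pass through."""
    rules = DEFAULT_RULES if rules is None else rules
    report = CleaningReport()
    channels: dict[str, ChannelSeries] = {}
    for name, ch in study.channels.items():
        if name in rules:
            channels[name], report.per_channel[name] = clean_channel(ch, rules[name])
        else:
            channels[name] = ch
            report.per_channel[name] = ChannelCleaningReport(
                name, 0, 0.0, np.empty(0, dtype=int), None, "no rule")
    cleaned = SleepStudy(study.metadata, channels, study.event_log, study.raw_flow,
                         {**study.provenance, "cleaned": True})
    return cleaned, report


def derive_rr_from_flow(nf: ChannelSeries, refractory_s: float = 1.5,
                        prominence_frac: float = 0.2) -> ChannelSeries:
    """Derive a 1 Hz respiratory-rate channel from the nasal-flow trace.

    Breaths are detected as flow peaks separated by at least
    ``refractory_s`` seconds with prominence at least ``prominence_frac``
    of the flow's interquartile range; the instantaneous rate
    60 / inter-breath-interval is sampled-and-held onto the 1 s grid and
    clipped to [0, 60] breaths/min.  Works best on the native-rate flow,
    before the 1 Hz reduction.
    """
    v = nf.values - np.median(nf.values)
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    if iqr <= 0:
        raise ValueError("flow signal unusable for RR (flat trace)")
    peaks, _ = find_peaks(v, distance=max(1, int(round(refractory_s * nf.rate_hz))),
                          prominence=prominence_frac * iqr)
    if peaks.size < 2:
        raise ValueError("flow signal unusable for RR (fewer than 2 breaths detected)")
    # parabolic interpolation refines peak times below the sample grid
    offsets = np.zeros(peaks.size)
    inner = (peaks > 0) & (peaks < v.size - 1)
    pm, p0, pp = v[peaks[inner] - 1], v[peaks[inner]], v[peaks[inner] + 1]
    denom = pm - 2 * p0 + pp
    with np.errstate(divide="ignore", invalid="ignore"):
        off = 0.5 * (pm - pp) / denom
    offsets[inner] = np.where(np.isfinite(off), np.clip(off, -0.5, 0.5), 0.0)
    peak_t = nf.t0 + (peaks + offsets) / nf.rate_hz
    inst_rate = 60.0 / np.diff(peak_t)  # breaths/min, valid from each breath onward
    n_sec = int(np.floor(nf.duration_s))
    t_grid = nf.t0 + np.arange(n_sec)
    # sample-and-hold: rate of the most recent completed breath interval
    idx = np.searchsorted(peak_t[1:], t_grid, side="right") - 1
    rr = inst_rate[np.clip(idx, 0, inst_rate.size - 1)]
    rr = np.clip(rr, 0.0, 60.0)
    return ChannelSeries(RR, rr, 1.0, "breaths/min", nf.t0,
                         {"derived_from": "nasal flow", "n_breaths": int(peaks.size)})


def time_below_90(spo2: ChannelSeries, threshold: float = 90.0) -> float:
    """T90: percent of samples with SpO2 strictly below the threshold."""
    if spo2.name != SPO2:
        raise ValueError(f"time_below_90 expects the SPO2 channel, got {spo2.name}")
    if len(spo2) == 0:
        raise ValueError("empty SpO2 channel")
    return 100.0 * float(np.count_nonzero(spo2.values < threshold)) / len(spo2)


def channel_summary(ch: ChannelSeries) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n-1 denominator)."""
    if len(ch) < 2:
        raise ValueError(f"channel {ch.name}: need >= 2 samples for SD")
    return float(np.mean(ch.values)), float(np.std(ch.values, ddof=1))
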