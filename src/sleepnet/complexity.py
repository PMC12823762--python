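"""Sample Entropy of cleaned 1 Hz physiological series.

SampEn(m, r) = -ln(A/B), where B counts pairs of length-m templates
whose Chebyshev distance is within the tolerance r, A counts the same
pairs extended to length m+1, and self-matches are excluded (Richman &
Moorman).  Both counts run over the N-m templates starting at
0..N-m-1 so that every m-template has an (m+1)-extension.  Low values
indicate a regular, predictable signal; overnight SpO2 entropy rises
with the density of desaturation events.

The tolerance is expressed as a fraction of the series' own standard
deviation, which makes the statistic exactly invariant under affine
rescaling of the signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .preprocessing import channel_summary, time_below_90
from .signals_io import CHANNEL_ORDER, SPO2, SleepStudy


@dataclass(frozen=True)
class SampEnParams:
    """Template length m, tolerance r as a fraction of the channel SD."""

    m: int = 2
    r_frac: float = 0.2

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not self.r_frac > 0:
            raise ValueError("r_frac must be positive")


@njit(cache=True)
def _template_counts(x, m, r):  # pragma: no cover - exercised via sample_entropy
    n = x.shape[0]
    nt = n - m  # templates with an (m+1)-extension
    a = 0
    b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            ok = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    ok = False
                    break
            if ok:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def sample_entropy(x, p: SampEnParams = SampEnParams()) -> float:
    """Sample Entropy of a 1-D series; NaN when no template pair matches.

    A constant (zero-variance) series is defined as perfectly regular
    and returns 0.0.  ``float('nan')`` marks the genuinely undefined
    case (A or B zero); callers must not silently substitute a value.
    """
    x = np.ascontiguousarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("sample_entropy expects a 1-D series")
    if x.size <= p.m + 1:
        raise ValueError(f"series too short for m={p.m} (N={x.size})")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        return 0.0
    a, b = _template_counts(x, p.m, p.r_frac * sd)
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


@dataclass
class ChannelProfile:
    mean: float
    sd: float
    sampen: float  # NaN = undefined (no template matches)
    degenerate: bool = False  # constant channel: SampEn defined as 0


@dataclass
class VariabilityProfile:
    """Per-study variability metrics: mean, SD and SampEn per channel, plus T90."""

    study_id: str
    channels: dict[str, ChannelProfile]
    t90: float
    params: SampEnParams = field(default_factory=SampEnParams)
    phenotype: str | None = None  # ground truth, when known

    @property
    def sampen_spo2(self) -> float:
        return self.channels[SPO2].sampen

    def to_dict(self) -> dict:
        d = {"study_id": self.study_id, "t90": self.t90,
             "m": self.params.m, "r_frac": self.params.r_frac}
        if self.phenotype:
            d["phenotype"] = self.phenotype
        for name, cp in self.channels.items():
            key = name.lower()
            d[f"mean_{key}"] = cp.mean
            d[f"sd_{key}"] = cp.sd
            d[f"sampen_{key}"] = cp.sampen
            if cp.degenerate:
                d[f"sampen_{key}_degenerate"] = True
        return d


def profile_study(study: SleepStudy, p: SampEnParams = SampEnParams(),
                  only: tuple[str, ...] | None = None) -> VariabilityProfile:
    """Mean, SD and Sample Entropy for every present channel, plus T90.

    Entropy is computed over the full night (one value per study), on
    the cleaned series.  Channels absent from the study are simply
    absent from the profile; degenerate (constant) channels are flagged.
    ``only`` restricts profiling to a subset of channels (SpO2 is always
    included, since T90 needs it).
    """
    channels: dict[str, ChannelProfile] = {}
    for name in CHANNEL_ORDER:
        if name not in study.channels:
            continue
        if only is not None and name not in only and name != SPO2:
            continue
        ch = study.channels[name]
        mean, sd = channel_summary(ch)
        se = sample_entropy(ch.values, p)
        channels[name] = ChannelProfile(mean, sd, se, degenerate=(sd == 0))
    t90 = time_below_90(study.channels[SPO2])
    return VariabilityProfile(study.metadata.study_id, channels, t90, p,
                              phenotype=study.metadata.phenotype)
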