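"""Reading, validating and resampling polygraphy channels.

The canonical in-memory object is a :class:`SleepStudy`: a dictionary of
1 Hz :class:`ChannelSeries` (SpO2 always present; HR, RR, NF optional)
plus :class:`StudyMetadata`.  Studies can be read from a per-study CSV
(columns ``time_s, spo2, hr, rr, nf``; any subset of signal columns) or
from a plain EDF file through a user-supplied channel map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

# Canonical channel identifiers and their units.
SPO2 = "SPO2"
HR = "HR"
RR = "RR"
NF = "NF"
CHANNEL_UNITS = {SPO2: "%", HR: "bpm", RR: "breaths/min", NF: "a.u."}
CHANNEL_ORDER = (SPO2, HR, RR, NF)

# Default CSV column -> channel identifier mapping.
CSV_COLUMNS = {"spo2": SPO2, "hr": HR, "rr": RR, "nf": NF}


@dataclass
class ChannelSeries:
    """One physiological channel: a named, uniformly sampled series."""

    name: str
    values: np.ndarray
    rate_hz: float = 1.0
    unit: str = ""
    t0: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError(f"channel {self.name}: values must be a non-empty 1-D array")
        if not self.rate_hz > 0:
            raise ValueError(f"channel {self.name}: rate_hz must be positive")
        if not self.unit:
            self.unit = CHANNEL_UNITS.get(self.name, "")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate_hz

    def __len__(self) -> int:
        return self.values.size


@dataclass
class StudyMetadata:
    """Study-level metadata used by the inclusion rules and diagnostics.

    ``central_event_pct``, ``ahi`` and ``odi`` come from conventional
    scoring (or from the simulator's ground truth) and are carried as
    metadata; this package never scores events from raw flow.
    """

    study_id: str = "study"
    recording_hours: float = 0.0
    central_event_pct: float | None = None
    ahi: float | None = None
    odi: float | None = None
    age: float | None = None
    sex: str | None = None
    bmi: float | None = None
    phenotype: str | None = None  # ground-truth label (synthetic cohorts only)

    def __post_init__(self):
        if self.recording_hours < 0:
            raise ValueError("recording_hours must be >= 0")
        if self.central_event_pct is not None and not 0 <= self.central_event_pct <= 100:
            raise ValueError("central_event_pct must lie in [0, 100]")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyMetadata":
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        return cls(**known)


@dataclass
class SleepStudy:
    """A single night's multichannel record at 1 Hz plus metadata.

    ``event_log`` holds the simulator's ground-truth desaturation events
    and exists only for synthetic studies.  ``raw_flow`` optionally keeps
    the native-rate nasal-flow trace so that respiratory rate can be
    derived from it before the 1 Hz reduction.
    """

    metadata: StudyMetadata
    channels: dict[str, ChannelSeries]
    event_log: object | None = None
    raw_flow: ChannelSeries | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if SPO2 not in self.channels:
            raise ValueError("a SleepStudy requires an SPO2 channel")
        lengths = {c.name: len(c) for c in self.channels.values()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channels have unequal lengths: {lengths}")
        for c in self.channels.values():
            if c.rate_hz != 1.0:
                raise ValueError(f"channel {c.name} is not at 1 Hz (rate={c.rate_hz})")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_h(self) -> float:
        return self.n_samples / 3600.0

    def channel(self, name: str) -> ChannelSeries:
        return self.channels[name]


def resample_to_1hz(ch: ChannelSeries) -> ChannelSeries:
    """Reduce (or raise) a channel to the canonical 1 Hz grid.

    Down-sampling averages each 1-second bin, which is robust to
    beat-to-beat jitter in oximeter output; a channel already at 1 Hz is
    returned unchanged.  Rates below 1 Hz (or non-integer ratios) fall
    back to linear interpolation onto the 1 s grid and are flagged in
    provenance.
    """
    if ch.rate_hz == 1.0:
        return ch
    n_sec = int(np.floor(ch.duration_s))
    if n_sec < 1:
        raise ValueError(f"channel {ch.name}: shorter than one second")
    ratio = ch.rate_hz
    if ratio > 1 and float(ratio).is_integer():
        k = int(ratio)
        vals = ch.values[: n_sec * k].reshape(n_sec, k).mean(axis=1)
        prov = {**ch.provenance, "resampled_from_hz": ch.rate_hz, "method": "bin-mean"}
    else:
        # upsampling / awkward ratio: linear interpolation at bin centres
        t_in = ch.t0 + np.arange(ch.values.size) / ch.rate_hz
        t_out = ch.t0 + np.arange(n_sec) + 0.5
        vals = np.interp(t_out, t_in, ch.values)
        prov = {**ch.provenance, "resampled_from_hz": ch.rate_hz, "method": "linear-interp"}
    return ChannelSeries(ch.name, vals, 1.0, ch.unit, ch.t0, prov)


def _truncate_equal(channels: dict[str, ChannelSeries]) -> dict[str, ChannelSeries]:
    n = min(len(c) for c in channels.values())
    out = {}
    for name, c in channels.items():
        if len(c) != n:
            c = ChannelSeries(name, c.values[:n], 1.0, c.unit, c.t0,
                              {**c.provenance, "truncated_to": n})
        out[name] = c
    return out


def read_study_csv(path: str | Path, metadata: StudyMetadata | None = None,
                   channel_map: Mapping[str, str] | None = None) -> SleepStudy:
    """Read a per-study CSV (``time_s`` + one column per channel).

    A sidecar ``<stem>.meta.json`` is picked up automatically when no
    metadata is supplied.  The sampling rate is inferred from the time
    column and every channel is resampled to 1 Hz.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "time_s" not in cols:
        raise ValueError(f"{path}: CSV requires a 'time_s' column; got {list(df.columns)}")
    cmap = dict(CSV_COLUMNS)
    if channel_map:
        cmap.update({k.lower(): v for k, v in channel_map.items()})
    t = df[cols["time_s"]].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    rate = 1.0 / float(np.median(np.diff(t)))
    channels: dict[str, ChannelSeries] = {}
    for col, name in cmap.items():
        if col in cols:
            ch = ChannelSeries(name, df[cols[col]].to_numpy(dtype=float),
                               rate_hz=round(rate, 9), t0=float(t[0]))
            channels[name] = resample_to_1hz(ch)
    if SPO2 not in channels:
        raise ValueError(
            f"{path}: no SpO2 column found; available columns: {list(df.columns)}")
    channels = _truncate_equal(channels)
    if metadata is None:
        meta_path = path.with_suffix("").with_suffix(".meta.json") \
            if path.suffix == ".csv" else path.with_suffix(".meta.json")
        if meta_path.exists():
            metadata = StudyMetadata.from_dict(json.loads(meta_path.read_text()))
        else:
            metadata = StudyMetadata(study_id=path.stem)
    if metadata.recording_hours == 0:
        metadata.recording_hours = len(channels[SPO2]) / 3600.0
    return SleepStudy(metadata, channels, provenance={"source": str(path), "format": "csv"})


def write_study_csv(study: SleepStudy, path: str | Path) -> Path:
    """Write a study to CSV plus a ``.meta.json`` sidecar."""
    path = Path(path)
    data = {"time_s": np.arange(study.n_samples, dtype=float)}
    for name in CHANNEL_ORDER:
        if name in study.channels:
            data[name.lower()] = study.channels[name].values
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6g")
    meta_path = path.with_suffix(".meta.json")
    meta_path.write_text(json.dumps(study.metadata.to_dict(), indent=1))
    return path


def read_study_edf(path: str | Path, channel_map: Mapping[str, str],
                   metadata: StudyMetadata | None = None) -> SleepStudy:
    """Read a plain EDF file, mapping labels to canonical channels.

    ``channel_map`` maps EDF signal labels (matched case-insensitively)
    to canonical identifiers; no label guessing happens beyond the map.
    """
    from . import edf

    path = Path(path)
    labels, rates, signals = edf.read_edf(path)
    lower = {lab.strip().lower(): i for i, lab in enumerate(labels)}
    channels: dict[str, ChannelSeries] = {}
    for raw_label, name in channel_map.items():
        idx = lower.get(raw_label.strip().lower())
        if idx is None:
            raise ValueError(
                f"{path}: label {raw_label!r} not in EDF; available: {labels}")
        ch = ChannelSeries(name, signals[idx], rate_hz=rates[idx],
                           provenance={"edf_label": labels[idx]})
        channels[name] = resample_to_1hz(ch)
    if SPO2 not in channels:
        raise ValueError(f"{path}: channel_map must resolve an SPO2 channel")
    channels = _truncate_equal(channels)
    if metadata is None:
        metadata = StudyMetadata(study_id=path.stem)
    if metadata.recording_hours == 0:
        metadata.recording_hours = len(channels[SPO2]) / 3600.0
    return SleepStudy(metadata, channels, provenance={"source": str(path), "format": "edf"})


def write_study_edf(study: SleepStudy, path: str | Path) -> Path:
    """Write the study's 1 Hz channels to a plain 16-bit EDF file."""
    from . import edf

    names = [n for n in CHANNEL_ORDER if n in study.channels]
    edf.write_edf(
        path,
        labels=names,
        signals=[study.channels[n].values for n in names],
        rates=[1.0] * len(names),
        units=[study.channels[n].unit for n in names],
        physical_ranges=[_physical_range(n) for n in names],
    )
    return Path(path)


def _physical_range(name: str) -> tuple[float, float]:
    # generous fixed ranges keep 16-bit quantisation error negligible
    return {SPO2: (0.0, 100.0), HR: (0.0, 300.0),
            RR: (0.0, 120.0), NF: (-1000.0, 1000.0)}[name]


def read_study(path: str | Path, format: str = "csv",
               channel_map: Mapping[str, str] | None = None,
               metadata: StudyMetadata | None = None) -> SleepStudy:
    """Read a study from ``csv`` or ``edf`` into the canonical 1 Hz form."""
    fmt = format.lower()
    if fmt == "csv":
        return read_study_csv(path, metadata=metadata, channel_map=channel_map)
    if fmt == "edf":
        if channel_map is None:
            raise ValueError("EDF ingest requires a channel_map")
        return read_study_edf(path, channel_map, metadata=metadata)
    raise ValueError(f"unknown format {format!r} (expected 'csv' or 'edf')")


@dataclass
class InclusionVerdict:
    include: bool
    reasons: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.include


def check_inclusion(md: StudyMetadata, cleaning) -> InclusionVerdict:
    """Apply the study-level inclusion rules.

    A study is excluded if it is shorter than 4 h, if more than 20% of
    its scored events are central, or if any channel carries 10% or more
    artifactual samples (entropy estimates degrade beyond that).  The
    verdict enumerates every failed rule.
    """
    reasons: list[str] = []
    if md.recording_hours < 4:
        reasons.append(f"recording < 4 h ({md.recording_hours:.2f} h)")
    if md.central_event_pct is None:
        pass_central = True
    else:
        pass_central = md.central_event_pct <= 20
        if not pass_central:
            reasons.append(f"central events > 20% ({md.central_event_pct:.1f}%)")
    for name, frac in sorted(cleaning.artifact_fractions().items()):
        if frac >= 0.10:
            reasons.append(f"artifact fraction >= 10% on {name} ({100 * frac:.1f}%)")
    verdict = InclusionVerdict(include=not reasons, reasons=reasons)
    if md.central_event_pct is None:
        verdict.reasons.append("note: central_event_pct missing, rule skipped")
    return verdict
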