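"""Cohort orchestration: clean -> include -> profile -> TE -> classify.

One call, :func:`run_cohort`, takes a list of studies and a
:class:`PipelineConfig` and returns every stage's outputs: cleaning
reports and exclusions (with reasons), variability profiles, TE
networks, phenotype decisions, and a per-group summary table
(mean +/- SD of each metric).  Excluded studies carry no downstream
results.  All randomness is seeded through the config; re-running with
the same inputs reproduces every output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .complexity import SampEnParams, VariabilityProfile, profile_study
from .diagnostics import ClassifierThresholds, PhenotypeDecision, classify_study
from .preprocessing import DEFAULT_RULES, CleaningReport, clean_study
from .signals_io import InclusionVerdict, SleepStudy, check_inclusion
from .te_network import TENetwork, TEParams, build_te_network


@dataclass
class PipelineConfig:
    sampen: SampEnParams = field(default_factory=SampEnParams)
    te: TEParams = field(default_factory=TEParams)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    compute_te: bool = True

    def fingerprint(self) -> dict:
        return {
            "m": self.sampen.m, "r_frac": self.sampen.r_frac,
            "lag_s": self.te.lag_s, "n_bins": self.te.n_bins,
            "n_surrogates": self.te.n_surrogates,
            "sampen_osa_cut": self.thresholds.sampen_osa_cut,
            "sampen_high_ahi_cut": self.thresholds.sampen_high_ahi_cut,
            "t90_cut": self.thresholds.t90_cut,
        }


@dataclass
class StudyResult:
    study_id: str
    cleaning: CleaningReport
    verdict: InclusionVerdict
    profile: VariabilityProfile | None = None
    network: TENetwork | None = None
    decision: PhenotypeDecision | None = None


@dataclass
class CohortResults:
    config: PipelineConfig
    results: list[StudyResult]

    @property
    def included(self) -> list[StudyResult]:
        return [r for r in self.results if r.verdict.include]

    @property
    def excluded(self) -> list[StudyResult]:
        return [r for r in self.results if not r.verdict.include]

    @property
    def profiles(self) -> list[VariabilityProfile]:
        return [r.profile for r in self.included]

    @property
    def networks(self) -> list[TENetwork]:
        return [r.network for r in self.included if r.network is not None]

    @property
    def decisions(self) -> list[PhenotypeDecision]:
        return [r.decision for r in self.included]

    def profiles_frame(self) -> pd.DataFrame:
        return pd.DataFrame([p.to_dict() for p in self.profiles])

    def decisions_frame(self) -> pd.DataFrame:
        return pd.DataFrame([d.to_dict() for d in self.decisions])

    def summary_table(self, by: str = "phenotype") -> pd.DataFrame:
        """Per-group mean +/- SD of every profile metric."""
        df = self.profiles_frame()
        if by not in df.columns:
            raise ValueError(f"no {by!r} column available to group by")
        num = df.select_dtypes("number").columns
        g = df.groupby(by)[num]
        out = g.mean().round(4).astype(str) + " ± " + g.std().round(4).astype(str)
        out.insert(0, "n", g.size())
        return out

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "profiles.json").write_text(json.dumps(
            [p.to_dict() for p in self.profiles], indent=1, default=_jsonable))
        (outdir / "networks.json").write_text(json.dumps(
            [n.to_dict() for n in self.networks], indent=1, default=_jsonable))
        self.decisions_frame().to_csv(outdir / "decisions.csv", index=False)
        pd.DataFrame(
            [{"study_id": r.study_id, "reasons": "; ".join(r.verdict.reasons)}
             for r in self.excluded]).to_csv(outdir / "exclusions.csv", index=False)
        try:
            self.summary_table().to_csv(outdir / "summary.csv")
        except ValueError:
            pass  # no phenotype labels to group by
        (outdir / "config.json").write_text(json.dumps(self.config.fingerprint(), indent=1))
        return outdir


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def run_cohort(studies: list[SleepStudy],
               cfg: PipelineConfig | None = None) -> CohortResults:
    """Run the full pipeline over a cohort of 1 Hz studies."""
    if not studies:
        raise ValueError("empty cohort")
    cfg = cfg or PipelineConfig()
    results: list[StudyResult] = []
    for study in studies:
        cleaned, cleaning = clean_study(study, DEFAULT_RULES)
        verdict = check_inclusion(study.metadata, cleaning)
        res = StudyResult(study.metadata.study_id, cleaning, verdict)
        if verdict.include:
            res.profile = profile_study(cleaned, cfg.sampen)
            if cfg.compute_te and len(cleaned.channels) >= 2:
                res.network = build_te_network(cleaned, cfg.te)
            if not np.isnan(res.profile.sampen_spo2):
                res.decision = classify_study(res.profile, cfg.thresholds)
        results.append(res)
    return CohortResults(cfg, results)
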