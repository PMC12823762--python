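"""ROC analysis, constrained threshold selection and the phenotype classifier.

The classifier is a two-stage rule on the (T90, SampEn SpO2) plane.
T90 at or above 30% marks sustained nocturnal hypoxaemia; within each
T90 stratum a SampEn SpO2 cut separates the event-rich phenotype from
the quiet one.  The default entropy cuts (0.1456 to call OSA with full
sensitivity, 0.3504 to call high-event-rate hypoxaemia with high
specificity) were chosen on a training cohort by constrained ROC
optimisation, which :func:`select_threshold` reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .complexity import VariabilityProfile

NORMAL = "NORMAL"
OSA = "OSA"
HYPOXIA_HIGH_AHI = "HYPOXIA_HIGH_AHI"
HYPOXIA_LOW_AHI = "HYPOXIA_LOW_AHI"
PHENOTYPES = (NORMAL, OSA, HYPOXIA_HIGH_AHI, HYPOXIA_LOW_AHI)


@dataclass(frozen=True)
class ClassifierThresholds:
    sampen_osa_cut: float = 0.1456
    sampen_high_ahi_cut: float = 0.3504
    t90_cut: float = 30.0

    def __post_init__(self):
        if not 0 < self.sampen_osa_cut < self.sampen_high_ahi_cut:
            raise ValueError("require 0 < sampen_osa_cut < sampen_high_ahi_cut")
        if not 0 < self.t90_cut < 100:
            raise ValueError("t90_cut must lie in (0, 100)")


@dataclass
class PhenotypeDecision:
    study_id: str
    label: str
    t90: float
    sampen_spo2: float
    thresholds: ClassifierThresholds

    def to_dict(self) -> dict:
        return {"study_id": self.study_id, "label": self.label,
                "t90": self.t90, "sampen_spo2": self.sampen_spo2,
                "sampen_osa_cut": self.thresholds.sampen_osa_cut,
                "sampen_high_ahi_cut": self.thresholds.sampen_high_ahi_cut,
                "t90_cut": self.thresholds.t90_cut}


def classify_study(profile: VariabilityProfile,
                   th: ClassifierThresholds = ClassifierThresholds()) -> PhenotypeDecision:
    """Two-stage rule: T90 stratum first, then the SampEn SpO2 cut.

    All boundaries are inclusive (>=).  Undefined SampEn is an error;
    callers should have excluded degenerate studies upstream.
    """
    se = profile.sampen_spo2
    if np.isnan(se):
        raise ValueError(f"study {profile.study_id}: SampEn SpO2 undefined")
    if profile.t90 >= th.t90_cut:
        label = HYPOXIA_HIGH_AHI if se >= th.sampen_high_ahi_cut else HYPOXIA_LOW_AHI
    else:
        label = OSA if se >= th.sampen_osa_cut else NORMAL
    return PhenotypeDecision(profile.study_id, label, profile.t90, se, th)


@dataclass
class ROCResult:
    """Empirical ROC curve under the score-positive convention.

    ``thresholds[i]`` is the cut "call positive when score >= cut";
    sensitivity is non-increasing and specificity non-decreasing as the
    cut rises.  AUC uses the rank (Mann-Whitney) formulation with
    half-credit for ties.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def roc_auc(scores, labels) -> ROCResult:
    """Empirical ROC over all distinct cuts plus the rank-statistic AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.size != labels.size:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    cuts = np.unique(scores)  # ascending; cut = "positive iff score >= cut"
    # counts of scores >= cut, per class, via cumulative sums from the top
    order = np.argsort(scores, kind="mergesort")
    s_sorted = scores[order]
    l_sorted = labels[order]
    pos_ge = n_pos - np.searchsorted(s_sorted[l_sorted == 1], cuts, side="left")
    neg_ge = n_neg - np.searchsorted(s_sorted[l_sorted == 0], cuts, side="left")
    sens = pos_ge / n_pos
    spec = 1.0 - neg_ge / n_neg

    # AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos * n_neg), midranks for ties
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return ROCResult(cuts, sens, spec, float(auc), n_pos, n_neg)


@dataclass
class ThresholdChoice:
    cut: float
    sensitivity: float
    specificity: float
    constraint: str


def select_threshold(roc: ROCResult, min_sensitivity: float | None = None,
                     min_specificity: float | None = None) -> ThresholdChoice:
    """Pick the ROC cut meeting one constraint while maximising the other.

    Exactly one of ``min_sensitivity`` / ``min_specificity`` must be
    given.  Among feasible cuts the one maximising the unconstrained
    coordinate wins; remaining ties break toward the higher cut.
    """
    if (min_sensitivity is None) == (min_specificity is None):
        raise ValueError("specify exactly one of min_sensitivity / min_specificity")
    if min_sensitivity is not None:
        if min_sensitivity > 1:
            raise ValueError("min_sensitivity must be <= 1")
        feasible = roc.sensitivity >= min_sensitivity
        objective = roc.specificity
        constraint = f"sensitivity >= {min_sensitivity}"
        if not feasible.any():
            raise ValueError(
                f"unachievable constraint {constraint}; best sensitivity "
                f"{roc.sensitivity.max():.3f}")
    else:
        if min_specificity > 1:
            raise ValueError("min_specificity must be <= 1")
        feasible = roc.specificity >= min_specificity
        objective = roc.sensitivity
        constraint = f"specificity >= {min_specificity}"
        if not feasible.any():
            raise ValueError(
                f"unachievable constraint {constraint}; best specificity "
                f"{roc.specificity.max():.3f}")
    obj = np.where(feasible, objective, -np.inf)
    best = obj.max()
    idx = np.flatnonzero(obj == best)[-1]  # tie-break toward the higher cut
    return ThresholdChoice(float(roc.thresholds[idx]),
                           float(roc.sensitivity[idx]),
                           float(roc.specificity[idx]), constraint)


@dataclass
class LinearAssociation:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int


def linear_association(x, y) -> LinearAssociation:
    """Univariate OLS fit of y on x plus the Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length x, y with n >= 3")
    if np.std(x) == 0:
        raise ValueError("x has zero variance")
    fit = stats.linregress(x, y)
    return LinearAssociation(float(fit.slope), float(fit.intercept),
                             float(fit.rvalue), float(fit.pvalue), x.size)
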