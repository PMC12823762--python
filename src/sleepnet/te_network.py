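"""Directed Transfer Entropy over the four-channel polygraphy network.

TE(X -> Y) at lag tau is the conditional mutual information
I(Y_{t+tau} ; X_t | Y_t): the information the source's present adds
about the target's future beyond the target's own present.  Signals are
reduced to equal-probability symbols (quantile binning on order
statistics, so any strictly monotone transform of a signal leaves the
estimate unchanged) and the plug-in estimator is evaluated in bits.

The plug-in estimator is biased upward on finite data, so each edge
also carries a surrogate-corrected value: the mean TE over circular
time-shift surrogates of the source is subtracted and the result
floored at zero.  Time-shifting destroys the temporal alignment of the
two signals while preserving each signal's own dynamics, giving a null
for "no directed coupling".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .signals_io import CHANNEL_ORDER, SleepStudy


@dataclass(frozen=True)
class TEParams:
    lag_s: int = 5
    n_bins: int = 3
    n_surrogates: int = 19
    min_shift_s: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.lag_s < 1:
            raise ValueError("lag_s must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def symbolize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Map a series onto 0..n_bins-1 equal-probability symbols.

    Each interior bin edge is the midpoint of the two order statistics
    flanking the cut position.  When a run of tied values spans the cut,
    the whole tied mass goes to whichever side leaves the bin occupancy
    closer to equal.  Every comparison against an edge reduces to a
    comparison between data values, so the symbol sequence is exactly
    invariant under strictly increasing transforms.  Heavily tied data
    may occupy fewer than n_bins distinct symbols.
    """
    x = np.asarray(x, dtype=float)
    xs = np.sort(x)
    n = x.size
    edges = np.empty(n_bins - 1)
    for j in range(1, n_bins):
        k = (j * n) // n_bins
        a, b = xs[k - 1], xs[k]
        if a < b:
            edges[j - 1] = 0.5 * (a + b)
        else:  # tie spanning the cut
            lo = int(np.searchsorted(xs, a, side="left"))
            hi = int(np.searchsorted(xs, a, side="right"))
            if abs(lo - k) <= abs(hi - k):  # tied mass to the upper bin
                edges[j - 1] = 0.5 * (xs[lo - 1] + a) if lo > 0 else a - 1.0
            else:                           # tied mass to the lower bin
                edges[j - 1] = a
    return np.searchsorted(edges, x, side="left").astype(np.int64)


def _entropy_bits(symbols: np.ndarray) -> float:
    counts = np.bincount(symbols, minlength=1)
    p = counts[counts > 0] / symbols.size
    return float(-(p * np.log2(p)).sum())


def _te_from_symbols(xs: np.ndarray, ys: np.ndarray, tau: int, n_bins: int) -> float:
    yf = ys[tau:]
    yp = ys[:-tau]
    xp = xs[:-tau]
    # joint symbol codes; plug-in conditional mutual information in bits
    h_yf_yp = _entropy_bits(yf * n_bins + yp)
    h_yp_xp = _entropy_bits(yp * n_bins + xp)
    h_yp = _entropy_bits(yp)
    h_all = _entropy_bits((yf * n_bins + yp) * n_bins + xp)
    te = h_yf_yp + h_yp_xp - h_yp - h_all
    return max(te, 0.0)


@dataclass
class TEResult:
    te: float                 # raw plug-in estimate, bits
    te_corrected: float       # surrogate-mean subtracted, floored at 0
    p_value: float            # one-sided surrogate rank p
    flag: str | None = None   # e.g. "constant source/target"


def transfer_entropy(source, target, p: TEParams = TEParams(),
                     rng: np.random.Generator | None = None) -> TEResult:
    """TE(source -> target) in bits with surrogate bias correction.

    A constant source or target carries no transferable information and
    yields TE = 0 with a flag.  The one-sided p-value is the rank of the
    observed TE within the surrogate null, resolution 1/(n_surrogates+1).
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.size != target.size:
        raise ValueError("source and target must have equal length")
    n = source.size
    if n < 100 * p.lag_s:
        raise ValueError(f"series too short for TE (n={n}, need >= {100 * p.lag_s})")
    if np.all(source == source[0]) or np.all(target == target[0]):
        return TEResult(0.0, 0.0, 1.0, flag="constant source/target")
    rng = rng if rng is not None else np.random.default_rng(p.seed)
    xs = symbolize(source, p.n_bins)
    ys = symbolize(target, p.n_bins)
    te = _te_from_symbols(xs, ys, p.lag_s, p.n_bins)
    if p.n_surrogates < 1:
        return TEResult(te, te, np.nan)
    lo = p.min_shift_s
    shifts = rng.integers(lo, n - lo, size=p.n_surrogates)
    null = np.array([_te_from_symbols(np.roll(xs, int(s)), ys, p.lag_s, p.n_bins)
                     for s in shifts])
    corrected = max(te - float(null.mean()), 0.0)
    p_value = (1 + int(np.sum(null >= te))) / (p.n_surrogates + 1)
    return TEResult(te, corrected, p_value)


@dataclass
class TENetwork:
    """Directed TE over ordered channel pairs of one study."""

    study_id: str
    edges: dict[tuple[str, str], TEResult]
    params: TEParams = field(default_factory=TEParams)
    phenotype: str | None = None

    def edge(self, source: str, target: str) -> TEResult:
        return self.edges[(source, target)]

    def to_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "phenotype": self.phenotype,
            "lag_s": self.params.lag_s,
            "n_bins": self.params.n_bins,
            "n_surrogates": self.params.n_surrogates,
            "units": "bits",
            "edges": [
                {"source": s, "target": t, "te": r.te,
                 "te_corrected": r.te_corrected, "p_value": r.p_value,
                 **({"flag": r.flag} if r.flag else {})}
                for (s, t), r in self.edges.items()
            ],
        }


def build_te_network(study: SleepStudy, p: TEParams = TEParams()) -> TENetwork:
    """TE for every ordered pair of present channels (self-edges excluded).

    With all four channels present this yields the 12 off-diagonal edges
    of the 4x4 network map; missing channels simply drop their edges.
    """
    present = [c for c in CHANNEL_ORDER if c in study.channels]
    if len(present) < 2:
        raise ValueError("TE network requires at least two channels")
    rng = np.random.default_rng(p.seed)
    edges: dict[tuple[str, str], TEResult] = {}
    for src, tgt in itertools.permutations(present, 2):
        edges[(src, tgt)] = transfer_entropy(
            study.channels[src].values, study.channels[tgt].values, p, rng=rng)
    return TENetwork(study.metadata.study_id, edges, p,
                     phenotype=study.metadata.phenotype)


@dataclass
class EdgeComparison:
    edge: tuple[str, str]
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    direction: str        # "a>b", "b>a" or "tie"
    p_value: float
    significant: bool


def compare_edges(cohort_a: list[TENetwork], cohort_b: list[TENetwork],
                  alpha: float = 0.05, corrected: bool = True) -> list[EdgeComparison]:
    """Per-edge two-sided rank-sum comparison of two cohorts of networks.

    Uses the surrogate-corrected TE values by default.  Edges are
    compared over the intersection of the two cohorts' edge sets and
    returned in canonical channel order.  No multiplicity correction is
    applied; each edge is reported at the stated alpha.
    """
    if len(cohort_a) < 3 or len(cohort_b) < 3:
        raise ValueError("need at least 3 networks per cohort")
    edges_a = set(cohort_a[0].edges)
    edges_b = set(cohort_b[0].edges)
    common = edges_a & edges_b

    def value(net: TENetwork, e):
        r = net.edges[e]
        return r.te_corrected if corrected else r.te

    out = []
    order = [e for e in itertools.permutations(CHANNEL_ORDER, 2) if e in common]
    for e in order:
        va = np.array([value(n, e) for n in cohort_a])
        vb = np.array([value(n, e) for n in cohort_b])
        stat = stats.mannwhitneyu(va, vb, alternative="two-sided")
        med_a, med_b = float(np.median(va)), float(np.median(vb))
        direction = "a>b" if med_a > med_b else ("b>a" if med_b > med_a else "tie")
        out.append(EdgeComparison(e, med_a, med_b, va.size, vb.size,
                                  direction, float(stat.pvalue),
                                  bool(stat.pvalue < alpha)))
    return out
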