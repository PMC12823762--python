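"""Shared fixtures and independent oracle implementations.

The oracles here deliberately use different algorithms/code paths from
the package (vectorised pairwise template counting for Sample Entropy,
exhaustive pair counting for AUC) so that agreement is a genuine
cross-check.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def sampen_bruteforce(x, m: int, r_frac: float) -> float:
    """O(N^2) Sample Entropy by explicit pairwise Chebyshev distances."""
    x = np.asarray(x, dtype=float)
    r = r_frac * np.std(x, ddof=1)
    nt = x.size - m
    tmpl = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:nt]
    d_m = np.max(np.abs(tmpl[:, None, :m] - tmpl[None, :, :m]), axis=-1)
    d_m1 = np.max(np.abs(tmpl[:, None, :] - tmpl[None, :, :]), axis=-1)
    iu = np.triu_indices(nt, k=1)
    b = int(np.count_nonzero(d_m[iu] <= r))
    a = int(np.count_nonzero(d_m1[iu] <= r))
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


def auc_pair_counting(scores, labels) -> float:
    """AUC as the probability a positive outscores a negative (ties = 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (pos.size * neg.size)


@pytest.fixture(scope="session")
def short_study():
    """A 1-hour OSA study reused by ingest/cleaning tests."""
    from sleepnet import phenotype_config, simulate_study

    return simulate_study(phenotype_config("OSA", seed=42, duration_h=1.0))


@pytest.fixture(scope="session")
def default_cohort_20():
    """Default 8 h cohorts, n=20 per phenotype, cleaned SpO2 profiles.

    Shared across the cohort-level acceptance checks; profiling is
    restricted to SpO2 (plus T90), which is all those checks consume.
    """
    from sleepnet import clean_study, profile_study, simulate_cohort
    from sleepnet.signals_io import SPO2

    studies = simulate_cohort(20, base_seed=100)
    profiles = []
    for s in studies:
        cleaned, _ = clean_study(s)
        profiles.append(profile_study(cleaned, only=(SPO2,)))
    return profiles
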