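"""Transfer Entropy: analytic channels, invariances, networks, cohorts."""

import numpy as np
import pytest

from sleepnet import (TEParams, build_te_network, clean_study, compare_edges,
                      phenotype_config, simulate_study, transfer_entropy)
from sleepnet.signals_io import HR, NF, RR, SPO2, SleepStudy
from sleepnet.te_network import symbolize


def ar_coupled_pair(seed, n=5000, lag=5, smooth_source=False):
    """Unidirectional X -> Y coupling at the given lag.

    With ``smooth_source`` the driver is itself AR(1)-autocorrelated,
    spreading the detectable coupling over a band of lags (the shape
    real cardiorespiratory couplings show).
    """
    rng = np.random.default_rng(seed)
    if smooth_source:
        xe = rng.normal(size=n + lag)
        x = np.zeros(n + lag)
        for t in range(1, n + lag):
            x[t] = 0.8 * x[t - 1] + xe[t]
    else:
        x = rng.normal(size=n + lag)
    e = rng.normal(size=n + lag)
    y = np.zeros(n + lag)
    for t in range(lag, n + lag):
        y[t] = 0.5 * y[t - 1] + 0.5 * x[t - lag] + 0.5 * e[t]
    return x[lag:], y[lag:]


class TestTransferEntropy:
    def test_constant_source_is_zero(self):
        rng = np.random.default_rng(0)
        r = transfer_entropy(np.full(2000, 3.0), rng.normal(size=2000))
        assert r.te == 0.0 and r.flag == "constant source/target"

    def test_deterministic_lagged_copy_is_one_bit(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 20000).astype(float)
        y = np.roll(x, 5)
        r = transfer_entropy(x, y, TEParams(n_bins=2, n_surrogates=0))
        assert r.te == pytest.approx(1.0, abs=0.01)

    def test_independent_noise_corrected_near_zero(self):
        rng = np.random.default_rng(2)
        r = transfer_entropy(rng.normal(size=10000), rng.normal(size=10000))
        assert r.te_corrected <= 0.02

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            transfer_entropy(np.ones(100), np.ones(100), TEParams(lag_s=5))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=3000), rng.normal(size=3000)
        p = TEParams(n_surrogates=0)
        base = transfer_entropy(x, y, p).te
        assert transfer_entropy(np.exp(x), y, p).te == pytest.approx(base)
        assert transfer_entropy(x, y ** 3, p).te == pytest.approx(base)

    def test_directionality_on_coupled_pair(self):
        wins = 0
        for seed in range(20):
            x, y = ar_coupled_pair(seed)
            fw = transfer_entropy(x, y, TEParams(seed=seed)).te_corrected
            bw = transfer_entropy(y, x, TEParams(seed=seed)).te_corrected
            wins += fw > bw
        assert wins >= 18

    def test_lag_rises_into_coupling_band(self):
        x, y = ar_coupled_pair(123, n=20000, smooth_source=True)
        tes = {lag: transfer_entropy(x, y, TEParams(lag_s=lag,
                                                    n_surrogates=0)).te
               for lag in (1, 2, 3, 5, 6, 8)}
        assert tes[1] < tes[2] < tes[3] < tes[5]  # rises toward the band
        assert min(tes[5], tes[6]) > 4 * tes[1]   # stays high across 5-6 s

    def test_symbolize_equal_probability(self):
        rng = np.random.default_rng(5)
        s = symbolize(rng.normal(size=9000), 3)
        counts = np.bincount(s, minlength=3)
        assert counts.min() > 2500  # near-equal occupancy


class TestNetwork:
    def test_twelve_edges_with_four_channels(self, short_study):
        cleaned, _ = clean_study(short_study)
        net = build_te_network(cleaned, TEParams(n_surrogates=5))
        assert len(net.edges) == 12
        assert all(r.te >= 0 for r in net.edges.values())
        assert (SPO2, SPO2) not in net.edges

    def test_six_edges_without_nf(self, short_study):
        cleaned, _ = clean_study(short_study)
        partial = SleepStudy(cleaned.metadata,
                             {k: v for k, v in cleaned.channels.items() if k != NF})
        net = build_te_network(partial, TEParams(n_surrogates=0))
        assert len(net.edges) == 6

    def test_single_channel_errors(self, short_study):
        solo = SleepStudy(short_study.metadata,
                          {SPO2: short_study.channels[SPO2]})
        with pytest.raises(ValueError, match="two channels"):
            build_te_network(solo)

    def test_osa_couples_events_into_spo2(self):
        study = simulate_study(phenotype_config("OSA", seed=5, duration_h=2.0))
        cleaned, _ = clean_study(study)
        net = build_te_network(cleaned)
        assert net.edge(RR, SPO2).te_corrected > 0

    def test_independent_channels_all_near_zero(self):
        study = simulate_study(phenotype_config("NORMAL", seed=8, duration_h=2.0))
        rng = np.random.default_rng(8)
        # replace every channel by white noise: no coupling anywhere
        for name, ch in study.channels.items():
            ch.values[:] = rng.normal(90, 3, ch.values.size)
        net = build_te_network(study)
        assert all(r.te_corrected <= 0.02 for r in net.edges.values())


class TestCohortComparison:
    def _nets(self, ph, n, base_seed):
        out = []
        for i in range(n):
            s = simulate_study(phenotype_config(ph, seed=base_seed + i,
                                                duration_h=2.0))
            cleaned, _ = clean_study(s)
            out.append(build_te_network(cleaned))
        return out

    def test_identical_cohorts_not_significant(self):
        nets = self._nets("NORMAL", 5, 50)
        comps = compare_edges(nets, nets)
        assert not any(c.significant for c in comps)

    def test_small_cohort_errors(self):
        nets = self._nets("NORMAL", 2, 60)
        with pytest.raises(ValueError, match="at least 3"):
            compare_edges(nets, nets + nets[:1])

    def test_osa_raises_te_into_spo2(self):
        normal = self._nets("NORMAL", 8, 70)
        osa = self._nets("OSA", 8, 90)
        comps = {c.edge: c for c in compare_edges(normal, osa)}
        for src in (HR, RR, NF):
            c = comps[(src, SPO2)]
            assert c.significant and c.direction == "b>a", c
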