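"""Ingest, resampling, round trips and the inclusion rules."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sleepnet import (SPO2, HR, ChannelSeries, StudyMetadata, check_inclusion,
                      read_study, read_study_csv, resample_to_1hz,
                      simulate_study, phenotype_config, write_study_csv,
                      write_study_edf, read_study_edf)
from sleepnet.preprocessing import CleaningReport, ChannelCleaningReport


def _report(fractions):
    rep = CleaningReport()
    for name, f in fractions.items():
        rep.per_channel[name] = ChannelCleaningReport(
            name, int(f * 100), f, np.empty(0, dtype=int), None, "test")
    return rep


class TestResample:
    def test_identity_at_1hz(self):
        ch = ChannelSeries(SPO2, np.array([95.0, 94.0, 96.0]), rate_hz=1.0)
        assert resample_to_1hz(ch) is ch

    def test_bin_means_4hz_ramp(self):
        ch = ChannelSeries(HR, np.arange(8.0), rate_hz=4.0)
        out = resample_to_1hz(ch)
        assert out.rate_hz == 1.0
        np.testing.assert_allclose(out.values, [1.5, 5.5])

    @pytest.mark.parametrize("rate", [2.0, 4.0, 8.0])
    def test_constant_signal_any_rate(self, rate):
        ch = ChannelSeries(HR, np.full(int(60 * rate), 72.0), rate_hz=rate)
        out = resample_to_1hz(ch)
        assert len(out) == 60
        assert np.all(out.values == 72.0)

    @given(st.integers(2, 8), st.integers(10, 50))
    def test_integer_decimation_preserves_mean(self, k, n_sec):
        rng = np.random.default_rng(k * 1000 + n_sec)
        vals = rng.uniform(80, 100, size=k * n_sec)
        out = resample_to_1hz(ChannelSeries(SPO2, vals, rate_hz=float(k)))
        assert abs(out.values.mean() - vals.mean()) < 1e-9

    def test_upsampling_flagged(self):
        ch = ChannelSeries(SPO2, np.array([90.0, 95.0, 92.0]), rate_hz=0.5)
        out = resample_to_1hz(ch)
        assert out.provenance["method"] == "linear-interp"
        assert len(out) == 6


class TestCSV:
    def test_identity_ingest_1hz(self, tmp_path):
        n = 600
        df = pd.DataFrame({"time_s": np.arange(n), "spo2": np.full(n, 95.0),
                           "hr": np.full(n, 70.0)})
        p = tmp_path / "s.csv"
        df.to_csv(p, index=False)
        study = read_study(p, format="csv")
        assert set(study.channels) == {SPO2, HR}
        assert study.n_samples == 600

    def test_4hz_csv_decimated(self, tmp_path):
        n = 2400
        df = pd.DataFrame({"time_s": np.arange(n) / 4.0,
                           "spo2": np.full(n, 95.0)})
        p = tmp_path / "s4.csv"
        df.to_csv(p, index=False)
        study = read_study_csv(p)
        assert study.n_samples == 600

    def test_missing_spo2_is_hard_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"time_s": [0, 1], "hr": [70, 71]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="SpO2"):
            read_study_csv(p)

    def test_round_trip(self, tmp_path, short_study):
        p = tmp_path / "rt.csv"
        write_study_csv(short_study, p)
        back = read_study_csv(p)
        for name, ch in short_study.channels.items():
            np.testing.assert_allclose(back.channels[name].values, ch.values,
                                       rtol=1e-5, atol=1e-4)
        assert back.metadata.phenotype == "OSA"


class TestEDF:
    CMAP = {"SPO2": "SPO2", "HR": "HR", "RR": "RR", "NF": "NF"}

    def test_round_trip_within_quantisation(self, tmp_path, short_study):
        p = tmp_path / "rt.edf"
        write_study_edf(short_study, p)
        back = read_study_edf(p, self.CMAP)
        # quantisation: half a 16-bit step of each declared physical range
        steps = {"SPO2": 100 / 65535, "HR": 300 / 65535,
                 "RR": 120 / 65535, "NF": 2000 / 65535}
        for name, ch in short_study.channels.items():
            err = np.abs(back.channels[name].values - ch.values).max()
            assert err <= steps[name], name

    def test_many_seeds_round_trip(self, tmp_path):
        # broad determinism/fidelity sweep at small size
        for seed in range(10):
            study = simulate_study(phenotype_config("NORMAL", seed=seed,
                                                    duration_h=0.2))
            p = tmp_path / f"s{seed}.edf"
            write_study_edf(study, p)
            back = read_study_edf(p, self.CMAP)
            for name, ch in study.channels.items():
                assert np.abs(back.channels[name].values - ch.values).max() < 0.05

    def test_agrees_with_mne_reader(self, tmp_path, short_study):
        mne = pytest.importorskip("mne")
        p = tmp_path / "x.edf"
        write_study_edf(short_study, p)
        raw = mne.io.read_raw_edf(p, preload=True, verbose="error")
        data = raw.get_data()
        for i, name in enumerate(raw.ch_names):
            ours = short_study.channels[name].values
            assert np.abs(data[i][: ours.size] - ours).max() < 0.05

    def test_unmappable_label_lists_available(self, tmp_path, short_study):
        p = tmp_path / "x.edf"
        write_study_edf(short_study, p)
        with pytest.raises(ValueError, match="available"):
            read_study_edf(p, {"SaO2": "SPO2"})

    def test_cli_ingest_edf(self, tmp_path, short_study):
        from click.testing import CliRunner

        from sleepnet.cli import main

        edf_path = tmp_path / "in.edf"
        write_study_edf(short_study, edf_path)
        cmap = tmp_path / "map.json"
        cmap.write_text(json.dumps(self.CMAP))
        out = tmp_path / "out.csv"
        res = CliRunner().invoke(main, ["ingest", "--input", str(edf_path),
                                        "--format", "edf", "--channel-map",
                                        str(cmap), "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert out.exists()


class TestInclusion:
    def test_clean_study_included(self):
        md = StudyMetadata("ok", recording_hours=6, central_event_pct=5)
        v = check_inclusion(md, _report({"SPO2": 0.02, "HR": 0.02}))
        assert v.include

    def test_short_recording_excluded(self):
        md = StudyMetadata("short", recording_hours=3.5)
        v = check_inclusion(md, _report({"SPO2": 0.0}))
        assert not v.include
        assert any("recording < 4 h" in r for r in v.reasons)

    def test_artifact_boundary_inclusive(self):
        md = StudyMetadata("art", recording_hours=8)
        v = check_inclusion(md, _report({"HR": 0.10}))
        assert not v.include
        assert any("HR" in r for r in v.reasons)

    def test_central_events_rule(self):
        md = StudyMetadata("cen", recording_hours=8, central_event_pct=25)
        assert not check_inclusion(md, _report({"SPO2": 0.0})).include

    def test_missing_central_pct_passes_with_note(self):
        md = StudyMetadata("nocen", recording_hours=8)
        v = check_inclusion(md, _report({"SPO2": 0.0}))
        assert v.include
        assert any("central_event_pct missing" in r for r in v.reasons)

    def test_pure_function(self):
        md = StudyMetadata("p", recording_hours=2, central_event_pct=30)
        rep = _report({"SPO2": 0.2})
        a = check_inclusion(md, rep)
        b = check_inclusion(md, rep)
        assert a.include == b.include and a.reasons == b.reasons
        assert len(a.reasons) == 3  # every failed rule enumerated
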