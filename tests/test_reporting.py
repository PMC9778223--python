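"""Subject/group summaries, progress reports, and CSV/JSON round trips."""

import itertools

import numpy as np
import pytest

import kneemon as km
from kneemon import io as kio
from kneemon.errors import ConfigurationError, ParseError


def subject(sid="S1", group="healthy", week="single", rom=85.0,
            mav_vl=0.1, mav_vm=0.08, rms_vl=0.15, rms_vm=0.12):
    return km.SubjectSummary(sid, group, week, rom, mav_vl, mav_vm, rms_vl, rms_vm)


def pick(cohort, group, week):
    return [s for s in cohort if s.group_label == group and s.week_label == week]


class TestAggregateGroup:
    def test_bone_joint_first_week_rom(self, reference_cohort):
        g = km.aggregate_group(pick(reference_cohort, "bone_joint", "first"))
        assert round(g.mean_rom_deg, 1) == 85.5

    def test_healthy_cohort_rom_to_5_dp(self, reference_cohort):
        g = km.aggregate_group(pick(reference_cohort, "healthy", "single"))
        assert round(g.mean_rom_deg, 5) == 87.73333

    def test_single_subject_group_equals_subject(self):
        s = subject()
        g = km.aggregate_group([s])
        assert g.n_subjects == 1
        assert g.mean_rom_deg == s.avg_rom_deg
        assert g.mean_rms_vm_v == s.rms_vm_v

    def test_permutation_invariance(self, reference_cohort):
        members = pick(reference_cohort, "neuro", "last")
        results = {
            km.aggregate_group(list(p)) for p in itertools.permutations(members)
        }
        assert len(results) == 1

    def test_mixed_labels_rejected(self):
        with pytest.raises(ConfigurationError, match="mixed"):
            km.aggregate_group([subject(group="healthy"), subject(group="neuro")])
        with pytest.raises(ConfigurationError, match="mixed"):
            km.aggregate_group([subject(week="first"), subject(week="last")])

    def test_empty_group_rejected(self):
        with pytest.raises(ConfigurationError):
            km.aggregate_group([])


class TestSummarizeSubject:
    def test_one_session_identity(self, sim_session):
        emg, angle, _ = sim_session
        res = km.run_session(emg, angle, km.SessionConfig())
        s = km.summarize_subject([res], "S1")
        assert s.avg_rom_deg == res.averages.avg_rom_deg
        assert s.mav_vl_v == res.averages.avg_mav_vl_v

    def test_two_sessions_mean(self, sim_session):
        emg, angle, _ = sim_session
        r1 = km.run_session(emg, angle, km.SessionConfig())
        cfg2 = km.SimulationConfig(seed=77, rest_s=2.0)
        emg2, angle2, _ = km.simulate_session(cfg2)
        r2 = km.run_session(emg2, angle2, km.SessionConfig())
        s = km.summarize_subject([r1, r2], "S1")
        assert s.avg_rom_deg == pytest.approx(
            (r1.averages.avg_rom_deg + r2.averages.avg_rom_deg) / 2)

    def test_five_seeded_sessions_recover_peak(self):
        """End-to-end: five full sessions, avg ROM within [86, 90] of peak 88."""
        results = []
        for seed in range(5):
            cfg = km.SimulationConfig(seed=seed, rest_s=2.0, angle_noise_deg=0.5)
            emg, angle, _ = km.simulate_session(cfg)
            results.append(km.run_session(emg, angle, km.SessionConfig()))
        s = km.summarize_subject(results, "S1")
        assert 86.0 <= s.avg_rom_deg <= 90.0

    def test_no_completed_sessions_rejected(self, sim_session):
        emg, angle, truth = sim_session
        partial = km.early_stop(emg, angle, km.SessionConfig(), truth[0].t_peak_s)
        with pytest.raises(ConfigurationError, match="no completed"):
            km.summarize_subject([partial], "S1")


class TestProgressReport:
    def test_group_a_rom_improvement(self, reference_cohort):
        first = km.aggregate_group(pick(reference_cohort, "bone_joint", "first"))
        last = km.aggregate_group(pick(reference_cohort, "bone_joint", "last"))
        report = km.progress_report(first, last).as_dict()
        rom = report["mean_rom_deg"]
        assert rom.delta == pytest.approx(1.66667, abs=1e-4)
        assert rom.direction == "improved"

    def test_sub_band_change_reported_unchanged(self, reference_cohort):
        """Patient P2's VM features barely move between weeks: 'unchanged'."""
        p2 = {s.week_label: s for s in reference_cohort if s.subject_id == "P2"}
        report = km.progress_report(p2["first"], p2["last"]).as_dict()
        mav_vm = report["mav_vm_v"]
        assert mav_vm.delta == pytest.approx(-0.001, abs=1e-9)
        assert mav_vm.direction == "unchanged"
        assert report["mav_vl_v"].direction == "improved"

    def test_identical_summaries_all_unchanged(self):
        a = subject(week="first")
        b = subject(week="last")
        report = km.progress_report(a, b)
        assert all(d.delta == 0.0 and d.direction == "unchanged" for d in report.deltas)

    def test_antisymmetry(self, reference_cohort):
        first = km.aggregate_group(pick(reference_cohort, "neuro", "first"))
        last = km.aggregate_group(pick(reference_cohort, "neuro", "last"))
        fwd = km.progress_report(first, last).as_dict()
        rev = km.progress_report(last, first).as_dict()
        for name in fwd:
            assert fwd[name].delta == pytest.approx(-rev[name].delta)

    def test_mismatched_entities_rejected(self):
        with pytest.raises(ConfigurationError, match="mismatched"):
            km.progress_report(subject(sid="A", week="first"), subject(sid="B", week="last"))
        with pytest.raises(ConfigurationError, match="different weeks"):
            km.progress_report(subject(), subject())


class TestIoRoundTrips:
    def test_summary_csv_round_trip(self, reference_cohort, tmp_path):
        path = tmp_path / "summaries.csv"
        km.write_summary_csv(reference_cohort, path)
        back = km.load_summary_csv(path)
        assert back == reference_cohort

    def test_emg_csv_round_trip(self, tmp_path, rng):
        rec = km.EmgRecording(vl=rng.normal(0, 0.1, 500).round(6),
                              vm=rng.normal(0, 0.1, 500).round(6),
                              sampling_rate_hz=1000.0)
        path = tmp_path / "emg.csv"
        kio.write_emg_csv(rec, path)
        back = kio.load_emg_csv(path)
        np.testing.assert_allclose(back.vl, rec.vl, atol=1e-6)
        assert back.sampling_rate_hz == pytest.approx(1000.0)

    def test_angle_csv_round_trip_and_accel_autodetect(self, tmp_path):
        trace = km.AngleTrace(np.arange(30) * 0.1, np.linspace(0, 88, 30).round(6))
        path = tmp_path / "angle.csv"
        kio.write_angle_csv(trace, path)
        back = kio.load_angle_csv(path)
        np.testing.assert_allclose(back.theta_deg, trace.theta_deg, atol=1e-6)

        accel_path = tmp_path / "accel.csv"
        accel_path.write_text(
            "time_s,ax_g,ay_g,az_g\n0.0,0,0,1\n0.1,1,0,0\n", encoding="utf-8"
        )
        fused = kio.load_angle_csv(accel_path)
        np.testing.assert_allclose(fused.theta_deg, [0.0, 90.0], atol=1e-9)

    def test_config_json_round_trip(self, tmp_path):
        cfg = km.SessionConfig(subject_id="S9", knee_side="left",
                               targets=km.Targets(0.05, 0.04, 0.08, 0.06, 70.0))
        path = tmp_path / "cfg.json"
        kio.write_config_json(cfg, path)
        assert kio.load_config_json(path) == cfg

    def test_unknown_config_key_named(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"subject_id": "S1", "sandbags_kg": 2}', encoding="utf-8")
        with pytest.raises(ConfigurationError, match="sandbags_kg"):
            kio.load_config_json(path)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "emg.csv"
        path.write_text("time_s,vl_v\n0.0,0.1\n", encoding="utf-8")
        with pytest.raises(ParseError, match="vm_v"):
            kio.load_emg_csv(path)

    def test_non_numeric_cell_reports_line(self, tmp_path):
        path = tmp_path / "emg.csv"
        path.write_text("time_s,vl_v,vm_v\n0.0,0.1,0.2\n0.001,oops,0.2\n",
                        encoding="utf-8")
        with pytest.raises(ParseError, match="line 3"):
            kio.load_emg_csv(path)

    def test_empty_file_is_parse_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("", encoding="utf-8")
        with pytest.raises(ParseError, match="empty"):
            kio.load_emg_csv(path)

    def test_render_report_contains_rows_and_progress(self, reference_cohort):
        first = km.aggregate_group(pick(reference_cohort, "bone_joint", "first"))
        last = km.aggregate_group(pick(reference_cohort, "bone_joint", "last"))
        text = km.render_report(reference_cohort, [first, last],
                                [km.progress_report(first, last)])
        assert "H1" in text and "bone_joint" in text and "improved" in text
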