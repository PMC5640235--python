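import datetime
import random
import re

import numpy as np
import pytest

from campimetry.calibration import PhotometerMeasurement
from campimetry.engine import BrightnessSpec, ExamConfig, StimulusSpec, run_exam
from campimetry.errors import StorageError
from campimetry.fixation import FeedbackSpec, FixationConfig
from campimetry.geometry import FieldLocation, ScreenSetup
from campimetry.maps import build_map
from campimetry.observer import make_observer, tunnel_truth
from campimetry.storage import (
    ID_PATTERN,
    PatientRecord,
    RecordId,
    ScaleRecord,
    append_record,
    generate_id,
    load_result_map,
    load_settings,
    read_registry,
    rebuild_map,
    save_result,
    save_settings,
)
from conftest import quadratic_measurements


class TestRecordIds:
    def test_generated_id_matches_the_documented_pattern(self, rng):
        rid = generate_id("P", datetime.date(2017, 10, 13), rng)
        assert re.fullmatch(r"P_20171013_[A-Za-z0-9]{4}", rid)
        assert str(RecordId.parse(rid)) == rid

    @pytest.mark.parametrize("prefix", ["P", "S", "R"])
    def test_all_three_prefixes_supported(self, prefix, rng):
        assert generate_id(prefix, None, rng).startswith(prefix + "_")

    def test_unknown_prefix_rejected(self, rng):
        with pytest.raises(StorageError):
            generate_id("X", None, rng)

    def test_ten_thousand_draws_against_one_registry_stay_unique(self, rng):
        existing: set[str] = set()
        for _ in range(10_000):
            rid = generate_id("R", datetime.date(2020, 1, 1), rng, existing)
            assert rid not in existing
            existing.add(rid)

    def test_malformed_id_rejected(self):
        with pytest.raises(StorageError):
            RecordId.parse("Q_20171013_ab1")


class TestRegistries:
    def test_missing_or_empty_file_reads_as_empty(self, tmp_path):
        assert read_registry(tmp_path / "patients.s", PatientRecord) == []
        (tmp_path / "patients.s").write_text("")
        assert read_registry(tmp_path / "patients.s", PatientRecord) == []

    def test_append_then_read_round_trips_exactly(self, tmp_path):
        path = tmp_path / "patients.s"
        record = PatientRecord("P_20171013_ab1Z", "Jane\tDoe", "notes\nwith newline")
        append_record(path, record)
        append_record(path, PatientRecord("P_20171013_cd2Y", "", ""))
        records = read_registry(path, PatientRecord)
        assert records[0] == record
        assert len(records) == 2

    def test_scale_record_round_trip_preserves_measurements(self, tmp_path):
        path = tmp_path / "screenLuminanceScales.s"
        record = ScaleRecord(
            "S_20171013_aaaa", "green 534nm", 100.0, 100.0,
            tuple(quadratic_measurements()), "LS-100 photometer",
        )
        append_record(path, record)
        restored = read_registry(path, ScaleRecord)[0]
        assert restored == record
        assert restored.fit().l_max == pytest.approx(110.5)

    def test_malformed_line_names_its_line_number(self, tmp_path):
        path = tmp_path / "patients.s"
        path.write_text("P_20200101_aaaa\tok\tok\nonly-one-field\n")
        with pytest.raises(StorageError, match=":2"):
            read_registry(path, PatientRecord)

    def test_crashy_append_never_corrupts_prior_lines(self, tmp_path):
        path = tmp_path / "patients.s"
        append_record(path, PatientRecord("P_20200101_aaaa", "x", "y"))
        before = path.read_text()

        class Exploding(PatientRecord):
            def to_fields(self):
                raise RuntimeError("boom")

        with pytest.raises(RuntimeError):
            append_record(path, Exploding("P_20200101_bbbb"))
        assert path.read_text() == before


class TestSettingsTemplates:
    def full_config(self):
        return ExamConfig(
            screen=ScreenSetup(535.0, 300.0, 1920, 1080, 370.0),
            spacing_x_deg=5.98,
            spacing_y_deg=5.52,
            fixation_x_deg=-14.0,
            fixation_y_deg=0.0,
            sphericity=True,
            stimulus=StimulusSpec(
                shape="polygon", width_deg=0.5, height_deg=0.4, inclination_deg=30.0,
                display_time_ms=200.0, isi_min_ms=900.0, isi_max_ms=1300.0,
            ),
            brightness=BrightnessSpec(min_pct=11.0, max_pct=100.0, length=13),
            stimulus_scale_id="S_20171013_aaaa",
            background_scale_id="S_20171013_bbbb",
            background_brightness_pct=10,
            fixation=FixationConfig(
                technique="both",
                blindspot_location=FieldLocation(15.0, -3.0),
                control_brightness_pct=100,
                check_freq_min=5,
                check_freq_max=10,
                feedback=FeedbackSpec(enabled=True, text="fixate!", font_size_pt=30),
            ),
            seed=77,
        )

    def test_save_load_round_trip_is_identity(self, tmp_path):
        path = tmp_path / "template.sset"
        config = self.full_config()
        save_settings(config, path)
        assert load_settings(path) == config

    def test_default_blindspot_round_trips_as_default(self, tmp_path, screen):
        config = ExamConfig(screen=screen)
        assert config.fixation.blindspot_location is None
        path = tmp_path / "t.sset"
        save_settings(config, path)
        assert load_settings(path).fixation.blindspot_location is None

    def test_missing_procedure_section_is_an_error(self, tmp_path):
        path = tmp_path / "t.sset"
        save_settings(self.full_config(), path)
        text = re.sub(r"\[procedure\][^\[]*", "", path.read_text())
        path.write_text(text)
        with pytest.raises(StorageError, match="procedure"):
            load_settings(path)

    def test_unknown_keys_warn_but_load(self, tmp_path):
        path = tmp_path / "t.sset"
        save_settings(self.full_config(), path)
        path.write_text(path.read_text() + "\n[screen]\nfrobnicate = 1\n")
        with pytest.warns(UserWarning, match="frobnicate"):
            config = load_settings(path)
        assert config == self.full_config()


class TestResultFolders:
    @pytest.fixture
    def session(self, tiny_config, quad_scale):
        grid = tiny_config.make_grid()
        observer = make_observer(grid, tunnel_truth(grid, 10.0, radius_deg=15.0), seed=9)
        return run_exam(tiny_config, observer, quad_scale, eye="right",
                        rng=random.Random(9))

    def test_folder_layout_and_naming(self, session, tmp_path, rng):
        folder = save_result(session, tmp_path / "Results", "P_20200101_aaaa", rng,
                             date=datetime.date(2020, 1, 2))
        assert folder.parent.name == "P_20200101_aaaa"
        assert ID_PATTERN.match(folder.name) and folder.name.startswith("R_20200102_")
        for name in ("session.csv", "map.csv", "settings.sset", "scale.csv", "summary.json"):
            assert (folder / name).exists()

    def test_saved_map_can_be_rebuilt_bit_for_bit(self, session, tmp_path, rng):
        folder = save_result(session, tmp_path / "Results", "P_20200101_aaaa", rng)
        direct = build_map(session)
        rebuilt = rebuild_map(folder)
        assert rebuilt.locations == direct.locations
        assert np.array_equal(rebuilt.db_values, direct.db_values)
        assert rebuilt.l_max == direct.l_max
        loaded = load_result_map(folder)
        assert loaded.db_values == pytest.approx(direct.db_values)
        assert loaded.eye == "right"

    def test_two_results_for_one_patient_get_distinct_ids(self, session, tmp_path, rng):
        a = save_result(session, tmp_path / "Results", "P_20200101_aaaa", rng)
        b = save_result(session, tmp_path / "Results", "P_20200101_aaaa", rng)
        assert a != b
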