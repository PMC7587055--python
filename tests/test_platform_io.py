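"""Raw-export parsing, curve serialization, and merged-table round trips."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qpcrmap import (
    EmptyRunError,
    FluorescenceCurve,
    PlatformDescriptor,
    StructureError,
    CurveParseError,
    descriptor_from_json,
    descriptor_to_json,
    deserialize_curve,
    get_descriptor,
    parse_raw_run,
    read_merged_table,
    serialize_curve,
    write_merged_table,
)
from qpcrmap.platform_io import WELLS_AS_COLUMNS

from conftest import random_record
from qpcrmap.simulate import well_names


class TestParseRawRun:
    def test_minimal_mic_csv(self, tmp_path):
        p = tmp_path / "mic.csv"
        p.write_text("Cycle,A1,B2\n1,0.5,0.4\n2,0.6,0.5\n3,4.2,0.6\n")
        run = parse_raw_run(p, get_descriptor("mic"))
        assert set(run.curves) == {"A1", "B2"}
        assert run.curves["A1"].readings == (0.5, 0.6, 4.2)
        assert run.curves["B2"].cycles == (1, 2, 3)

    def test_non_increasing_cycles_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("Cycle,A1\n1,0.5\n2,0.6\n2,0.7\n")
        with pytest.raises(StructureError, match="strictly increasing"):
            parse_raw_run(p, get_descriptor("mic"))

    def test_ragged_well_names_offender(self, tmp_path):
        p = tmp_path / "ragged.csv"
        p.write_text("Cycle,A1,B2\n1,0.5,0.4\n2,0.6,\n3,0.7,0.6\n")
        with pytest.raises(StructureError, match="B2"):
            parse_raw_run(p, get_descriptor("mic"))

    def test_nonmatching_labels_reported_not_dropped(self, tmp_path):
        p = tmp_path / "mixed.csv"
        p.write_text("Cycle,A1,NTC_control\n1,0.5,0.4\n2,0.6,0.5\n")
        run = parse_raw_run(p, get_descriptor("mic"))
        assert set(run.curves) == {"A1"}
        assert run.rejected_wells == ("NTC_control",)

    def test_no_matching_wells_is_empty_run(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("Cycle,blank_1\n1,0.5\n2,0.6\n")
        with pytest.raises(EmptyRunError):
            parse_raw_run(p, get_descriptor("mic"))

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(OSError):
            parse_raw_run(tmp_path / "nope.csv", get_descriptor("mic"))

    @pytest.mark.parametrize("platform", ["mic", "biomeme2", "biomeme3"])
    def test_generator_matrix_reproduced_exactly(self, small_sim, platform):
        """Every dialect parses back to the generator's matrix, bitwise."""
        run = parse_raw_run(small_sim.paths[platform], get_descriptor(platform))
        assert len(run.curves) == small_sim.params.n_wells
        for i, well in enumerate(small_sim.well_ids):
            assert run.curves[well].readings == tuple(small_sim.matrix[i])

    def test_xlsx_dialect_via_descriptor(self, tmp_path, small_sim):
        import pandas as pd

        df = pd.read_csv(small_sim.paths["mic"])
        xlsx = tmp_path / "run.xlsx"
        df.to_excel(xlsx, index=False, sheet_name="raw")
        desc = PlatformDescriptor(
            platform_id="mic-xlsx",
            orientation=WELLS_AS_COLUMNS,
            cycle_field="Cycle",
            sheet_name="raw",
        )
        run = parse_raw_run(xlsx, desc)
        assert len(run.curves) == small_sim.params.n_wells


class TestDescriptor:
    def test_bad_orientation_rejected(self):
        with pytest.raises(ValueError):
            PlatformDescriptor("x", "diagonal", "Cycle")

    def test_json_round_trip(self, tmp_path):
        desc = get_descriptor("biomeme3")
        path = tmp_path / "desc.json"
        descriptor_to_json(desc, path)
        assert descriptor_from_json(path) == desc


class TestCurveStrings:
    def test_declared_format(self):
        c = FluorescenceCurve("A1", (1, 2, 3), (1.0, 2.5, 7.25))
        assert serialize_curve(c) == "1.0;2.5;7.25"

    def test_single_reading_curve_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            FluorescenceCurve("A1", (1,), (1.0,))

    def test_parse_error_names_token_position(self):
        with pytest.raises(CurveParseError) as err:
            deserialize_curve("1.0;;2.0")
        assert err.value.token_index == 2

    def test_deserialize_assigns_cycles(self):
        c = deserialize_curve("1.0;2.5;7.25")
        assert c.readings == (1.0, 2.5, 7.25)
        assert c.cycles == (1, 2, 3)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False).map(lambda x: round(x, 9)),
            min_size=2,
            max_size=40,
        )
    )
    def test_serialize_round_trip(self, readings):
        c = FluorescenceCurve("A1", tuple(range(1, len(readings) + 1)), tuple(readings))
        assert deserialize_curve(serialize_curve(c), well_id="A1") == c


class TestMergedTable:
    def test_empty_table_is_header_only(self, tmp_path):
        path = tmp_path / "m.csv"
        write_merged_table([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        header = lines[0].split(",")
        assert header[-2:] == ["fluorescence", "ct"]
        assert header[0] == "run_location"

    def test_two_record_round_trip(self, tmp_path):
        rng = random.Random(3)
        records = [random_record(rng, w) for w in ("A1", "B2")]
        path = tmp_path / "m.csv"
        write_merged_table(records, path)
        assert len(path.read_text().strip().splitlines()) == 3
        assert read_merged_table(path) == records

    def test_lossless_round_trip_many(self, tmp_path):
        rng = random.Random(42)
        records = [random_record(rng, w) for w in well_names(500)]
        path = tmp_path / "big.csv"
        write_merged_table(records, path)
        assert read_merged_table(path) == records

    def test_missing_ct_column_is_schema_error(self, tmp_path):
        from qpcrmap import SchemaError

        rng = random.Random(3)
        path = tmp_path / "m.csv"
        write_merged_table([random_record(rng, "A1")], path)
        import pandas as pd

        df = pd.read_csv(path).drop(columns=["ct"])
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="ct"):
            read_merged_table(path)
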