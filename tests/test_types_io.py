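"""Domain-type invariants and sheet/report round trips."""

import pytest

import potlipid as pl
from potlipid import compounds as cmp
from potlipid import io
from potlipid.types import (
    AcidQuant,
    IsotopeMeasurement,
    Peak,
    PeakTable,
    SampleRecord,
    SchemaError,
    TagProfile,
    ValidationError,
)


class TestInvariants:
    @pytest.mark.parametrize(
        "build",
        [
            lambda: SampleRecord("a", "S", lipid_concentration=-1.0),
            lambda: SampleRecord("", "S", lipid_concentration=1.0),
            lambda: IsotopeMeasurement(-50.0, -28.0),  # outside plausibility window
            lambda: IsotopeMeasurement(-28.0, -5.0),
            lambda: TagProfile({}),
            lambda: TagProfile({48: 0.0, 50: 0.0}),
            lambda: TagProfile({47: 1.0}),  # odd carbon number
            lambda: TagProfile({50: -0.1}),
            lambda: AcidQuant(tartaric=-0.5),
            lambda: Peak("x", "no_such_class"),
            lambda: Peak("x", "n_alkane", abundance=-1.0),
        ],
    )
    def test_invalid_values_rejected(self, build):
        with pytest.raises(ValidationError):
            build()

    def test_delta13c_is_difference_of_fatty_acid_values(self):
        m = IsotopeMeasurement(-26.0, -30.0)
        assert m.delta13c == pytest.approx(-4.0, abs=1e-9)

    def test_duplicate_peak_rows_rejected(self):
        with pytest.raises(ValidationError):
            PeakTable([cmp.alkane(29, 1.0), cmp.alkane(29, 2.0)])

    def test_named_sterols_share_structure_but_coexist(self):
        table = PeakTable(
            [cmp.sterol(cmp.B_SITOSTEROL, 1.0), cmp.sterol(cmp.A_SPINASTEROL, 2.0)]
        )
        assert len(table) == 2


class TestSampleSheet:
    def _sheet(self, tmp_path, text):
        p = tmp_path / "sheet.csv"
        p.write_text(text)
        return p

    def test_two_valid_rows_give_two_records(self, tmp_path):
        path = self._sheet(
            tmp_path,
            "sample_id,site,lipid_concentration\nA1,CSP,12.0\nA2,GA,40.5\n",
        )
        res = io.read_sample_sheet(path)
        assert len(res.records) == 2 and not res.diagnostics

    def test_negative_concentration_row_rejected_with_diagnostic(self, tmp_path):
        path = self._sheet(
            tmp_path,
            "sample_id,site,lipid_concentration\nA1,CSP,12.0\nA2,GA,-1.0\n",
        )
        res = io.read_sample_sheet(path)
        assert len(res.records) == 1
        assert len(res.diagnostics) == 1
        assert res.diagnostics[0].row_index == 1
        assert res.diagnostics[0].sample_id == "A2"

    def test_every_row_is_record_or_diagnostic(self, tmp_path):
        path = self._sheet(
            tmp_path,
            "sample_id,site,lipid_concentration,d13c_16_0,d13c_18_0\n"
            "A1,CSP,12.0,-28.0,-30.0\nA2,GA,-3.0,,\nA3,PB,,-27.0,-28.0\nA4,PB,8.0,,\n",
        )
        res = io.read_sample_sheet(path)
        assert len(res.records) + len(res.diagnostics) == 4

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        path = self._sheet(tmp_path, "sample_id,lipid_concentration\nA1,5\n")
        with pytest.raises(SchemaError, match="site"):
            io.read_sample_sheet(path)

    def test_duplicate_sample_id_is_validation_error(self, tmp_path):
        path = self._sheet(
            tmp_path, "sample_id,site,lipid_concentration\nA1,CSP,5\nA1,CSP,6\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            io.read_sample_sheet(path)

    def test_blank_isotopes_round_trip_as_absent(self, tmp_path):
        rec_with = SampleRecord(
            "W", "CSP", "olla", 20.0, isotopes=IsotopeMeasurement(-28.0, -30.0)
        )
        rec_without = SampleRecord("WO", "CSP", "olla", 20.0)
        out = tmp_path / "rt.csv"
        io.write_sample_sheet([rec_with, rec_without], out)
        res = io.read_sample_sheet(out)
        by_id = {r.sample_id: r for r in res.records}
        assert by_id["W"].isotopes == rec_with.isotopes
        assert by_id["WO"].isotopes is None

    def test_column_map_adapts_foreign_layout(self, tmp_path):
        path = self._sheet(tmp_path, "Sample,Site,Lipid (ug/g)\nA1,CSP,7.5\n")
        res = io.read_sample_sheet(
            path,
            column_map={
                "sample_id": "Sample",
                "site": "Site",
                "lipid_concentration": "Lipid (ug/g)",
            },
        )
        assert res.records[0].lipid_concentration == 7.5

    def test_generated_assemblage_round_trips(self, tmp_path, noisy_assemblage):
        records, _ = noisy_assemblage
        sheet = tmp_path / "s.csv"
        peaks = tmp_path / "p.csv"
        io.write_sample_sheet(records, sheet)
        io.write_peak_table({r.sample_id: r.peaks for r in records}, peaks)
        res = io.read_sample_sheet(sheet)
        assert len(res.records) == len(records) and not res.diagnostics
        tables = io.read_peak_table(peaks)
        io.attach_peaks(res.records, tables)
        for orig, back in zip(records, res.records):
            assert back.sample_id == orig.sample_id
            assert back.peaks == orig.peaks
            assert back.isotopes == orig.isotopes
            assert (back.acids is None) == (orig.acids is None)

    def test_unknown_compound_class_rows_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "p.csv"
        p.write_text(
            "sample_id,compound,compound_class,chain_length,"
            "substituent_position,unsaturation,abundance\n"
            "A1,n-alkane C29,n_alkane,29,0,0,5.0\n"
            "A1,mystery,exotic_class,0,0,0,1.0\n"
        )
        import logging

        with caplog.at_level(logging.WARNING):
            tables = io.read_peak_table(p)
        assert len(tables["A1"]) == 1
        assert "exotic_class" in caplog.text


class TestReport:
    @pytest.mark.parametrize("fmt", ["json", "tsv"])
    def test_round_trip_preserves_flags_and_notes(self, tmp_path, noisy_profiles, fmt):
        path = tmp_path / f"report.{fmt}"
        io.write_report(noisy_profiles[:25], path, format=fmt)
        rows = io.read_report(path, format=fmt)
        assert len(rows) == 25
        for (rec, prof), row in zip(noisy_profiles[:25], rows):
            assert row["sample_id"] == rec.sample_id
            assert row["flags"] == {k: v.value for k, v in prof.flags.items()}
            assert row["notes"] == prof.notes
            assert row["heating"] == prof.heating

    def test_empty_profile_list_is_error_not_empty_file(self, tmp_path):
        with pytest.raises(ValidationError):
            io.write_report([], tmp_path / "r.json")
        assert not (tmp_path / "r.json").exists()

    def test_single_profile_writes_one_data_row(self, tmp_path, noisy_profiles):
        path = tmp_path / "one.tsv"
        io.write_report(noisy_profiles[:1], path, format="tsv")
        assert len(path.read_text().splitlines()) == 2
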