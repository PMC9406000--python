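import numpy as np
import pandas as pd
import pytest

from shiftbind.peaklist_io import (
    AmidePeak,
    Condition,
    ShiftTable,
    read_shift_csv,
    read_sparky_list,
    write_csp_table,
    write_shift_csv,
    write_sparky_list,
)
import shiftbind as sb


class TestAmidePeak:
    def test_rejects_nonpositive_residue_number(self):
        with pytest.raises(ValueError, match="residue_number"):
            AmidePeak(residue_number=0, residue_code="D", shift_N=115.2, shift_H=8.4)

    def test_warns_but_keeps_out_of_window_shifts(self):
        with pytest.warns(UserWarning, match="amide window"):
            p = AmidePeak(residue_number=5, residue_code="G", shift_N=150.0, shift_H=8.0)
        assert p.shift_N == 150.0

    def test_in_window_shift_is_silent(self, recwarn):
        AmidePeak(residue_number=5, residue_code="G", shift_N=120.0, shift_H=8.0)
        assert not recwarn.list


class TestShiftTable:
    def test_rejects_proline(self):
        peak = AmidePeak(residue_number=3, residue_code="P", shift_N=120.0, shift_H=8.0)
        with pytest.raises(ValueError, match="proline"):
            ShiftTable([peak], Condition(ligand_conc=0.0))

    def test_rejects_duplicate_residue(self):
        peaks = [
            AmidePeak(residue_number=9, residue_code="D", shift_N=120.0, shift_H=8.0),
            AmidePeak(residue_number=9, residue_code="E", shift_N=121.0, shift_H=8.1),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            ShiftTable(peaks, Condition(ligand_conc=0.0))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="ligand_conc"):
            Condition(ligand_conc=-1.0)


class TestSparkyList:
    def test_reads_fixture(self, sparky_fixture):
        table = read_sparky_list(sparky_fixture)
        assert table.residues == [66, 99]
        assert table[99].residue_code == "D"
        assert table[66].residue_code == "E"
        assert table[99].shift_N == pytest.approx(115.20)
        assert table[99].shift_H == pytest.approx(8.41)

    def test_empty_file_gives_empty_table(self, tmp_path):
        path = tmp_path / "empty.list"
        path.write_text("      Assignment         w1         w2\n")
        assert len(read_sparky_list(path)) == 0

    @pytest.mark.parametrize(
        "line, match",
        [
            ("D99N-H abc 8.41", "non-numeric"),
            ("99D-NH 115.2 8.41", "assignment"),
            ("D99N-H 115.2", "fields"),
        ],
    )
    def test_malformed_line_names_line_number(self, tmp_path, line, match):
        path = tmp_path / "bad.list"
        path.write_text("Assignment w1 w2\n" + line + "\n")
        with pytest.raises(ValueError, match=match) as err:
            read_sparky_list(path)
        assert ":2:" in str(err.value)

    def test_duplicate_residue_is_hard_error(self, tmp_path):
        path = tmp_path / "dup.list"
        path.write_text("D99N-H 115.2 8.41\nD99N-H 115.3 8.42\n")
        with pytest.raises(ValueError, match="duplicate residue 99"):
            read_sparky_list(path)

    @pytest.mark.parametrize("suffix", ["N-H", "N-HN", "NH", ""])
    def test_assignment_dialects(self, tmp_path, suffix):
        path = tmp_path / "dialect.list"
        path.write_text(f"K15{suffix} 118.00 7.80\n")
        table = read_sparky_list(path)
        assert table.residues == [15]

    def test_axis_order_swap(self, tmp_path):
        path = tmp_path / "hn.list"
        path.write_text("D99N-H 8.41 115.20\n")
        table = read_sparky_list(path, axis_order="hn")
        assert table[99].shift_N == pytest.approx(115.20)

    def test_round_trip_preserves_shifts_to_4dp(self, tmp_path, noisy_two_site):
        tables, _ = noisy_two_site
        original = tables[3]
        path = tmp_path / "rt.list"
        write_sparky_list(original, path)
        back = read_sparky_list(path, original.condition)
        assert back.residues == original.residues
        for r in original.residues:
            assert back[r].shift_H == pytest.approx(original[r].shift_H, abs=5e-5)
            assert back[r].shift_N == pytest.approx(original[r].shift_N, abs=5e-5)


class TestShiftCsv:
    def _write(self, tmp_path, rows):
        path = tmp_path / "shifts.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    def test_groups_by_ligand_conc_ascending(self, tmp_path):
        rows = [
            dict(residue_number=99, residue_code="D", shift_N=115.2, shift_H=8.4, ligand_conc=10),
            dict(residue_number=66, residue_code="E", shift_N=120.1, shift_H=7.9, ligand_conc=10),
            dict(residue_number=99, residue_code="D", shift_N=115.1, shift_H=8.4, ligand_conc=0),
            dict(residue_number=66, residue_code="E", shift_N=120.0, shift_H=7.9, ligand_conc=0),
        ]
        tables = read_shift_csv(self._write(tmp_path, rows))
        assert [t.condition.ligand_conc for t in tables] == [0.0, 10.0]
        assert all(len(t) == 2 for t in tables)

    def test_missing_column_lists_names(self, tmp_path):
        rows = [dict(residue_number=99, shift_N=115.2, shift_H=8.4, ligand_conc=0)]
        with pytest.raises(ValueError, match="residue_code"):
            read_shift_csv(self._write(tmp_path, rows))

    def test_duplicate_residue_conc_pair_rejected(self, tmp_path):
        rows = [
            dict(residue_number=99, residue_code="D", shift_N=115.2, shift_H=8.4, ligand_conc=0),
            dict(residue_number=99, residue_code="D", shift_N=115.3, shift_H=8.4, ligand_conc=0),
        ]
        with pytest.raises(ValueError, match="duplicated"):
            read_shift_csv(self._write(tmp_path, rows))

    def test_round_trip_through_csv(self, tmp_path, noisy_two_site):
        tables, _ = noisy_two_site
        path = tmp_path / "titration.csv"
        write_shift_csv(tables, path)
        back = read_shift_csv(path)
        assert len(back) == len(tables)
        for a, b in zip(tables, back):
            assert a.condition.ligand_conc == b.condition.ligand_conc
            for r in a.residues:
                assert b[r].shift_H == pytest.approx(a[r].shift_H, abs=1e-6)


class TestCspTable:
    def test_row_count_and_round_trip(self, tmp_path, noiseless_two_site):
        tables, _ = noiseless_two_site
        profile = sb.build_profile(tables)
        path = tmp_path / "csp.tsv"
        write_csp_table(profile, path)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == len(profile.residues) * len(profile.points)
        row = df[(df.residue == 99) & (df.ligand_conc == 100.0)].iloc[0]
        rec = profile.records[99]
        assert row.delta_combined == pytest.approx(rec.delta_combined[-1], abs=1e-6)

    def test_untracked_rows_have_empty_shift_fields(self, tmp_path):
        spec = sb.two_site_spec(seed=2, noise_sd_H=0.0, noise_sd_N=0.0, dropout_rate=0.4)
        tables, _ = sb.simulate_titration(spec)
        profile = sb.build_profile(tables)
        path = tmp_path / "csp.tsv"
        write_csp_table(profile, path)
        df = pd.read_csv(path, sep="\t")
        untracked = df[~df.tracked]
        assert len(untracked) > 0
        assert untracked.delta_H.isna().all()

    def test_empty_profile_rejected(self, tmp_path):
        profile = sb.csp_profile.CSPProfile(
            reference=Condition(ligand_conc=0.0),
            points=[Condition(ligand_conc=0.0)],
            records={},
            reference_index=0,
        )
        with pytest.raises(ValueError, match="empty"):
            write_csp_table(profile, tmp_path / "x.tsv")
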