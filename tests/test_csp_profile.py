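import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import shiftbind as sb
from shiftbind.csp_profile import (
    build_profile,
    combined_csp,
    profile_from_arrays,
    salt_comparison,
    significance,
)
from shiftbind.peaklist_io import AmidePeak, Condition, ShiftTable


def _table(peaks, conc):
    return ShiftTable(
        [AmidePeak(residue_number=r, residue_code=c, shift_N=n, shift_H=h)
         for r, c, n, h in peaks],
        Condition(ligand_conc=conc),
    )


class TestCombinedCsp:
    @pytest.mark.parametrize(
        "dh, dn, expected",
        [
            (0.0, 0.0, 0.0),
            (0.03, 0.13, 0.036056),  # sqrt(0.0009 + 0.0004)
            (-0.03, -0.13, 0.036056),  # sign symmetric
        ],
    )
    def test_values(self, dh, dn, expected):
        assert combined_csp(dh, dn, 6.5) == pytest.approx(expected, abs=1e-6)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError, match="scale_N"):
            combined_csp(0.1, 0.1, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        dh=st.floats(-1, 1), dn=st.floats(-5, 5),
        bump=st.floats(0, 0.5),
    )
    def test_monotone_in_each_magnitude(self, dh, dn, bump):
        base = combined_csp(dh, dn)
        grow_h = combined_csp(np.sign(dh) * (abs(dh) + bump) or bump, dn)
        grow_n = combined_csp(dh, np.sign(dn) * (abs(dn) + bump) or bump)
        assert grow_h >= base - 1e-12
        assert grow_n >= base - 1e-12


class TestBuildProfile:
    def test_identical_tables_give_zero_csp(self):
        peaks = [(99, "D", 115.20, 8.41), (66, "E", 120.10, 7.95)]
        profile = build_profile([_table(peaks, 0.0), _table(peaks, 10.0)])
        for rec in profile.records.values():
            assert np.allclose(rec.delta_combined, 0.0)

    def test_hand_computed_deltas(self):
        ref = _table([(99, "D", 115.20, 8.41)], 0.0)
        pt = _table([(99, "D", 115.33, 8.44)], 20.0)
        profile = build_profile([ref, pt])
        rec = profile.records[99]
        assert rec.delta_H[1] == pytest.approx(0.03, abs=1e-12)
        assert rec.delta_N[1] == pytest.approx(0.13, abs=1e-12)
        assert rec.delta_combined[1] == pytest.approx(0.036056, abs=1e-6)
        # reference point is exactly zero
        assert rec.delta_combined[0] == 0.0

    def test_missing_at_one_point_only_untracks_that_point(self):
        ref = _table([(99, "D", 115.2, 8.4), (66, "E", 120.1, 7.9)], 0.0)
        mid = _table([(99, "D", 115.3, 8.4)], 60.0)  # 66 lost here
        top = _table([(99, "D", 115.4, 8.5), (66, "E", 120.2, 8.0)], 100.0)
        profile = build_profile([ref, mid, top])
        assert list(profile.records[66].tracked) == [True, False, True]
        assert list(profile.records[99].tracked) == [True, True, True]

    def test_residue_absent_from_reference_warns_and_excludes(self):
        ref = _table([(99, "D", 115.2, 8.4)], 0.0)
        pt = _table([(99, "D", 115.3, 8.4), (51, "E", 118.0, 8.2)], 100.0)
        with pytest.warns(UserWarning, match=r"\[51\]"):
            profile = build_profile([ref, pt])
        assert 51 not in profile.records

    def test_no_reference_is_hard_error(self):
        with pytest.raises(ValueError, match="reference"):
            build_profile(
                [_table([(99, "D", 115.2, 8.4)], 5.0),
                 _table([(99, "D", 115.3, 8.4)], 10.0)]
            )

    def test_points_sorted_by_concentration(self, noisy_two_site):
        tables, _ = noisy_two_site
        shuffled = [tables[0], tables[5], tables[2], tables[1]]
        profile = build_profile(shuffled)
        concs = profile.ligand_concs
        assert list(concs) == sorted(concs)

    def test_noiseless_csp_monotone_in_ligand(self, noiseless_two_site):
        tables, truth = noiseless_two_site
        profile = build_profile(tables)
        binding = {
            int(r)
            for site in truth["sites"].values()
            for r in site["residues"]
        }
        for r in binding:
            dc = profile.records[r].delta_combined
            assert np.all(np.diff(dc) >= -1e-12)


class TestSignificance:
    def test_zero_variance_flags_nothing(self):
        conds = [Condition(ligand_conc=0.0), Condition(ligand_conc=100.0)]
        dh = {r: [0.0, 0.02] for r in range(1, 6)}
        dn = {r: [0.0, 0.0] for r in range(1, 6)}
        profile = profile_from_arrays(conds, dh, dn)
        sig = significance(profile, 1)
        assert sig.sd == 0.0
        assert sig.threshold == pytest.approx(0.02)
        assert sig.flagged == frozenset()

    def test_single_outlier_hand_arithmetic(self):
        # ten residues at 0.01 and one at 0.20, sample (n-1) sd
        conds = [Condition(ligand_conc=0.0), Condition(ligand_conc=100.0)]
        values = [0.01] * 10 + [0.20]
        dh = {r: [0.0, v] for r, v in enumerate(values, start=1)}
        dn = {r: [0.0, 0.0] for r in range(1, 12)}
        profile = profile_from_arrays(conds, dh, dn)
        sig = significance(profile, 1)
        assert sig.mean == pytest.approx(0.027273, abs=1e-6)
        assert sig.sd == pytest.approx(0.057286, abs=1e-5)
        assert sig.threshold == pytest.approx(0.141844, abs=1e-5)
        assert sig.flagged == frozenset({11})

    def test_threshold_at_boundary_not_flagged(self):
        conds = [Condition(ligand_conc=0.0), Condition(ligand_conc=100.0)]
        values = [0.01, 0.01, 0.01, 0.05]  # mean 0.02, sd 0.02, threshold 0.06
        dh = {r: [0.0, v] for r, v in enumerate(values, start=1)}
        dn = {r: [0.0, 0.0] for r in range(1, 5)}
        sig = significance(profile_from_arrays(conds, dh, dn), 1)
        assert sig.threshold == pytest.approx(0.06, abs=1e-12)
        assert sig.flagged == frozenset()

    def test_fewer_than_two_tracked_is_hard_error(self):
        conds = [Condition(ligand_conc=0.0), Condition(ligand_conc=100.0)]
        profile = profile_from_arrays(conds, {1: [0.0, 0.1]}, {1: [0.0, 0.0]})
        with pytest.raises(ValueError, match="tracked"):
            significance(profile, 1)

    @pytest.mark.parametrize("scale", [0.5, 3.0])
    def test_uniform_rescaling_preserves_flags(self, noisy_two_site, scale):
        tables, _ = noisy_two_site
        profile = build_profile(tables)
        idx = len(profile.points) - 1
        base = significance(profile, idx)
        scaled = profile_from_arrays(
            profile.points,
            {r: rec.delta_H * scale for r, rec in profile.records.items()},
            {r: rec.delta_N * scale for r, rec in profile.records.items()},
        )
        sig = significance(scaled, idx)
        assert sig.mean == pytest.approx(base.mean * scale, rel=1e-9)
        assert sig.sd == pytest.approx(base.sd * scale, rel=1e-9)
        assert sig.threshold == pytest.approx(base.threshold * scale, rel=1e-9)
        assert sig.flagged == base.flagged


class TestSaltComparison:
    def test_control_mean_matches_hand_arithmetic(self):
        conds = [Condition(ligand_conc=0.0), Condition(ligand_conc=100.0)]
        ctrl_dh = {1: [0.0, -0.01], 2: [0.0, 0.0], 3: [0.0, -0.008]}
        zeros = {r: [0.0, 0.0] for r in ctrl_dh}
        control = profile_from_arrays(conds, ctrl_dh, zeros)
        test = profile_from_arrays(conds, {r: [0.0, 0.01] for r in ctrl_dh}, zeros)
        comp = salt_comparison(test, control, 100.0)
        assert comp.mean_delta_H == pytest.approx(-0.006, abs=1e-9)

    def test_identical_profiles_nothing_specific(self, noisy_two_site):
        tables, _ = noisy_two_site
        profile = build_profile(tables)
        comp = salt_comparison(profile, profile, 100.0)
        assert comp.specific == frozenset()

    def test_specific_is_set_difference(self, noisy_two_site):
        tables, _ = noisy_two_site
        test = build_profile(tables)
        # a control with the binding signal stripped: inert-only panel
        ctrl_tables, _ = sb.simulate_titration(
            sb.TitrationSimSpec(sites=[], inert_residues=25, seed=9)
        )
        # align residue numbering so profiles overlap
        control = build_profile(ctrl_tables)
        shared = set(test.records) & set(control.records)
        assert shared
        comp = salt_comparison(test, control, 100.0)
        assert comp.specific == comp.flagged_test - comp.flagged_control
        assert comp.specific <= comp.flagged_test

    def test_no_matching_point_is_error(self, noisy_two_site):
        tables, _ = noisy_two_site
        profile = build_profile(tables)
        with pytest.raises(ValueError, match="titration point"):
            salt_comparison(profile, profile, 7.0)
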