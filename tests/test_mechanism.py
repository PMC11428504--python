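"""Site activity, rankings, solvent shifts, mechanism verdicts and double HAT."""

import pytest
from hypothesis import given, settings, strategies as st

import radscav as rs
from radscav.errors import InvalidInputError, NotComputableError
from radscav.mechanism import (
    load_double_hat_fixture,
    second_hat_from_costs,
)
from radscav.descriptors import load_bde_ranking_fixture
from radscav.species import Species, normalize_site


class TestMinSite:
    def test_pt_gas_bde_minimum_is_4prime(self, table1):
        site, value = rs.min_site(table1, "Pt-3-O-glc", "gas", "bde")
        assert (site, value) == (normalize_site("4'-OH"), 86.2)

    def test_pt_water_pa_minimum_is_7(self, table1):
        site, value = rs.min_site(table1, "Pt-3-O-glc", "water", "pa")
        assert (site, value) == ("7-OH", 22.2)

    def test_tie_breaks_to_canonically_earlier_site(self):
        table = rs.DescriptorTable([
            rs.DescriptorRecord("C", "7-OH", "gas", bde=90.0),
            rs.DescriptorRecord("C", "4'-OH", "gas", bde=90.0),
        ])
        site, _ = rs.min_site(table, "C", "gas", "bde")
        assert site == normalize_site("4'-OH")

    def test_absent_descriptor_not_computable(self, table1):
        table = rs.DescriptorTable([rs.DescriptorRecord("C", "5-OH", "gas", bde=90.0)])
        with pytest.raises(NotComputableError):
            rs.min_site(table, "C", "gas", "pa")

    @settings(derandomize=True, max_examples=30)
    @given(values=st.lists(st.floats(10, 300), min_size=1, max_size=5))
    def test_minimum_not_exceeding_any_input(self, values):
        sites = ["3'-OH", "4'-OH", "5'-OH", "5-OH", "7-OH"]
        table = rs.DescriptorTable([
            rs.DescriptorRecord("C", s, "gas", bde=v)
            for s, v in zip(sites, values)])
        _, best = rs.min_site(table, "C", "gas", "bde")
        assert all(best <= v for v in values)


class TestRankCompounds:
    def test_text_quoted_4prime_gas_ranking(self):
        ranking = rs.rank_compounds(load_bde_ranking_fixture(), "bde", "4'-OH", "gas")
        assert ranking.order() == ("Pt-3-O-glc", "Dp-3-O-glc", "Mv-3-O-glc",
                                   "Cy-3-O-glc", "Pn-3-O-glc")
        assert ranking.ranked[0][1] == 86.2

    def test_lowest_gas_ete_compound_is_pt(self, table1):
        best_per_compound = {
            compound: rs.min_site(table1, compound, "gas", "ete")
            for compound in table1.compounds()}
        winner = min(best_per_compound, key=lambda c: best_per_compound[c][1])
        assert winner == "Pt-3-O-glc"
        assert best_per_compound[winner] == (normalize_site("3'-OH"), 130.0)

    def test_singleton_table(self):
        table = rs.DescriptorTable([rs.DescriptorRecord("C", "4'-OH", "gas", bde=90.0)])
        ranking = rs.rank_compounds(table, "bde", "4'-OH", "gas")
        assert ranking.ranked == (("C", 90.0),)

    def test_missing_rows_listed_unranked(self, table1):
        # 3'-OH exists only for Dp and Pt
        ranking = rs.rank_compounds(table1, "bde", "3'-OH", "gas")
        assert set(ranking.unranked) == {"Cy-3-O-glc", "Mv-3-O-glc", "Pn-3-O-glc"}
        assert ranking.order() == ("Pt-3-O-glc", "Dp-3-O-glc")

    def test_output_is_permutation_of_ranked_inputs(self, table1):
        ranking = rs.rank_compounds(table1, "bde", "4'-OH", "gas")
        assert sorted(ranking.order()) == sorted(
            set(table1.compounds()) - set(ranking.unranked))


class TestClassifyMechanism:
    def test_pt_gas_is_hat(self, table1):
        v = rs.classify_mechanism(table1, "Pt-3-O-glc", "gas")
        assert v.mechanism == "HAT"
        assert v.min_bde == (normalize_site("4'-OH"), 86.2)
        assert v.ip == 239.6
        assert v.min_pa == ("7-OH", 247.3)

    def test_pt_water_is_splet(self, table1):
        v = rs.classify_mechanism(table1, "Pt-3-O-glc", "water")
        assert v.mechanism == "SPLET"
        assert v.min_bde[1] == 83.7 and v.ip == 138.1 and v.min_pa[1] == 22.2

    def test_all_compounds_hat_in_gas_splet_in_solvents(self, table1):
        for compound in table1.compounds():
            assert rs.classify_mechanism(table1, compound, "gas").mechanism == "HAT"
            for solvent in ("water", "ethanol"):
                assert rs.classify_mechanism(table1, compound,
                                             solvent).mechanism == "SPLET"

    def test_low_ip_forces_set_pt(self):
        table = rs.DescriptorTable([
            rs.DescriptorRecord("C", "4'-OH", "gas", bde=86.0, ip=50.0, pa=250.0)])
        assert rs.classify_mechanism(table, "C", "gas").mechanism == "SET-PT"

    def test_exact_tie_reports_priority_with_flag(self):
        table = rs.DescriptorTable([
            rs.DescriptorRecord("C", "4'-OH", "gas", bde=86.0, ip=86.0, pa=86.0)])
        v = rs.classify_mechanism(table, "C", "gas")
        assert v.mechanism == "HAT" and v.tie

    def test_missing_leg_not_computable(self):
        table = rs.DescriptorTable([
            rs.DescriptorRecord("C", "4'-OH", "gas", bde=86.0, ip=240.0)])
        with pytest.raises(NotComputableError):
            rs.classify_mechanism(table, "C", "gas")


class TestSolventShift:
    def test_ip_gas_to_water_mean(self, table1):
        shift = rs.solvent_shift_summary(table1, "ip", "gas", "water")
        assert shift.mean == pytest.approx(101.5, abs=0.05)
        assert len(shift.per_compound) == 5

    def test_ip_gas_to_ethanol_mean(self, table1):
        shift = rs.solvent_shift_summary(table1, "ip", "gas", "ethanol")
        assert shift.mean == pytest.approx(105.6, abs=0.05)

    def test_identical_phases_give_zero(self, table1):
        shift = rs.solvent_shift_summary(table1, "ip", "gas", "gas")
        assert all(v == 0.0 for v in shift.per_compound.values())

    def test_no_overlap_not_computable(self):
        table = rs.DescriptorTable([rs.DescriptorRecord("C", "4'-OH", "gas", ip=240.0)])
        with pytest.raises(NotComputableError):
            rs.solvent_shift_summary(table, "ip", "gas", "water")


class TestSubstituentContrast:
    def test_methoxy_hydroxy_substitution_lowers_4prime_bde(self, table1):
        contrast = rs.substituent_contrast(table1, "bde", "4'-OH", "gas",
                                           "Pn-3-O-glc",
                                           ["Mv-3-O-glc", "Pt-3-O-glc"])
        assert contrast == pytest.approx(6.6, abs=1e-9)

    def test_self_contrast_is_zero(self, table1):
        assert rs.substituent_contrast(table1, "bde", "4'-OH", "gas",
                                       "Pn-3-O-glc", ["Pn-3-O-glc"]) == 0.0

    def test_single_contrast_is_plain_difference(self, table1):
        assert rs.substituent_contrast(table1, "bde", "4'-OH", "gas",
                                       "Pn-3-O-glc", ["Pt-3-O-glc"]) \
            == pytest.approx(93.4 - 86.2, abs=1e-9)


class TestSecondHAT:
    def test_fixture_favors_benzodioxole_in_every_phase(self):
        results = load_double_hat_fixture()
        assert len(results) == 3
        for res in results:
            assert res.favored == "benzodioxole"
        gas = next(r for r in results if r.phase == "gas")
        assert gas.channels["benzodioxole"][1] == 44.4
        assert gas.channels["o-quinone"] == ("singlet", 80.8)
        water = next(r for r in results if r.phase == "water")
        assert water.channels["benzodioxole"][1] == 48.3
        assert water.channels["o-quinone"][1] == 75.9

    def test_cheaper_o_quinone_wins_argmin(self):
        res = second_hat_from_costs("X", "gas", "4'-OH",
                                    {"benzodioxole": 60.0, "o-quinone": 41.0})
        assert res.favored == "o-quinone"

    def test_species_level_costs_match_acceptor_convention(self, refs):
        gas = refs["gas"]
        parent = Species("Pt-3-O-glc", "parent", "gas", -1000.0)
        radical = Species("Pt-3-O-glc", "radical", "gas",
                          -1000.0 + 86.2 - gas.h_hydrogen_atom, site="4'-OH")
        h_rad = radical.enthalpy
        prods = [
            Species("benzodioxole", "product", "gas",
                    h_rad + 44.4 - gas.h_hydrogen_atom, spin_state="singlet"),
            Species("o-quinone", "product", "gas",
                    h_rad + 80.8 - gas.h_hydrogen_atom, spin_state="singlet"),
        ]
        res = rs.second_hat_analysis(parent, radical, prods, gas)
        assert res.favored == "benzodioxole"
        assert res.channels["benzodioxole"][1] == pytest.approx(44.4, abs=1e-9)
        assert res.channels["o-quinone"][1] == pytest.approx(80.8, abs=1e-9)

    def test_lowest_spin_state_selected_and_recorded(self, refs):
        gas = refs["gas"]
        parent = Species("X", "parent", "gas", -1000.0)
        radical = Species("X", "radical", "gas", -900.0, site="3'-OH")
        prods = [Species("o-quinone", "product", "gas", -870.0, spin_state="triplet"),
                 Species("o-quinone", "product", "gas", -880.0, spin_state="singlet")]
        res = rs.second_hat_analysis(parent, radical, prods, gas)
        assert res.channels["o-quinone"][0] == "singlet"

    @settings(derandomize=True, max_examples=20)
    @given(perm=st.permutations([("a", 50.0), ("b", 44.4), ("c", 80.8)]))
    def test_favored_invariant_to_channel_order(self, perm):
        res = second_hat_from_costs("X", "gas", "4'-OH", dict(perm))
        assert res.favored == "b"

    def test_no_channels_is_an_error(self, refs):
        parent = Species("X", "parent", "gas", -1000.0)
        radical = Species("X", "radical", "gas", -900.0, site="3'-OH")
        with pytest.raises(InvalidInputError):
            rs.second_hat_analysis(parent, radical, [], refs["gas"])
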