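"""PES assembly, Wigner tunnelling and transition-state-theory rates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import radscav as rs
from radscav.errors import InvalidInputError, NotComputableError
from radscav.kinetics import PC, PRODUCTS, check_rank_consistency
from radscav.species import Species

# independent constants oracle: CODATA 2018 literals, typed here on purpose
KB = 1.380649e-23        # J/K
H = 6.62607015e-34       # J s
C_CM = 2.99792458e10     # cm/s
R_KCAL = 8.31446261815324 / 4184.0  # kcal mol^-1 K^-1


def pes_species(barrier=7.6, reaction_energy=-31.1, rc=-502.0, with_pc=True,
                nu=None):
    species = [
        Species("R", "parent", "gas", -500.0, gibbs=-500.0),
        Species("OH", "co_reactant", "gas", 0.0, gibbs=0.0),
        Species("R", "pre_complex", "gas", rc, gibbs=rc, site="4'-OH"),
        Species("R", "transition_state", "gas", rc + barrier, gibbs=rc + barrier,
                site="4'-OH", imaginary_wavenumber=nu),
    ]
    if with_pc:
        species.append(Species("R", "post_complex", "gas", rc + reaction_energy,
                               gibbs=rc + reaction_energy, site="4'-OH"))
    return species


class TestBuildPES:
    def test_profile_re_referenced_to_rc(self):
        profile = rs.build_pes(pes_species())
        rel = profile.relative
        assert rel["rc"] == 0.0
        assert rel["ts"] == pytest.approx(7.6)
        assert rel["pc"] == pytest.approx(-31.1)
        assert rel["reactants"] == pytest.approx(2.0)
        # absolute energies retained
        assert profile.gibbs["rc"] == -502.0

    def test_missing_ts_is_an_error(self):
        species = [sp for sp in pes_species() if sp.role != "transition_state"]
        with pytest.raises(InvalidInputError):
            rs.build_pes(species)

    def test_ts_below_rc_flags_barrierless(self):
        profile = rs.build_pes(pes_species(barrier=-1.0))
        assert profile.barrierless
        assert rs.activation_free_energy(profile) == pytest.approx(-1.0)

    def test_mixed_phases_rejected(self):
        species = pes_species()
        species[1] = Species("OH", "co_reactant", "water", 0.0, gibbs=0.0)
        with pytest.raises(rs.errors.PhaseMismatchError):
            rs.build_pes(species)


class TestProfileEnergies:
    @pytest.mark.parametrize("barrier", [7.6, 9.8, 0.0])
    def test_activation_energy_is_ts_minus_rc(self, barrier):
        profile = rs.build_pes(pes_species(barrier=barrier))
        assert rs.activation_free_energy(profile) == pytest.approx(barrier)

    @pytest.mark.parametrize("dg", [-31.1, -21.2])
    def test_reaction_energy_to_post_complex(self, dg):
        profile = rs.build_pes(pes_species(reaction_energy=dg))
        assert rs.reaction_free_energy(profile, PC) == pytest.approx(dg)

    def test_rc_endpoint_is_zero_and_missing_endpoint_errors(self):
        profile = rs.build_pes(pes_species(with_pc=False))
        assert rs.reaction_free_energy(profile, "rc") == 0.0
        with pytest.raises(NotComputableError):
            rs.reaction_free_energy(profile, PC)


class TestWigner:
    def test_kappa_tends_to_one_as_wavenumber_vanishes(self):
        assert rs.wigner_kappa(1e-6) - 1.0 < 1e-12

    def test_value_against_independent_constants(self):
        u = H * C_CM * 1500.0 / (KB * 298.15)
        expected = 1.0 + u * u / 24.0
        assert rs.wigner_kappa(1500.0, 298.15) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3.18, abs=0.005)

    @settings(derandomize=True, max_examples=30)
    @given(nu=st.floats(10.0, 4000.0), t=st.floats(150.0, 1000.0))
    def test_quadratic_scaling(self, nu, t):
        assert rs.wigner_kappa(2 * nu, t) - 1.0 == pytest.approx(
            4.0 * (rs.wigner_kappa(nu, t) - 1.0), rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            rs.wigner_kappa(-10.0)
        with pytest.raises(InvalidInputError):
            rs.wigner_kappa(100.0, temperature=0.0)


class TestTSTRate:
    def test_prefactor_at_298(self):
        expected = KB * 298.15 / H
        assert rs.tst_rate(0.0, 298.15) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(6.212e12, rel=1e-3)

    def test_barrier_7p6_against_independent_arithmetic(self):
        expected = (KB * 298.15 / H) * math.exp(-7.6 / (R_KCAL * 298.15))
        assert rs.tst_rate(7.6) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1.68e7, rel=0.01)

    def test_linearity_in_sigma_and_kappa_floor(self):
        assert rs.tst_rate(7.6, sigma=2) == pytest.approx(2 * rs.tst_rate(7.6))
        with pytest.raises(InvalidInputError):
            rs.tst_rate(7.6, kappa=0.5)
        with pytest.raises(InvalidInputError):
            rs.tst_rate(7.6, sigma=0)

    @settings(derandomize=True, max_examples=40)
    @given(dg=st.floats(0.5, 30.0), ddg=st.floats(0.1, 10.0),
           t=st.floats(200.0, 600.0), dt=st.floats(1.0, 200.0))
    def test_strictly_monotone_in_barrier_and_temperature(self, dg, ddg, t, dt):
        assert rs.tst_rate(dg + ddg, t) < rs.tst_rate(dg, t)
        assert rs.tst_rate(dg, t + dt) > rs.tst_rate(dg, t)

    def test_eyring_form_ln_k_over_t_affine_in_inverse_t(self):
        # with dG(T) = dH - T*dS, ln(k/T) must be affine in 1/T
        dh, ds = 8.0, -0.005  # kcal/mol, kcal/mol/K
        temps = np.linspace(250.0, 400.0, 7)
        lnk_t = np.array([math.log(rs.tst_rate(dh - t * ds, t) / t) for t in temps])
        inv_t = 1.0 / temps
        slope, intercept = np.polyfit(inv_t, lnk_t, 1)
        residual = lnk_t - (slope * inv_t + intercept)
        assert np.abs(residual).max() < 1e-10
        # slope is -dH/R, intercept is ln(kB/h) + dS/R
        assert slope == pytest.approx(-dh / R_KCAL, rel=1e-9)
        assert intercept == pytest.approx(math.log(KB / H) + ds / R_KCAL, rel=1e-9)


class TestRateTable:
    def make_profiles(self):
        barriers = {"3'": 9.8, "4'": 7.6, "5": 8.1, "7": 8.3}
        energies = {"3'": -22.7, "4'": -31.1, "5": -24.0, "7": -21.2}
        targets = rs.PESTargets(rows=[
            rs.PESTargetRow(f"Pt-{s}-OH+OH", b, energies[s])
            for s, b in barriers.items()])
        species = rs.make_pes(targets)
        return [rs.build_pes(sl, reaction_id=rid) for rid, sl in species.items()]

    def test_lowest_barrier_reaction_ranks_first(self):
        results = rs.rate_table(self.make_profiles())
        assert results[0].reaction_id == "Pt-4'-OH+OH"
        assert results[0].is_fastest and results[0].is_lowest_barrier
        assert [r.reaction_id for r in results] == \
            ["Pt-4'-OH+OH", "Pt-5-OH+OH", "Pt-7-OH+OH", "Pt-3'-OH+OH"]
        assert results[0].delta_g_reaction == pytest.approx(-31.1)

    def test_sigma_and_kappa_always_reported(self):
        results = rs.rate_table(self.make_profiles(), kappa_policy="unit")
        assert all(r.sigma == 1 and r.kappa == 1.0 for r in results)

    def test_wigner_policy_uses_ts_wavenumber(self):
        targets = rs.PESTargets(rows=[
            rs.PESTargetRow("rx", 7.6, -31.1, imaginary_wavenumber=1500.0)])
        profiles = [rs.build_pes(sl, reaction_id=rid)
                    for rid, sl in rs.make_pes(targets).items()]
        (res,) = rs.rate_table(profiles, kappa_policy="wigner")
        assert res.kappa == pytest.approx(rs.wigner_kappa(1500.0), rel=1e-12)
        assert res.rate_constant == pytest.approx(
            res.kappa * rs.tst_rate(7.6), rel=1e-12)

    def test_singleton_is_trivially_top_ranked(self):
        (res,) = rs.rate_table(self.make_profiles()[:1])
        assert res.is_fastest and res.is_lowest_barrier


class TestFixtureConsistency:
    def test_printed_rate_ordering_matches_barrier_ordering(self):
        kin = rs.load_table2()
        assert len(kin) == 4
        assert check_rank_consistency(kin.delta_g_activation.tolist(),
                                      kin.k_ref.tolist())
        best = kin.loc[kin.k_ref.idxmax()]
        assert best["site"] == "4'-OH"
        assert best["delta_g_activation"] == 7.6
        assert best["delta_g"] == -31.1
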