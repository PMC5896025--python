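"""Equilibrium solver: oracles, conservation, monotonicity, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soxoct import binding, titration
from soxoct.binding import (
    BindingParameters,
    MixtureComposition,
    ReadoutMode,
    bound_fraction,
    infer_omega,
    simulate_titration,
    solve_equilibrium,
)
from soxoct.errors import ValidationError

from conftest import fixed_point_equilibrium, single_site_bound_fraction


class TestSolveEquilibrium:
    def test_no_protein_means_no_binding(self):
        st_ = solve_equilibrium(
            BindingParameters(25, 40, 2.0), MixtureComposition(5, 0, 0)
        )
        assert st_.free_dna == pytest.approx(5.0)
        assert st_.sox_dna == st_.oct_dna == st_.ternary == 0.0

    def test_single_site_matches_depletion_quadratic(self):
        # kd_sox=25, D=5, S=25: oracle gives bound fraction 0.4751
        st_ = solve_equilibrium(
            BindingParameters(25, 40, 1.0), MixtureComposition(5, 25, 0)
        )
        frac = (st_.sox_dna + st_.ternary) / 5
        assert frac == pytest.approx(0.4751, abs=5e-5)
        assert frac == pytest.approx(single_site_bound_fraction(25, 5, 25), abs=1e-10)

    def test_quadratic_oracle_over_random_draws(self, rng):
        # cofactor absent: full model must collapse to the one-site closed form
        for _ in range(100):
            kd = float(rng.uniform(1, 200))
            p = float(10 ** rng.uniform(-1, 3))
            st_ = solve_equilibrium(
                BindingParameters(kd, 42.5, float(rng.uniform(0, 10))),
                MixtureComposition(5, p, 0),
            )
            expect = single_site_bound_fraction(p, 5, kd)
            assert (st_.sox_dna + st_.ternary) / 5 == pytest.approx(expect, abs=1e-8)

    def test_independence_at_omega_one_vs_fixed_point_oracle(self):
        st_ = solve_equilibrium(
            BindingParameters(25, 25, 1.0), MixtureComposition(5, 500, 500)
        )
        s_free, o_free = fixed_point_equilibrium(25, 25, 1.0, 5, 500, 500)
        assert st_.free_sox == pytest.approx(s_free, rel=1e-6)
        assert st_.free_oct == pytest.approx(o_free, rel=1e-6)
        occ_s = (st_.sox_dna + st_.ternary) / 5
        occ_o = (st_.oct_dna + st_.ternary) / 5
        # independent sites: ternary occupancy factorizes
        assert st_.ternary / 5 == pytest.approx(occ_s * occ_o, rel=1e-6)

    @given(
        kd_sox=st.floats(1.0, 200.0),
        kd_oct=st.floats(1.0, 200.0),
        omega=st.floats(0.0, 100.0),
        s_tot=st.floats(0.0, 1000.0),
        o_tot=st.floats(0.0, 1000.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation_property(self, kd_sox, kd_oct, omega, s_tot, o_tot):
        st_ = solve_equilibrium(
            BindingParameters(kd_sox, kd_oct, omega),
            MixtureComposition(5.0, s_tot, o_tot),
        )
        dna = st_.free_dna + st_.sox_dna + st_.oct_dna + st_.ternary
        sox = st_.free_sox + st_.sox_dna + st_.ternary
        oct_ = st_.free_oct + st_.oct_dna + st_.ternary
        assert dna == pytest.approx(5.0, rel=1e-8)
        assert sox == pytest.approx(s_tot, rel=1e-8, abs=1e-12)
        assert oct_ == pytest.approx(o_tot, rel=1e-8, abs=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            MixtureComposition(-1, 0, 0)
        with pytest.raises(ValidationError):
            BindingParameters(-25, 40)


class TestBoundFraction:
    def test_all_free_state_is_zero_in_every_mode(self):
        st_ = solve_equilibrium(BindingParameters(25, 40), MixtureComposition(5, 0, 0))
        for mode in ReadoutMode:
            assert bound_fraction(st_, mode, "sox") == 0.0

    def test_saturated_ternary_is_one_in_every_mode(self):
        st_ = binding.EquilibriumState(
            free_dna=0, sox_dna=0, oct_dna=0, ternary=5, free_sox=1, free_oct=1,
            dna_total=5, sox_total=6, oct_total=6,
        )
        for mode in ReadoutMode:
            assert bound_fraction(st_, mode, "sox") == pytest.approx(1.0)

    def test_titrant_bound_equals_site_occupancy_at_omega_one(self):
        st_ = solve_equilibrium(
            BindingParameters(25, 25, 1.0), MixtureComposition(5, 500, 500)
        )
        s_free, _ = fixed_point_equilibrium(25, 25, 1.0, 5, 500, 500)
        occ = (s_free / 25) / (1 + s_free / 25)
        assert bound_fraction(st_, ReadoutMode.TITRANT_BOUND, "sox") == pytest.approx(
            occ, rel=1e-6
        )

    def test_zero_dna_is_undefined(self):
        st_ = solve_equilibrium(BindingParameters(25, 40), MixtureComposition(0, 10, 0))
        with pytest.raises(ValidationError):
            bound_fraction(st_)


class TestSimulateTitration:
    def test_zero_grid_single_point(self, sox_only_params):
        curve = simulate_titration(sox_only_params, titrant="sox", titrant_grid=[0.0])
        assert curve.n == 1
        assert curve.bound_fraction[0] == 0.0

    def test_empty_grid_rejected(self, sox_only_params):
        with pytest.raises(ValidationError):
            simulate_titration(sox_only_params, titrant="sox", titrant_grid=[])

    def test_curve_monotone_and_fit_recovers_kd(self, sox_only_params):
        curve = simulate_titration(sox_only_params, titrant="sox")
        assert np.all(np.diff(curve.bound_fraction) > 0)
        est = titration.fit_akd(curve, n_boot=0)
        assert est.akd == pytest.approx(70.2, rel=1e-6)

    def test_bound_fraction_monotone_in_omega(self):
        fracs = []
        for omega in (0.5, 1.0, 2.0, 5.0):
            st_ = solve_equilibrium(
                BindingParameters(60, 42.5, omega), MixtureComposition(5, 50, 40)
            )
            fracs.append(bound_fraction(st_, ReadoutMode.TITRANT_BOUND, "sox"))
        assert np.all(np.diff(fracs) > 0)

    def test_saturating_cofactor_divides_apparent_kd_by_omega(self):
        # cofactor at 100x its Kd: apparent Kd -> kd_sox / omega
        curve = simulate_titration(
            BindingParameters(60, 42.5, 3.0), titrant="sox", cofactor=("oct", 4250.0)
        )
        est = titration.fit_akd(curve, n_boot=0)
        assert est.akd == pytest.approx(60.0 / 3.0, rel=0.05)

    def test_omega_one_apparent_kd_independent_of_cofactor(self):
        akds = []
        for cof in (None, ("oct", 42.5), ("oct", 425.0), ("oct", 4250.0)):
            curve = simulate_titration(
                BindingParameters(60, 42.5, 1.0), titrant="sox", cofactor=cof
            )
            akds.append(titration.fit_akd(curve, n_boot=0).akd)
        assert (max(akds) - min(akds)) / np.mean(akds) <= 0.005


class TestInferOmega:
    def test_no_shift_means_no_cooperativity(self):
        w = infer_omega(60.0, 60.0, 42.5, 42.5)
        assert w == pytest.approx(1.0, abs=1e-3)

    def test_roundtrip_recovers_omega(self):
        curve = simulate_titration(
            BindingParameters(60, 42.5, 3.0), titrant="sox", cofactor=("oct", 100.0)
        )
        akd_with = titration.fit_akd(curve, n_boot=0).akd
        w = infer_omega(60.0, akd_with, 100.0, 42.5)
        assert w == pytest.approx(3.0, abs=1e-3)

    def test_measured_fgf4_shift_implies_positive_cooperativity(self):
        # Sox2 titration of the Fgf4 element: 70.2 alone vs 23.3 with 40 nM Oct4
        w = infer_omega(70.2, 23.3, 40.0, 42.5, 5.0)
        assert w > 1.0

    def test_unreachable_shift_raises(self):
        with pytest.raises(ValidationError):
            infer_omega(60.0, 1e-4, 42.5, 42.5)
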