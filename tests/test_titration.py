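"""aKd fitting, cooperativity factors, tabulation and CSV round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soxoct import binding, synth
from soxoct.datasets import AKD_TABLE
from soxoct.errors import (
    DegenerateDataError,
    ReportingError,
    ValidationError,
)
from soxoct.titration import (
    KdEstimate,
    TitrationCurve,
    TitrationResult,
    akd_from_half_saturation,
    cooperativity_factor,
    fit_akd,
    isotherm,
    read_titration_csv,
    round_half_up,
    summarize_table,
    write_titration_csv,
)


def make_curve(kd=25.0, dna=5.0, n=10, noise_sd=0.0, seed=0, fmax=1.0):
    grid = np.geomspace(1, 500, n)
    y = isotherm(grid, kd, dna, fmax)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(0, noise_sd, n), 0, 1.05)
    return TitrationCurve(grid, y, dna_total=dna)


class TestFitAkd:
    def test_exact_on_noiseless_data(self):
        est = fit_akd(make_curve(kd=25.0), n_boot=0)
        assert est.akd == pytest.approx(25.0, rel=1e-6)
        assert est.fitted_fmax == 1.0

    def test_recovers_generating_kd_over_random_draws(self, rng):
        for _ in range(50):
            kd = float(rng.uniform(5, 200))
            est = fit_akd(make_curve(kd=kd), n_boot=0)
            assert est.akd == pytest.approx(kd, rel=1e-3)

    def test_noisy_recovery_statistics(self):
        # sd 0.05 on 10 points puts the aKd standard error near 10%, so the
        # median |relative error| sits well inside 15% and the bulk of the
        # seeds land within that band
        errors = np.array(
            [
                abs(fit_akd(make_curve(noise_sd=0.05, seed=s), n_boot=0).akd - 25) / 25
                for s in range(200)
            ]
        )
        assert np.median(errors) < 0.15
        assert np.mean(errors < 0.15) >= 0.75

    def test_free_fmax_recovers_submaximal_plateau(self):
        est = fit_akd(make_curve(kd=25.0, fmax=0.8), fix_fmax=False, n_boot=0)
        assert est.akd == pytest.approx(25.0, rel=1e-4)
        assert est.fitted_fmax == pytest.approx(0.8, rel=1e-4)

    def test_saturating_cofactor_curve_from_binding_model(self):
        curve = binding.simulate_titration(
            binding.BindingParameters(60, 42.5, 3.0),
            titrant="sox",
            cofactor=("oct", 4250.0),
        )
        assert fit_akd(curve, n_boot=0).akd == pytest.approx(20.0, rel=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_akd(make_curve(n=3), n_boot=0)

    def test_flat_zero_data_rejected(self):
        curve = TitrationCurve(np.geomspace(1, 500, 8), np.zeros(8))
        with pytest.raises(DegenerateDataError):
            fit_akd(curve, n_boot=0)

    def test_bootstrap_se_reproducible_and_shrinks_with_n(self):
        rng = np.random.default_rng(7)
        grid_n = np.geomspace(1, 500, 12)
        grid_4n = np.sort(np.concatenate([grid_n * f for f in (1, 1.01, 1.02, 1.03)]))
        curves = {}
        for label, grid in (("n", grid_n), ("4n", grid_4n)):
            y = np.clip(isotherm(grid, 25, 5) + rng.normal(0, 0.05, grid.size), 0, 1.05)
            curves[label] = TitrationCurve(grid, y)
        se_n = fit_akd(curves["n"], n_boot=300, seed=11).se
        se_n_again = fit_akd(curves["n"], n_boot=300, seed=11).se
        se_4n = fit_akd(curves["4n"], n_boot=300, seed=11).se
        assert se_n == se_n_again
        # quadrupling the points should roughly halve the bootstrap se
        assert se_4n < se_n
        assert se_n / se_4n == pytest.approx(2.0, rel=0.5)

    def test_half_saturation_estimator_agrees_roughly(self):
        curve = make_curve(kd=25.0, n=30)
        assert akd_from_half_saturation(curve) == pytest.approx(25.0, rel=0.1)


class TestCooperativityFactor:
    # the nine measured aKd pairs and their printed parenthetical factors
    TABLE_CASES = [
        ("Nanog", "oct4", ("sox2", 37.0), 2.0, 0.6),
        ("Nanog", "oct4", ("sox2", 72.0), 2.4, 0.7),
        ("Nanog", "sox2", ("oct4", 40.0), 2.4, 1.2),
        ("Fgf4", "oct4", ("sox2", 37.0), 0.9, 0.1),
        ("Fgf4", "oct4", ("sox2", 72.0), 1.7, 0.4),
        ("Fgf4", "sox2", ("oct4", 40.0), 3.0, 0.8),
        ("Utf1", "oct4", ("sox2", 37.0), 1.6, 0.7),
        ("Utf1", "oct4", ("sox2", 72.0), 2.1, 0.9),
        ("Utf1", "sox2", ("oct4", 40.0), 1.0, 0.2),
    ]

    @pytest.mark.parametrize("element,titrant,cof,value,se", TABLE_CASES)
    def test_published_factors_reproduce(self, element, titrant, cof, value, se):
        alone = AKD_TABLE[(element, titrant, None)]
        with_cof = AKD_TABLE[(element, titrant, cof)]
        assert cooperativity_factor(alone, with_cof).rounded(1) == (value, se)

    def test_identity_ratio(self):
        a = KdEstimate(30.0, 0.0)
        cf = cooperativity_factor(a, a)
        assert (cf.value, cf.se) == (1.0, 0.0)

    @given(
        a=st.floats(1.0, 200.0), b=st.floats(1.0, 200.0),
        sa=st.floats(0.0, 20.0), sb=st.floats(0.0, 20.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_swap(self, a, b, sa, sb):
        x = KdEstimate(a, sa)
        y = KdEstimate(b, sb)
        assert cooperativity_factor(x, y).value == pytest.approx(
            1.0 / cooperativity_factor(y, x).value
        )

    def test_rounding_is_half_up(self):
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(2.35, 1) == 2.4


class TestSummarizeTable:
    def _results(self):
        out = []
        for (element, titrant, cof), est in AKD_TABLE.items():
            out.append(TitrationResult(element, titrant, cof, est))
        return out

    def test_reproduces_all_nine_parentheticals(self):
        table = summarize_table(self._results())
        cases = {
            (e, t, c[1]): (v, s) for e, t, c, v, s in TestCooperativityFactor.TABLE_CASES
        }
        with_cof = table[table.cofactor_name.notna()]
        assert len(with_cof) == 9
        for row in with_cof.itertuples():
            expect = cases[(row.element, row.titrant, row.cofactor_nM)]
            assert (row.coop_factor, row.coop_se) == expect
            assert f"({expect[0]} ± {expect[1]})*" in row.formatted

    def test_empty_input_empty_report(self):
        assert summarize_table([]).empty

    def test_missing_baseline_raises(self):
        res = [
            TitrationResult("X", "sox2", ("oct4", 40.0), KdEstimate(10.0, 1.0))
        ]
        with pytest.raises(ReportingError):
            summarize_table(res)

    def test_factor_ordering_follows_omega(self):
        # two synthetic elements with known cooperativity: the stronger omega
        # must yield the larger tabulated factor
        rows = []
        for name, omega in (("low", 2.0), ("high", 5.0)):
            params = binding.BindingParameters(60, 42.5, omega)
            alone = binding.simulate_titration(params, titrant="sox")
            with_c = binding.simulate_titration(
                params, titrant="sox", cofactor=("oct", 4250.0)
            )
            rows += [
                TitrationResult(name, "sox2", None, fit_akd(alone, n_boot=0)),
                TitrationResult(
                    name, "sox2", ("oct4", 4250.0), fit_akd(with_c, n_boot=0)
                ),
            ]
        table = summarize_table(rows)
        factors = table.dropna(subset=["cofactor_name"]).set_index("element").coop_factor
        assert factors["high"] > factors["low"]


class TestCsvRoundTrip:
    def test_write_read_preserves_curve(self, tmp_path):
        curve, _ = synth.generate_titration_dataset(
            binding.BindingParameters(25, 40, 1.0), seed=3
        )
        path = tmp_path / "curve.csv"
        write_titration_csv(curve, path)
        back = read_titration_csv(path)
        np.testing.assert_allclose(back.titrant_total, curve.titrant_total)
        np.testing.assert_allclose(back.bound_fraction, curve.bound_fraction)
        assert back.dna_total == curve.dna_total
        assert back.titrant_name == curve.titrant_name
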