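import warnings

import numpy as np
import pytest

from hairpinxb.constants import R_GAS
from hairpinxb.melting import (MeltFitError, ShiftMeltSeries, TwoStateMelt,
                               delta_g, fit_two_state, folded_fraction,
                               global_melt_fit, relative_folding,
                               temperature_coefficients, two_state_shift,
                               van_t_hoff_entropy)

T_GRID = np.arange(218.0, 349.0, 10.0)


def make_series(du=8.00, df=8.50, tm=274.0, dhm=23_900.0, noise=0.0,
                rng=None, label="h"):
    d = two_state_shift(T_GRID, du, df, tm, dhm)
    if noise:
        d = d + rng.normal(0.0, noise, size=d.shape)
    return ShiftMeltSeries(label, T_GRID, d)


class TestTwoStateFit:
    def test_exact_recovery(self):
        fit = fit_two_state(make_series())
        assert fit.delta_u_ == pytest.approx(8.00, rel=1e-6)
        assert fit.delta_f_ == pytest.approx(8.50, rel=1e-6)
        assert fit.tm_ == pytest.approx(274.0, rel=1e-6)
        assert fit.dhm_ == pytest.approx(23_900.0, rel=1e-6)

    def test_midpoint_is_mean_of_terminals(self):
        fit = fit_two_state(make_series())
        assert fit.predict(fit.tm_) == pytest.approx(
            (fit.delta_u_ + fit.delta_f_) / 2, abs=1e-9)

    def test_noisy_recovery_study(self):
        """Monte-Carlo: 50 replicates at 0.005 ppm noise recover T_m to 1 K."""
        rng = np.random.default_rng(0)
        errs = [abs(fit_two_state(make_series(noise=0.005, rng=rng)).tm_
                    - 274.0) for _ in range(50)]
        assert np.median(errs) <= 1.0

    def test_flat_series_rejected(self):
        flat = ShiftMeltSeries("h", T_GRID, np.full_like(T_GRID, 8.0))
        with pytest.raises(MeltFitError, match="no transition"):
            fit_two_state(flat)

    def test_too_few_points_rejected(self):
        with pytest.raises(MeltFitError, match=">= 5"):
            fit_two_state(ShiftMeltSeries("h", T_GRID[:4],
                                          np.linspace(8, 8.5, 4)))

    def test_sklearn_param_interface(self):
        est = TwoStateMelt(shift_floor=0.02)
        assert est.get_params()["shift_floor"] == 0.02
        est.set_params(shift_floor=0.05)
        assert est.shift_floor == 0.05


class TestFoldedFraction:
    def test_half_at_tm_and_low_T_limit(self):
        fit = fit_two_state(make_series())
        assert folded_fraction(fit, fit.tm_) == pytest.approx(0.5, abs=1e-12)
        assert folded_fraction(fit, 1e-3) == pytest.approx(1.0, abs=1e-12)

    def test_hand_checked_value(self):
        # closed form at T = 284 K for (274 K, 23.9 kJ/mol)
        assert folded_fraction((274.0, 23_900.0), 284.0) == pytest.approx(
            0.409, abs=1e-3)

    def test_negative_temperature_rejected(self):
        with pytest.raises(ValueError):
            folded_fraction((274.0, 23_900.0), -1.0)

    def test_kf_equals_odds_of_folding(self):
        fit = fit_two_state(make_series())
        for t in (240.0, 274.0, 300.0):
            f = folded_fraction(fit, t)
            _, kf = delta_g(fit, t)
            assert kf == pytest.approx(f / (1 - f), rel=1e-9)


class TestDeltaG:
    def test_table_arithmetic_route_b(self):
        # dG = dH_m - T dS_m at 298 K
        dg, _ = delta_g(dhm=23_900.0, dsm=73.1, T=298.0)
        assert dg / 1000 == pytest.approx(2.1, abs=0.05)

    def test_equimolar_is_zero(self):
        fit = fit_two_state(make_series())
        dg, kf = delta_g(fit, fit.tm_)
        assert kf == pytest.approx(1.0, rel=1e-9)
        assert dg == pytest.approx(0.0, abs=1e-6)

    def test_hand_checked_route_a(self):
        fit = fit_two_state(make_series())
        dg, kf = delta_g(fit, 284.0)
        assert kf == pytest.approx(0.692, abs=1e-3)
        assert dg / 1000 == pytest.approx(0.87, abs=0.01)

    def test_shift_outside_terminals_rejected(self):
        fit = fit_two_state(make_series())
        with pytest.raises(ValueError, match="outside"):
            delta_g(fit, 284.0, shift=9.2)


class TestVantHoff:
    def test_exact_data_gives_dhm_over_tm(self):
        fit = fit_two_state(make_series())
        res = van_t_hoff_entropy(fit)
        assert res["ds"] == pytest.approx(23_900.0 / 274.0, rel=1e-6)
        assert res["dh"] == pytest.approx(23_900.0, rel=1e-6)

    def test_noisy_recovery_within_15_percent(self):
        rng = np.random.default_rng(1)
        truth = 23_900.0 / 274.0
        errs = []
        for _ in range(50):
            fit = fit_two_state(make_series(noise=0.005, rng=rng))
            errs.append(abs(van_t_hoff_entropy(fit)["ds"] - truth) / truth)
        assert np.median(errs) <= 0.15

    def test_too_few_usable_points(self):
        fit = fit_two_state(make_series())
        with pytest.raises(MeltFitError, match=">= 4"):
            van_t_hoff_entropy(fit, f_bounds=(0.499, 0.501))


class TestGlobalFit:
    def make_set(self, rng=None, noise=0.0, n=10):
        out = []
        gen = np.random.default_rng(7)
        for i in range(n):
            du = gen.uniform(7.2, 8.6)
            df = du + gen.uniform(0.15, 0.5) * gen.choice([-1, 1])
            out.append(make_series(du, df, noise=noise, rng=rng,
                                   label=f"h{i}"))
        return out

    def test_consistent_generator_recovered(self):
        g = global_melt_fit(self.make_set())
        assert g.tm_ == pytest.approx(274.0, rel=1e-4)
        assert g.dhm_ == pytest.approx(23_900.0, rel=1e-4)

    def test_noisy_global_recovery(self):
        rng = np.random.default_rng(3)
        errs = [abs(global_melt_fit(self.make_set(rng=rng, noise=0.005)).tm_
                    - 274.0) for _ in range(20)]
        assert np.median(errs) <= 1.5

    def test_degenerate_proton_excluded_with_warning(self):
        series = self.make_set()
        flat = ShiftMeltSeries("flat", T_GRID, np.full_like(T_GRID, 8.0))
        with pytest.warns(UserWarning, match="flat"):
            g = global_melt_fit(series + [flat])
        assert "flat" in g.excluded_
        ref = global_melt_fit(series)
        assert g.tm_ == pytest.approx(ref.tm_, rel=1e-9)

    def test_fewer_than_two_series_rejected(self):
        with pytest.raises(MeltFitError, match="at least 2"):
            global_melt_fit([make_series()])


class TestRelativeFolding:
    @staticmethod
    def norm_series(tm, dhm, label):
        return ShiftMeltSeries(
            label, T_GRID, two_state_shift(T_GRID, 0.0, 1.0, tm, dhm))

    def test_self_comparison_is_unity(self):
        s = make_series()
        rel = relative_folding(s, s, (8.0, 8.5), (8.0, 8.5), tm2=274.0)
        assert rel.k_ratio == pytest.approx(1.0, rel=1e-9)
        assert rel.ddg == pytest.approx(0.0, abs=1e-6)

    def test_paper_worked_example(self):
        # K = 1.3 at T_m2 = 267.6 K -> ddG = -0.6 kJ/mol at 1 d.p.
        ddg = -R_GAS * 267.6 * np.log(1.3)
        assert ddg / 1000 == pytest.approx(-0.6, abs=0.05)

    def test_equal_enthalpy_closed_form(self):
        dh = 25_000.0
        s1 = self.norm_series(274.0, dh, "c1")
        s2 = self.norm_series(268.0, dh, "c2")
        rel = relative_folding(s1, s2, (0.0, 1.0), (0.0, 1.0), tm2=268.0)
        expected = np.exp(dh / R_GAS * (1 / 268.0 - 1 / 274.0))
        assert expected == pytest.approx(1.278, abs=1e-3)
        assert rel.k_ratio == pytest.approx(expected, abs=1e-3)
        # exact collinearity of the bilinear products
        resid = rel.points["y"] - rel.k_ratio * rel.points["x"]
        assert np.allclose(resid, 0.0, atol=1e-12)

    def test_antisymmetry_under_swap(self):
        s1 = self.norm_series(274.0, 25_000.0, "c1")
        s2 = self.norm_series(268.0, 25_000.0, "c2")
        fwd = relative_folding(s1, s2, (0.0, 1.0), (0.0, 1.0), tm2=268.0)
        rev = relative_folding(s2, s1, (0.0, 1.0), (0.0, 1.0), tm2=274.0)
        assert fwd.k_ratio * rev.k_ratio == pytest.approx(1.0, rel=1e-6)


class TestTemperatureCoefficients:
    def test_table_value_and_class(self):
        # 2.45 ppb/K slope -> intramolecular H-bond class
        d = 8.0 - 0.00245 * (T_GRID - 218.0)
        out = temperature_coefficients([ShiftMeltSeries("Lys7", T_GRID, d)])
        assert out.loc["Lys7", "coeff_ppb_per_K"] == pytest.approx(2.45,
                                                                   abs=1e-9)
        assert out.loc["Lys7", "class"] == "intramolecular H-bond"

    def test_constant_shift_and_boundaries(self):
        rows = {
            "flat": 0.0, "three": 3.0, "five": 5.0, "exposed": 5.5,
        }
        series = [
            ShiftMeltSeries(k, T_GRID, 8.0 - v / 1000.0 * (T_GRID - 218.0))
            for k, v in rows.items()
        ]
        out = temperature_coefficients(series)
        assert out.loc["flat", "coeff_ppb_per_K"] == pytest.approx(0.0)
        # exact 3 and 5 fall in the middle band
        assert out.loc["three", "class"] == "dynamic equilibrium"
        assert out.loc["five", "class"] == "dynamic equilibrium"
        assert out.loc["exposed", "class"] == "solvent exposed"

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 3"):
            temperature_coefficients(
                [ShiftMeltSeries("x", T_GRID[:2], np.array([8.0, 8.1]))])
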