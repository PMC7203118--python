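"""4PL fitting, ECx interpolation, bootstrap, potency and endpoint comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from phycotox.datasets import psii_ec50_pairs
from phycotox.doseresponse import (FourPLModel, bootstrap_ecx,
                                   ec50_ratio_summary, four_pl, one_way_anova,
                                   ols_endpoint_regression, relative_potency)


def _noiseless_data(bottom=0.0, top=100.0, ec50=10.0, hill=1.0,
                    conc=(0.3, 1, 3, 10, 30, 100, 300), reps=5):
    c = np.repeat(np.asarray(conc, float), reps)
    y = four_pl(c, bottom, top, np.log10(ec50), hill)
    return c, y


class TestFourPLFit:
    def test_noiseless_parameter_recovery(self):
        c, y = _noiseless_data(bottom=0.0, top=100.0, ec50=10.0, hill=1.0)
        res = FourPLModel(c, y).fit()
        assert res.converged
        assert res.params["top"] == pytest.approx(100.0, rel=1e-6, abs=1e-6)
        assert res.params["bottom"] == pytest.approx(0.0, abs=1e-5)
        assert res.params["hill"] == pytest.approx(1.0, rel=1e-6)
        assert res.ec50 == pytest.approx(10.0, rel=1e-6)

    def test_flat_response_censors_ecx(self):
        # consistent 5-7 % inhibition with no concentration dependence
        rng = np.random.default_rng(0)
        c = np.repeat([1.0, 10.0, 100.0, 1000.0, 3700.0], 5)
        y = rng.uniform(5.0, 7.0, c.size)
        res = FourPLModel(c, y).fit()
        est = res.ecx(50)
        assert est.censored
        assert est.point == pytest.approx(3700.0)
        assert est.render() == ">3,700"

    def test_grid_search_never_beats_fit(self):
        """Optimization oracle: a brute-force grid over (log10 EC50, hill)
        with bounded linear profiling of (bottom, top) cannot find a lower
        SSE than the returned fit."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            ec50 = 10 ** rng.uniform(-0.5, 2.0)
            hill = rng.uniform(0.5, 3.0)
            top = rng.uniform(80, 105)
            c = np.repeat(np.geomspace(0.1, 300, 6), 3)
            y = four_pl(c, 0.0, top, np.log10(ec50), hill)
            y = y + rng.normal(0, 4.0, c.size)
            model = FourPLModel(c, y)
            res = model.fit()
            best = np.inf
            logc = np.log10(c)
            for L in np.linspace(logc.min() - 1, logc.max() + 1, 40):
                for h in np.geomspace(0.2, 6.0, 30):
                    w = 1.0 / (1.0 + 10.0 ** ((L - logc) * h))
                    A = np.column_stack([1.0 - w, w])
                    sol = optimize.lsq_linear(A, y, bounds=([-20, 50], [20, 110]))
                    best = min(best, float(np.sum((A @ sol.x - y) ** 2)))
            assert res.sse <= best + 1e-6

    @given(hill=st.floats(0.3, 5.0), ec50=st.floats(0.5, 100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_fitted_curve_monotone_nondecreasing(self, hill, ec50):
        grid = np.geomspace(1e-3, 1e4, 200)
        y = four_pl(grid, 0.0, 100.0, np.log10(ec50), hill)
        assert np.all(np.diff(y) >= -1e-12)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            FourPLModel([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestECxInterpolation:
    def test_ec10_is_ec50_over_nine_for_unit_hill(self):
        c, y = _noiseless_data(ec50=10.0, hill=1.0)
        res = FourPLModel(c, y).fit()
        assert res.ecx(10).point == pytest.approx(10.0 / 9.0, rel=1e-6)

    @pytest.mark.parametrize("hill", [0.5, 1.0, 2.7])
    def test_ec50_equals_fitted_parameter(self, hill):
        c, y = _noiseless_data(ec50=5.0, hill=hill)
        res = FourPLModel(c, y).fit()
        assert res.ecx(50).point == pytest.approx(res.ec50, rel=1e-9)

    def test_root_agrees_with_bisection_oracle(self):
        rng = np.random.default_rng(11)
        c = np.repeat(np.geomspace(0.3, 300, 7), 5)
        y = four_pl(c, 0, 95, np.log10(8.0), 1.4) + rng.normal(0, 3, c.size)
        res = FourPLModel(c, y).fit()
        for x in (10, 20, 50):
            target = res.ecx(x).point
            f = lambda conc: res.predict(conc) - x
            oracle = optimize.bisect(f, 1e-8, res.model.max_tested,
                                     xtol=1e-14, rtol=1e-13)
            assert target == pytest.approx(oracle, rel=1e-8)

    def test_identity_on_generated_family(self):
        """interpolate(fit(data from 4PL)) returns the generating ECx."""
        c, y = _noiseless_data(bottom=0.0, top=100.0, ec50=20.0, hill=2.0)
        res = FourPLModel(c, y).fit()
        for x in (10, 50):
            truth = 20.0 * ((100.0 - x) / x) ** (-1.0 / 2.0)
            assert res.ecx(x).point == pytest.approx(truth, rel=1e-6)


class TestBootstrap:
    def test_noiseless_ci_width_shrinks_to_zero(self, noiseless_assay):
        endpoints, exposure = noiseless_assay
        est = bootstrap_ecx(endpoints, exposure, 50, n_boot=50, seed=0)
        assert est.ci_high - est.ci_low < 1e-6 * est.point
        assert est.ci_low <= est.point <= est.ci_high

    def test_point_inside_ci_and_deterministic(self, noisy_assay):
        endpoints, exposure = noisy_assay
        a = bootstrap_ecx(endpoints, exposure, 50, n_boot=100, seed=5)
        b = bootstrap_ecx(endpoints, exposure, 50, n_boot=100, seed=5)
        assert (a.point, a.ci_low, a.ci_high) == (b.point, b.ci_low, b.ci_high)
        assert a.ci_low <= a.point <= a.ci_high


class TestPotencyAndComparison:
    def test_rep_of_reference_is_one(self):
        assert relative_potency(6.27, 6.27) == 1.0

    @pytest.mark.parametrize("ec50,printed", [(13.4, 0.47), (112.0, 0.056)])
    def test_rep_matches_printed_precision(self, ec50, printed):
        rep = relative_potency(6.27, ec50)
        assert round(rep, len(str(printed).split(".")[1])) == printed

    @given(a=st.floats(0.1, 1e3), b=st.floats(0.1, 1e3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rep_antisymmetry(self, a, b):
        assert relative_potency(a, b) * relative_potency(b, a) == pytest.approx(1.0)

    def test_equal_ec50s_give_unit_ratio(self):
        tab = pd.DataFrame({"herbicide": ["a"], "ec50_sgr": [5.0],
                            "ec50_yield": [5.0]})
        out, mean = ec50_ratio_summary(tab)
        assert out["ec50_ratio"].iloc[0] == 1.0 and mean == 1.0

    def test_reference_ratio_printed_value(self):
        tab = pd.DataFrame({"herbicide": ["diuron"], "ec50_sgr": [6.27],
                            "ec50_yield": [1.71]})
        out, _ = ec50_ratio_summary(tab)
        assert round(out["ec50_ratio"].iloc[0], 1) == 3.7


class TestOLSRegression:
    def test_two_points_perfect_fit(self):
        reg = ols_endpoint_regression([1.0, 2.0], [10.0, 20.0])
        assert reg.r_squared == pytest.approx(1.0)

    def test_agrees_with_normal_equations(self):
        pairs = psii_ec50_pairs()
        y = pairs["ec50_sgr"].to_numpy()
        x = pairs["ec50_yield"].to_numpy()
        reg = ols_endpoint_regression(y, x)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        intercept = y.mean() - slope * x.mean()
        r2 = 1 - np.sum((y - intercept - slope * x) ** 2) / np.sum((y - y.mean()) ** 2)
        assert reg.slope == pytest.approx(slope, abs=1e-10)
        assert reg.intercept == pytest.approx(intercept, abs=1e-10)
        assert reg.r_squared == pytest.approx(r2, abs=1e-10)

    def test_invariant_to_pair_order(self):
        pairs = psii_ec50_pairs().sample(frac=1.0, random_state=4)
        ref = ols_endpoint_regression(psii_ec50_pairs()["ec50_sgr"],
                                      psii_ec50_pairs()["ec50_yield"])
        shuffled = ols_endpoint_regression(pairs["ec50_sgr"], pairs["ec50_yield"])
        assert shuffled.slope == pytest.approx(ref.slope, abs=1e-12)
        assert shuffled.r_squared == pytest.approx(ref.r_squared, abs=1e-12)


class TestOneWayAnova:
    def test_hand_computed_sums_of_squares(self):
        groups = [[6.0, 8.0, 4.0, 5.0, 3.0, 4.0],
                  [8.0, 12.0, 9.0, 11.0, 6.0, 8.0],
                  [13.0, 9.0, 11.0, 8.0, 7.0, 12.0]]
        flat = np.concatenate(groups)
        grand = flat.mean()
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
        f_hand = (ssb / 2) / (ssw / 15)
        res = one_way_anova(groups)
        assert res.statistic == pytest.approx(f_hand, rel=1e-10)
        assert (res.df_between, res.df_within) == (2, 15)

    def test_null_data_f_near_one(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(1.2, 0.05, 5) for _ in range(7)]
        res = one_way_anova(groups)
        assert res.pvalue > 0.05
        assert str(res).startswith("F(6,28)")

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0]])
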