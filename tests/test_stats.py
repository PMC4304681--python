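import copy

import numpy as np
import pandas as pd
import pytest

from gmma.design import simulate_dataset
from gmma.equilibria import Component, InteractionModel, Species
from gmma.fitting import Parameter, ParameterSpace, fit_global
from gmma.stats import (
    consistency_test,
    covariance_and_correlation,
    information_report,
    monte_carlo_intervals,
    profile_projection,
    weight_scan,
)


def linear_model():
    """Non-associating probe with a linear fluorescence response: the fit of
    (slope, baseline) is an ordinary linear least-squares problem with a
    closed-form covariance."""
    return InteractionModel(
        components=[Component("P", signals={"fl": 1.0e6})],
        species=[Species("PP", {"P": 2}, log10beta=-30.0)],
    )


@pytest.fixture
def linear_fit():
    model = linear_model()
    x = np.linspace(1e-7, 2e-6, 12)
    exp = simulate_dataset(
        model, "signal", pd.DataFrame({"P": x}), {"baseline": 0.1},
        0.05, seed=3, meta={"signal": "fl"}, name="lin",
    )
    params = ParameterSpace(
        [
            Parameter("component.P.signal.fl", 0.8e6, fixed=False),
            Parameter("exp[0].baseline", 0.0, fixed=False),
        ]
    )
    fit = fit_global([exp], model, params, method="ml")
    return fit, x


def closed_form_cov(x, sigma):
    X = np.column_stack([x, np.ones_like(x)])
    return np.linalg.inv(X.T @ X / sigma**2)


class TestCovariance:
    def test_linear_model_matches_closed_form(self, linear_fit):
        fit, x = linear_fit
        cov, corr, names = covariance_and_correlation(fit)
        expect = closed_form_cov(x, 0.05) * fit.chisq_reduced
        order = [names.index("component.P.signal.fl"), names.index("exp[0].baseline")]
        got = cov[np.ix_(order, order)]
        assert np.allclose(got, expect, rtol=1e-8)

    def test_correlation_diagonal_and_range(self, linear_fit):
        fit, _ = linear_fit
        _, corr, _ = covariance_and_correlation(fit)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.all(np.abs(corr) <= 1.0 + 1e-12)

    def test_orthogonal_design_uncorrelated(self):
        """Two experiments, each sensitive to exactly one parameter, give a
        block-diagonal curvature and near-zero cross-correlation."""
        model = InteractionModel(
            components=[Component("P", signals={"s1": 1.0e6, "s2": 0.0}),
                        Component("Q", signals={"s1": 0.0, "s2": 1.0e6})],
            species=[Species("PQ", {"P": 1, "Q": 1}, log10beta=-30.0)],
        )
        x = np.linspace(1e-7, 2e-6, 10)
        e1 = simulate_dataset(model, "signal",
                              pd.DataFrame({"P": x, "Q": x * 0}), {},
                              0.02, seed=1, meta={"signal": "s1"}, name="e1")
        e2 = simulate_dataset(model, "signal",
                              pd.DataFrame({"P": x * 0, "Q": x}), {},
                              0.02, seed=2, meta={"signal": "s2"}, name="e2")
        params = ParameterSpace([
            Parameter("component.P.signal.s1", 0.9e6, fixed=False),
            Parameter("component.Q.signal.s2", 0.9e6, fixed=False),
        ])
        fit = fit_global([e1, e2], model, params, method="ml")
        _, corr, names = covariance_and_correlation(fit)
        i = names.index("component.P.signal.s1")
        j = names.index("component.Q.signal.s2")
        assert abs(corr[i, j]) < 0.05


class TestProfileProjection:
    def test_best_fit_node_inside_every_contour(self, linear_fit):
        fit, _ = linear_fit
        center = fit.free_dict()["component.P.signal.fl"]
        grid = np.linspace(center - 1e5, center + 1e5, 11)
        proj = profile_projection(fit, "component.P.signal.fl", [grid],
                                  (0.68, 0.95))
        k = np.argmin(np.abs(grid - center))
        assert proj.chisq[k] / proj.chisq_min == pytest.approx(1.0, abs=0.02)
        assert proj.inside(0.68)[k] and proj.inside(0.95)[k]
        # profile never dips below the global minimum
        assert np.all(proj.chisq[proj.valid] >= proj.chisq_min - 1e-9)

    def test_quadratic_surface_matches_analytic_ellipse(self, linear_fit):
        """For a linear model the 68% profile contour crossing equals the
        analytic ellipse half-axis within 2%."""
        from scipy import stats as sps

        fit, x = linear_fit
        cov, _, names = covariance_and_correlation(fit)
        k = names.index("component.P.signal.fl")
        sig = np.sqrt(cov[k, k])
        center = fit.params.free_values()[k]
        grid = np.linspace(center - 4 * sig, center + 4 * sig, 81)
        proj = profile_projection(fit, "component.P.signal.fl", [grid], (0.68,))
        crit = proj.critical[0.68]
        k0 = int(np.argmin(proj.chisq))
        # interpolate the contour crossings on both flanks
        left = np.interp(crit, proj.chisq[: k0 + 1][::-1], grid[: k0 + 1][::-1])
        right = np.interp(crit, proj.chisq[k0:], grid[k0:])
        half_width = (right - left) / 2.0
        dof = fit.n_eff - fit.n_free
        # analytic crossing: delta-chi2 = chi2_min * (1/dof) * F(1, dof)
        dchi = fit.chisq * sps.f.ppf(0.68, 1, dof) / dof
        sig_unscaled = sig / np.sqrt(fit.chisq_reduced)
        expect = sig_unscaled * np.sqrt(dchi)
        assert half_width == pytest.approx(expect, rel=0.02)


class TestMonteCarlo:
    def test_linear_intervals_match_analytic(self, linear_fit):
        fit, x = linear_fit
        mc = monte_carlo_intervals(fit, n_replicates=300, seed=9)
        lo, hi = mc["intervals"][0.68]["component.P.signal.fl"]
        analytic = np.sqrt(closed_form_cov(x, 0.05)[0, 0])
        assert (hi - lo) / 2.0 == pytest.approx(analytic, rel=0.15)

    def test_determinism_under_seed(self, linear_fit):
        fit, _ = linear_fit
        a = monte_carlo_intervals(fit, n_replicates=100, seed=4)
        b = monte_carlo_intervals(fit, n_replicates=100, seed=4)
        assert a["intervals"] == b["intervals"]

    def test_tiny_noise_gives_tiny_intervals(self, linear_fit):
        fit, x = linear_fit
        small = copy.deepcopy(fit)
        for e in small.experiments:
            e.sigma = e.sigma * 1e-4
        mc = monte_carlo_intervals(small, n_replicates=100, seed=5)
        lo, hi = mc["intervals"][0.68]["component.P.signal.fl"]
        assert hi - lo < 50.0  # vs ~5e4 at the real noise level

    def test_replicate_floor(self, linear_fit):
        fit, _ = linear_fit
        with pytest.raises(ValueError):
            monte_carlo_intervals(fit, n_replicates=10, seed=1)


def _aniso_model(log10beta=6.0):
    return InteractionModel(
        components=[Component("A"), Component("B", anisotropy=0.05)],
        species=[Species("AB", {"A": 1, "B": 1}, log10beta=log10beta,
                         anisotropy=0.2)],
    )


def _aniso_exp(model, seed, subgroup, b_tot=1e-6, n=8):
    x = np.logspace(-7.5, -4.5, n)
    return simulate_dataset(
        model, "anisotropy", pd.DataFrame({"A": x, "B": np.full(n, b_tot)}),
        {"r_free": 0.05}, 0.002, seed=seed, meta={"probe": "B"},
        subgroup=subgroup, name=f"{subgroup}_{seed}",
    )


def _aniso_params(start=5.8):
    return ParameterSpace(
        [Parameter("species.AB.log10beta", start, fixed=False, lower=3, upper=9)]
    )


class TestWeightScan:
    def test_identical_weight_sets_give_single_interval(self):
        model = _aniso_model()
        exps = [_aniso_exp(model, s, f"g{s}") for s in (1, 2)]
        fit = fit_global(exps, model, _aniso_params(), method="ml")
        from scipy import stats as sps

        scan = weight_scan(fit, [[1.0, 1.0], [1.0, 1.0]], confidence_level=0.68)
        lo, hi = scan["envelope"]["species.AB.log10beta"]
        theta = float(scan["per_set"][0]["values"][0])
        z = sps.norm.ppf(0.84)
        sig = float(scan["per_set"][0]["sigma"][0])
        assert lo == pytest.approx(theta - z * sig, rel=1e-12)
        assert hi == pytest.approx(theta + z * sig, rel=1e-12)
        assert scan["flagged"] == []

    def test_consistent_data_not_flagged(self):
        model = _aniso_model()
        exps = [_aniso_exp(model, s, f"g{s}") for s in (3, 4, 5)]
        fit = fit_global(exps, model, _aniso_params(), method="ml")
        scan = weight_scan(
            fit, [[1, 1, 1], [3, 1, 1], [1, 3, 1], [1, 1, 3]]
        )
        assert scan["flagged"] == []

    def test_constructed_inconsistency_flagged(self):
        model = _aniso_model()
        exps = [_aniso_exp(model, s, f"g{s}") for s in (3, 4)]
        exps.append(_aniso_exp(_aniso_model(7.0), 6, "shifted"))
        fit = fit_global(exps, model, _aniso_params(), method="ml")
        scan = weight_scan(fit, [[1, 1, 1], [1, 1, 10], [10, 10, 1]])
        assert "species.AB.log10beta" in scan["flagged"]

    def test_all_zero_weight_set_rejected(self):
        model = _aniso_model()
        exps = [_aniso_exp(model, s, f"g{s}") for s in (1, 2)]
        fit = fit_global(exps, model, _aniso_params(), method="ml")
        with pytest.raises(ValueError, match="zero"):
            weight_scan(fit, [[1, 1], [0, 0]])


class TestConsistencyTest:
    def test_single_subgroup_is_error(self):
        model = _aniso_model()
        exps = [_aniso_exp(model, 1, "only")]
        with pytest.raises(ValueError, match="subgroups"):
            consistency_test(exps, model, _aniso_params())

    def test_consistent_subgroups_not_flagged(self):
        model = _aniso_model()
        exps = [_aniso_exp(model, s, f"g{s}") for s in (11, 12, 13)]
        res = consistency_test(exps, model, _aniso_params(), confidence=0.99)
        assert not any(v.get("flagged") for v in res.values())

    def test_shifted_subgroup_flagged(self):
        model = _aniso_model()
        exps = [_aniso_exp(model, s, f"g{s}") for s in (1, 2)]
        exps.append(_aniso_exp(_aniso_model(7.0), 3, "bad"))
        res = consistency_test(exps, model, _aniso_params(), confidence=0.95)
        assert res["bad"]["flagged"]
        assert res["bad"]["f_ratio"] > res["g1"]["f_ratio"]
        assert res["bad"]["f_ratio"] > res["g2"]["f_ratio"]


class TestInformationReport:
    def test_enthalpy_probed_only_calorimetrically(self, suite, suite_fit):
        """Perturbing dH moves only the ITC experiments' chi-square; the
        s_w, SPR and anisotropy data carry no enthalpy information."""
        report = information_report(suite_fit, "species.AB.dH")
        by_name = {r["name"]: r for r in report}
        itc_delta = sum(
            r["delta_chisq"] for r in report if r["technique"] == "itc"
        )
        other = [r for r in report if r["technique"] != "itc"]
        assert itc_delta > 0
        top = report[0]
        assert top["technique"] == "itc"
        for r in other:
            assert abs(r["delta_chisq"]) < 0.05 * itc_delta
        assert sum(r["delta_chisq"] for r in report) > 0

    def test_unknown_parameter(self, suite_fit):
        with pytest.raises(ValueError):
            information_report(suite_fit, "species.AB.nope")
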