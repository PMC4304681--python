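"""Self-validation studies.

End-to-end numerical experiments that the test-suite and the results
reproduction script both run: equilibrium-solver oracle checks, parameter
recovery on the bundled two-site suite, the correlation-breaking contour
comparison between the global fit and single-technique fits, type-I error
calibration of the consistency test, and Monte-Carlo vs closed-form
interval agreement on a linear-response isotherm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import simulate_dataset
from .equilibria import Component, InteractionModel, Species, solve_free_concentrations
from .fitting import Parameter, ParameterSpace, fit_global
from .fixtures import make_fixture_suite
from .stats import (
    consistency_test,
    contour_area,
    covariance_and_correlation,
    monte_carlo_intervals,
    profile_projection,
)

__all__ = [
    "solver_oracle_errors",
    "two_site_recovery",
    "correlation_breaking_areas",
    "consistency_type1_rate",
    "linear_mc_vs_analytic",
]


# -- solver oracle equivalence -------------------------------------------------


def _closed_form_ab(a_tot, b_tot, kd):
    # stable form of (s - sqrt(s^2 - 4ab))/2, avoiding cancellation for
    # weak binding where the complex is a tiny fraction of the totals
    s = a_tot + b_tot + kd
    return 2.0 * a_tot * b_tot / (s + np.sqrt(s * s - 4.0 * a_tot * b_tot))


def solver_oracle_errors(n_models: int = 100, seed: int = 42) -> dict:
    """Random 1:1 and 2:1 models solved and compared against independent
    oracles: the closed-form quadratic (1:1) and dense grid searches
    minimizing the mass-balance error (both).

    Returns the worst relative error of [AB] vs the closed form, and the
    worst log-distance of the solved free concentrations from the grid
    optimum (to be compared with the grid resolution).
    """
    rng = np.random.default_rng(seed)
    n_11 = n_models // 2
    worst_closed = 0.0
    worst_grid_units = 0.0  # |log(free_solver/free_grid)| / grid spacing
    for i in range(n_models):
        la = rng.uniform(-9, -4)
        lb = rng.uniform(-9, -4)
        a, b = 10.0**la, 10.0**lb
        if i < n_11:
            logk = rng.uniform(3, 12)
            m = InteractionModel(
                components=[Component("A"), Component("B")],
                species=[Species("AB", {"A": 1, "B": 1}, log10beta=logk)],
            )
            st = solve_free_concentrations(m, {"A": a, "B": b})
            ab = _closed_form_ab(a, b, 10.0**-logk)
            worst_closed = max(worst_closed, abs(st.species_conc["AB"] - ab) / ab)
            # 1-D grid oracle on free A
            fa_grid = np.logspace(la - 9, la, 4001)
            fb_grid = b / (1.0 + 10.0**logk * fa_grid)
            resid = np.abs(fa_grid + 10.0**logk * fa_grid * fb_grid - a)
            fa_best = fa_grid[np.argmin(resid)]
            spacing = np.log(fa_grid[1] / fa_grid[0])
            worst_grid_units = max(
                worst_grid_units, abs(np.log(st.free["A"] / fa_best)) / spacing
            )
        else:
            lb1 = rng.uniform(5, 8)
            lb2 = lb1 + rng.uniform(4, 7)
            m = InteractionModel(
                components=[Component("A"), Component("B")],
                species=[
                    Species("AB", {"A": 1, "B": 1}, log10beta=lb1),
                    Species("ABB", {"A": 1, "B": 2}, log10beta=lb2),
                ],
            )
            st = solve_free_concentrations(m, {"A": a, "B": b})
            # reduce to one dimension: for each trial free A the B balance
            # b = fB (1 + beta1 fA) + 2 beta2 fA fB^2 has the stable
            # closed-form root below; the remaining A-balance residual is
            # strictly monotone in free A, so the dense-grid argmin brackets
            # the root within one spacing
            b1, b2 = 10.0**lb1, 10.0**lb2
            fa = np.logspace(la - 8, la, 4001)
            lin = 1.0 + b1 * fa
            fb = 2.0 * b / (lin + np.sqrt(lin * lin + 8.0 * b2 * fa * b))
            resid = np.abs(fa + b1 * fa * fb + b2 * fa * fb**2 - a)
            fa_best = fa[np.argmin(resid)]
            spacing = np.log(fa[1] / fa[0])
            worst_grid_units = max(
                worst_grid_units, abs(np.log(st.free["A"] / fa_best)) / spacing
            )
    return {
        "n_models": n_models,
        "max_rel_error_closed_form": worst_closed,
        "max_grid_distance_in_spacings": worst_grid_units,
    }


# -- two-site suite recovery ---------------------------------------------------


def two_site_recovery(seed: int = 1) -> dict:
    """Fit the bundled 11-dataset suite and report stepwise-parameter
    recovery as z-scores |fit - truth| / sigma (sigma from the covariance,
    propagated to stepwise quantities)."""
    suite = make_fixture_suite(seed=seed)
    fit = fit_global(
        suite.experiments, suite.model, suite.start_parameters,
        method="marquardt-levenberg",
    )
    cov, _, names = covariance_and_correlation(fit)
    theta = dict(zip(names, fit.params.free_values()))
    idx = {n: names.index(n) for n in names}

    def stepwise(name1, name2=None):
        """value and sigma of theta1 (name2 None) or theta2 - theta1."""
        i = idx[name1]
        if name2 is None:
            return theta[name1], np.sqrt(cov[i, i])
        j = idx[name2]
        return (
            theta[name2] - theta[name1],
            np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j]),
        )

    t = suite.truth
    out = {"chisq_reduced": float(fit.chisq_reduced), "fit": fit, "suite": suite}
    for label, (val_sig, truth) in {
        "log10K1": (stepwise("species.AB.log10beta"),
                    t["species.AB.log10beta"]),
        "log10K2": (stepwise("species.AB.log10beta", "species.ABB.log10beta"),
                    t["species.ABB.log10beta"] - t["species.AB.log10beta"]),
        "dH1": (stepwise("species.AB.dH"), t["species.AB.dH"]),
        "dH2": (stepwise("species.AB.dH", "species.ABB.dH"),
                t["species.ABB.dH"] - t["species.AB.dH"]),
    }.items():
        (val, sig) = val_sig
        out[label] = {
            "value": float(val),
            "truth": float(truth),
            "sigma": float(sig),
            "z": float(abs(val - truth) / sig),
        }
    return out


# -- correlation breaking (global vs single technique) -------------------------


def correlation_breaking_areas(
    seed: int = 1,
    n_grid: int = 31,
    span_sigma: float = 8.0,
    confidence: float = 0.95,
) -> dict:
    """95% joint (log10K1, log10beta2) F-contour areas of the global fit and
    of the SPR-only, single-ITC and SV-only fits of the same suite.

    Association constants are the only free parameters (enthalpies fixed at
    their global best-fit values), so each grid node is a direct chi-square
    evaluation; each fit gets its own grid scaled to its covariance, and
    areas are in (log10 K)^2 units, comparable across fits.
    """
    suite = make_fixture_suite(seed=seed)
    pnames = ["species.AB.log10beta", "species.ABB.log10beta"]

    def area_of(experiments):
        params = ParameterSpace(
            [
                Parameter(pnames[0], 6.5, fixed=False, lower=3.0, upper=11.0),
                Parameter(pnames[1], 12.0, fixed=False, lower=7.0, upper=18.0),
                Parameter("species.AB.dH", suite.truth["species.AB.dH"], fixed=True),
                Parameter("species.ABB.dH", suite.truth["species.ABB.dH"], fixed=True),
            ]
        )
        fit = fit_global(experiments, suite.model, params,
                         method="marquardt-levenberg")
        cov, _, names = covariance_and_correlation(fit)
        kk = [names.index(p) for p in pnames]
        sig = np.sqrt(np.diag(cov))[kk]
        center = fit.params.free_values()[kk]
        spans = np.minimum(span_sigma * sig, 3.0)
        grids = [np.linspace(c - s, c + s, n_grid) for c, s in zip(center, spans)]
        proj = profile_projection(fit, pnames, grids, (confidence,),
                                  reoptimize=False)
        return contour_area(proj, confidence)

    by_tech = {}
    for tech in ("spr_competition", "itc", "sv_sw"):
        members = [e for e in suite.experiments if e.technique == tech]
        if tech == "itc":
            members = members[1:2]  # a single titration, as in a one-shot ITC study
        by_tech[tech] = members
    return {
        "gmma": area_of(suite.experiments),
        "spr": area_of(by_tech["spr_competition"]),
        "itc_single": area_of(by_tech["itc"]),
        "sv": area_of(by_tech["sv_sw"]),
    }


# -- consistency-test calibration ----------------------------------------------


def _consistency_model(log10beta=6.0):
    return InteractionModel(
        components=[Component("A"), Component("B", anisotropy=0.05)],
        species=[Species("AB", {"A": 1, "B": 1}, log10beta=log10beta,
                         anisotropy=0.2)],
    )


def consistency_type1_rate(
    n_sims: int = 200, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Flag rate of the cross-validation consistency test on suites where
    all subgroups share one truth (should not exceed alpha by more than
    binomial noise)."""
    model = _consistency_model()
    x = np.logspace(-7.5, -4.5, 8)
    params = ParameterSpace(
        [Parameter("species.AB.log10beta", 5.8, fixed=False, lower=3, upper=9)]
    )
    rng = np.random.default_rng(seed)
    flags = total = 0
    for _ in range(n_sims):
        exps = []
        for g in range(3):
            plan = pd.DataFrame({"A": x, "B": np.full(8, (g + 1) * 1e-6)})
            exps.append(
                simulate_dataset(
                    model, "anisotropy", plan, {"r_free": 0.05}, 0.002,
                    seed=int(rng.integers(2**31)), meta={"probe": "B"},
                    subgroup=f"g{g}", name=f"g{g}",
                )
            )
        res = consistency_test(exps, model, params, confidence=1 - alpha)
        for v in res.values():
            total += 1
            flags += bool(v.get("flagged"))
    # flags within one suite are positively correlated (they share the data
    # and the joint fit), so the independent sampling unit is the suite
    return {
        "rate": flags / total,
        "n_tests": total,
        "n_suites": n_sims,
        "alpha": alpha,
    }


# -- Monte-Carlo vs analytic ---------------------------------------------------


def linear_mc_vs_analytic(seed: int = 3, n_replicates: int = 500) -> dict:
    """On a linear-response isotherm (non-associating probe, signal linear
    in its concentration) the Monte-Carlo 68% interval half-widths must
    match the closed-form least-squares standard errors."""
    model = InteractionModel(
        components=[Component("P", signals={"fl": 1.0e6})],
        species=[Species("PP", {"P": 2}, log10beta=-30.0)],
    )
    x = np.linspace(1e-7, 2e-6, 12)
    sigma = 0.05
    exp = simulate_dataset(
        model, "signal", pd.DataFrame({"P": x}), {"baseline": 0.1},
        sigma, seed=seed, meta={"signal": "fl"}, name="lin",
    )
    params = ParameterSpace(
        [
            Parameter("component.P.signal.fl", 0.8e6, fixed=False),
            Parameter("exp[0].baseline", 0.0, fixed=False),
        ]
    )
    fit = fit_global([exp], model, params, method="marquardt-levenberg")
    mc = monte_carlo_intervals(fit, n_replicates=n_replicates, seed=seed + 1)
    X = np.column_stack([x, np.ones_like(x)])
    analytic = np.sqrt(np.diag(np.linalg.inv(X.T @ X / sigma**2)))
    names = ["component.P.signal.fl", "exp[0].baseline"]
    out = {}
    for name, se in zip(names, analytic):
        lo, hi = mc["intervals"][0.68][name]
        out[name] = {
            "mc_halfwidth": (hi - lo) / 2.0,
            "analytic_se": float(se),
            "ratio": (hi - lo) / 2.0 / se,
        }
    return out
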