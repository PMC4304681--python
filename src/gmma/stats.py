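"""Post-fit statistical analysis.

Covariance/cross-correlation, profile (error-surface) projections with
F-statistics confidence contours, Monte-Carlo confidence intervals, scans of
the per-experiment statistical weights, a leave-one-subgroup-out
cross-validation consistency test, and per-experiment information reports.

Conventions: the effective number of data points N_eff = sum_e w_e N_e and
the free-parameter count P (after link resolution) match the reduced
chi-square convention of the fitting module, so F-statistics thresholds

    chi2_crit = chi2_min * (1 + p/(N_eff - P) * F(p, N_eff - P; CL))

are consistent with chi2_r ~ 1 under correct sigmas.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .equilibria import InteractionModel
from .fitting import (
    Experiment,
    FitResult,
    ParameterSpace,
    apply_parameters,
    fit_global,
    global_chisq,
    predict,
    weighted_residuals,
)

__all__ = [
    "ErrorSurfaceProjection",
    "covariance_and_correlation",
    "profile_projection",
    "contour_area",
    "monte_carlo_intervals",
    "weight_scan",
    "consistency_test",
    "information_report",
]


def _free_jacobian(fit: FitResult, rel_step: float = 1e-6) -> np.ndarray:
    """Jacobian of the stacked weighted residuals w.r.t. free parameter
    *values* (central differences), one column per link group."""
    params = fit.params.copy()
    model = copy.deepcopy(fit.model)
    experiments = [copy.deepcopy(e) for e in fit.experiments]
    theta = params.free_values()

    def resid(values):
        params.set_free_values(values)
        apply_parameters(params, model, experiments)
        return np.concatenate(weighted_residuals(experiments, model))

    r0 = resid(theta)
    J = np.empty((len(r0), len(theta)))
    for k in range(len(theta)):
        h = rel_step * max(abs(theta[k]), 1.0)
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        J[:, k] = (resid(tp) - resid(tm)) / (2 * h)
    return J


def covariance_and_correlation(
    fit: FitResult,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Covariance matrix and cross-correlation coefficients at the optimum.

    The covariance is the inverse curvature (J^T J)^-1 of the weighted
    least-squares problem, scaled by the reduced chi-square.  A singular
    curvature is flagged with a warning and handled by pseudo-inverse.
    """
    J = _free_jacobian(fit)
    H = J.T @ J
    scale = fit.chisq_reduced if np.isfinite(fit.chisq_reduced) and fit.chisq_reduced > 0 else 1.0
    try:
        cov = np.linalg.inv(H) * scale
        if not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular curvature matrix: parameters are not all identifiable; "
            "using pseudo-inverse",
            stacklevel=2,
        )
        cov = np.linalg.pinv(H) * scale
    d = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(d, d)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return cov, corr, list(fit.free_names)


@dataclass
class ErrorSurfaceProjection:
    """Profiled chi-square over one or two parameters.

    ``chisq`` has shape (n1,) or (n1, n2); invalid nodes (failed
    re-optimization) are masked out, never interpolated.  ``critical`` maps
    each confidence level to its F-statistics chi-square threshold.
    """

    param_names: list[str]
    grids: list[np.ndarray]
    chisq: np.ndarray
    chisq_min: float
    critical: dict[float, float]
    valid: np.ndarray

    def inside(self, cl: float) -> np.ndarray:
        return self.valid & (self.chisq <= self.critical[cl])


def profile_projection(
    fit: FitResult,
    param_names: str | list[str],
    grids: list[np.ndarray] | dict[str, np.ndarray],
    confidence_levels: tuple[float, ...] = (0.68, 0.95),
    reoptimize: bool = True,
) -> ErrorSurfaceProjection:
    """Project the error surface onto 1 or 2 free parameters.

    At each grid node the projected parameters are fixed and all remaining
    free parameters are re-optimized (unless none remain or ``reoptimize``
    is False); the profiled chi-square is thresholded by F-statistics to
    draw confidence contours.
    """
    if isinstance(param_names, str):
        param_names = [param_names]
    if len(param_names) not in (1, 2):
        raise ValueError("project onto 1 or 2 parameters")
    if isinstance(grids, dict):
        grids = [np.asarray(grids[n], dtype=float) for n in param_names]
    else:
        grids = [np.asarray(g, dtype=float) for g in grids]
    for n in param_names:
        if n not in fit.free_names:
            raise ValueError(f"{n!r} is not a free parameter of this fit")

    shape = tuple(len(g) for g in grids)
    chisq = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    base_params = fit.params.copy()
    others_free = [n for n in fit.free_names if n not in param_names]

    nodes = np.ndindex(*shape)
    for idx in nodes:
        params = base_params.copy()
        for name, g, i in zip(param_names, grids, idx):
            _fix_group(params, name, float(g[i]))
        try:
            if others_free and reoptimize:
                sub = fit_global(
                    fit.experiments, fit.model, params,
                    method="marquardt-levenberg", auto_locals=False,
                )
                chisq[idx] = sub.chisq
            else:
                model = copy.deepcopy(fit.model)
                exps = [copy.deepcopy(e) for e in fit.experiments]
                chisq[idx] = global_chisq(exps, model, params)["chisq"]
            valid[idx] = np.isfinite(chisq[idx])
        except Exception:
            valid[idx] = False

    p = len(param_names)
    dof = fit.n_eff - fit.n_free
    critical = {
        cl: fit.chisq * (1.0 + p / dof * sps.f.ppf(cl, p, dof))
        for cl in confidence_levels
    }
    return ErrorSurfaceProjection(
        param_names=param_names,
        grids=grids,
        chisq=chisq,
        chisq_min=fit.chisq,
        critical=critical,
        valid=valid,
    )


def _fix_group(params: ParameterSpace, group_name: str, value: float) -> None:
    """Fix every member of a free link group at a value, widening bounds if
    the profile grid steps outside them."""
    for p in params:
        if (p.link or p.name) == group_name:
            p.lower = min(p.lower, value)
            p.upper = max(p.upper, value)
            p.value = value
            p.fixed = True


def contour_area(proj: ErrorSurfaceProjection, cl: float) -> float:
    """Area of the confidence region on a 2-D projection grid (in grid
    coordinate units), counting one cell per inside node."""
    if len(proj.param_names) != 2:
        raise ValueError("contour_area needs a 2-D projection")
    gx, gy = proj.grids
    dx = float(np.mean(np.diff(gx)))
    dy = float(np.mean(np.diff(gy)))
    return float(np.count_nonzero(proj.inside(cl)) * dx * dy)


def monte_carlo_intervals(
    fit: FitResult,
    n_replicates: int = 500,
    confidence_levels: tuple[float, ...] = (0.68,),
    seed: int = 0,
    max_failure_fraction: float = 0.1,
) -> dict:
    """Monte-Carlo confidence intervals by refitting synthetic replicates.

    Replicate data are the best-fit model plus Gaussian noise at each point's
    sigma; each replicate is refitted from the best-fit start (a deliberate,
    mildly anti-conservative choice that keeps desk-scale runtime).
    """
    if n_replicates < 100:
        raise ValueError("use at least 100 replicates")
    rng = np.random.default_rng(seed)
    best_model = fit.model
    f_best = [predict(best_model, e) for e in fit.experiments]
    samples = []
    failures = 0
    for _ in range(n_replicates):
        exps = [copy.deepcopy(e) for e in fit.experiments]
        for e, f in zip(exps, f_best):
            e.y = f + rng.normal(size=len(f)) * e.sigma
        try:
            sub = fit_global(
                exps, fit.model, fit.params,
                method="marquardt-levenberg", auto_locals=False,
            )
            samples.append(sub.params.free_values())
        except Exception:
            failures += 1
            if failures > max_failure_fraction * n_replicates:
                raise RuntimeError(
                    f"{failures} Monte-Carlo replicate fits failed "
                    f"(> {max_failure_fraction:.0%} of {n_replicates})"
                )
    samples = np.asarray(samples)
    intervals = {}
    for cl in confidence_levels:
        lo = np.percentile(samples, 50 * (1 - cl), axis=0)
        hi = np.percentile(samples, 50 * (1 + cl), axis=0)
        intervals[cl] = {
            name: (float(l), float(h))
            for name, l, h in zip(fit.free_names, lo, hi)
        }
    return {
        "intervals": intervals,
        "samples": samples,
        "free_names": list(fit.free_names),
        "n_failures": failures,
    }


def weight_scan(
    fit: FitResult,
    weight_sets: list[dict[str, float] | list[float]],
    confidence_level: float = 0.68,
) -> dict:
    """Refit under alternative per-experiment weight sets {w_e}.

    Reports, per parameter, the union envelope of the confidence intervals
    across all weight sets and flags parameters whose best-fit value moves by
    more than its reference 1-sigma uncertainty — an alert that the analysis
    is sensitive to the weighting choice.
    """
    if len(weight_sets) < 2:
        raise ValueError("need at least 2 weight sets to scan")
    z = sps.norm.ppf(0.5 * (1 + confidence_level))
    cov_ref, _, names = covariance_and_correlation(fit)
    sigma_ref = np.sqrt(np.clip(np.diag(cov_ref), 0, np.inf))
    theta_ref = fit.params.free_values()

    envelope_lo = np.full(len(names), np.inf)
    envelope_hi = np.full(len(names), -np.inf)
    max_shift = np.zeros(len(names))
    per_set = []
    for wset in weight_sets:
        exps = [copy.deepcopy(e) for e in fit.experiments]
        if isinstance(wset, dict):
            weights = [float(wset[e.name]) for e in exps]
        else:
            weights = [float(w) for w in wset]
        if len(weights) != len(exps):
            raise ValueError("weight set length mismatch")
        if all(w == 0 for w in weights):
            raise ValueError("a weight set with all-zero weights is invalid")
        for e, w in zip(exps, weights):
            e.weight = w
        sub = fit_global(exps, fit.model, fit.params,
                         method="marquardt-levenberg", auto_locals=False)
        cov, _, _ = covariance_and_correlation(sub)
        sig = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        theta = sub.params.free_values()
        envelope_lo = np.minimum(envelope_lo, theta - z * sig)
        envelope_hi = np.maximum(envelope_hi, theta + z * sig)
        max_shift = np.maximum(max_shift, np.abs(theta - theta_ref))
        per_set.append({"weights": weights, "values": theta, "sigma": sig})
    flagged = [
        n for n, shift, s in zip(names, max_shift, sigma_ref) if shift > s
    ]
    return {
        "free_names": names,
        "envelope": {
            n: (float(lo), float(hi))
            for n, lo, hi in zip(names, envelope_lo, envelope_hi)
        },
        "max_shift": dict(zip(names, max_shift)),
        "reference_sigma": dict(zip(names, sigma_ref)),
        "flagged": flagged,
        "per_set": per_set,
    }


def consistency_test(
    experiments: list[Experiment],
    model: InteractionModel,
    params: ParameterSpace,
    confidence: float = 0.95,
) -> dict:
    """Cross-validation/F-statistics flagging of mutually inconsistent data.

    Experiments are partitioned by their ``subgroup`` label.  For each
    subgroup g the global parameters are cross-validated by refitting
    without g and refitting g alone; the joint fit is then compared against
    the split fits through the extra-sum-of-squares F-ratio

        F = ((chi2_joint - chi2_own - chi2_rest)/p)
            / ((chi2_own + chi2_rest)/(N_tot - 2p))

    with p free global parameters, which is F(p, N_tot-2p)-distributed for
    mutually consistent data (both the subgroup's and the leave-out
    estimation noise enter the denominator, keeping the test calibrated).
    A subgroup exceeding the critical F at the requested confidence is
    flagged as inconsistent with the remainder of the data.  The chi-square
    of g under the transferred leave-out parameters is reported as a
    diagnostic alongside.
    """
    groups: dict[str, list[Experiment]] = {}
    for e in experiments:
        groups.setdefault(e.subgroup or e.name, []).append(e)
    if len(groups) < 2:
        raise ValueError("need at least 2 subgroups to cross-validate")

    # only global (model-level) parameters transfer between subsets;
    # per-experiment locals stay fixed at their provided values
    gparams = ParameterSpace(
        [copy.deepcopy(p) for p in params if not p.name.startswith("exp[")]
    )
    p = len(gparams.free_groups())
    if p == 0:
        raise ValueError("consistency test needs at least one free global parameter")
    n_tot = sum(e.n_points for e in experiments)
    fit_joint = fit_global(experiments, model, gparams, method="marquardt-levenberg")
    results = {}
    for label, members in groups.items():
        rest = [e for e in experiments if e not in members]
        n_g = sum(e.n_points for e in members)
        if n_g <= p:
            warnings.warn(
                f"subgroup {label!r} too small to fit alone; skipped",
                stacklevel=2,
            )
            results[label] = {"skipped": True}
            continue
        fit_rest = fit_global(rest, model, gparams, method="marquardt-levenberg")
        # chi-square of g under the transferred leave-out parameters
        transfer = ParameterSpace(
            [copy.deepcopy(q) for q in fit_rest.params if not q.name.startswith("exp[")]
        )
        chisq_transfer = _eval_subset(members, model, transfer)
        fit_own = fit_global(members, model, gparams, method="marquardt-levenberg")
        chisq_split = fit_own.chisq + fit_rest.chisq
        denom_dof = n_tot - 2 * p
        f_ratio = ((fit_joint.chisq - chisq_split) / p) / max(
            chisq_split / denom_dof, 1e-300
        )
        f_crit = sps.f.ppf(confidence, p, denom_dof)
        results[label] = {
            "skipped": False,
            "chisq_joint": fit_joint.chisq,
            "chisq_own": fit_own.chisq,
            "chisq_rest": fit_rest.chisq,
            "chisq_transfer": chisq_transfer,
            "n": n_g,
            "f_ratio": float(f_ratio),
            "f_critical": float(f_crit),
            "flagged": bool(f_ratio > f_crit),
        }
    return results


def _eval_subset(members, model, gparams) -> float:
    """Chi-square of a subgroup under fixed global parameters; the
    subgroup's own locals stay at their provided values."""
    model = copy.deepcopy(model)
    members = [copy.deepcopy(e) for e in members]
    apply_parameters(gparams, model, members)
    return global_chisq(members, model)["chisq"]


def information_report(
    fit: FitResult, parameter: str, rel_sigma: float = 1.0
) -> list[dict]:
    """Which experiments carry information on a parameter?

    The parameter is perturbed by ``rel_sigma`` times its 1-sigma
    uncertainty and held fixed, the other global parameters stay at their
    best-fit values, and any free per-experiment locals are re-optimized;
    the per-experiment increase in chi-square, ranked in descending order,
    measures each experiment's sensitivity.
    """
    if parameter not in fit.free_names:
        raise ValueError(f"{parameter!r} is not a free parameter")
    cov, _, names = covariance_and_correlation(fit)
    k = names.index(parameter)
    sigma = math.sqrt(max(cov[k, k], 0.0))
    if sigma == 0.0:
        sigma = 1e-6 * max(abs(fit.params.free_values()[k]), 1.0)

    params = fit.params.copy()
    _fix_group(params, parameter, fit.params.free_values()[k] + rel_sigma * sigma)
    for q in params:
        if not q.name.startswith("exp["):
            q.fixed = True
    if any(not p.fixed for p in params):
        sub = fit_global(fit.experiments, fit.model, params,
                         method="marquardt-levenberg", auto_locals=False)
        perturbed = sub.per_experiment
    else:
        model = copy.deepcopy(fit.model)
        exps = [copy.deepcopy(e) for e in fit.experiments]
        perturbed = global_chisq(exps, model, params)["per_experiment"]
    base = {e["name"]: e["chisq"] for e in fit.per_experiment}
    report = [
        {
            "name": pe["name"],
            "technique": pe["technique"],
            "delta_chisq": pe["chisq"] - base[pe["name"]],
        }
        for pe in perturbed
    ]
    report.sort(key=lambda d: d["delta_chisq"], reverse=True)
    return report
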