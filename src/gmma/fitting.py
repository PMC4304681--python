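"""Global multi-method fitting.

One interaction model is projected into the observable space of every
experiment; the weighted global chi-square

    chi2_glob = sum_e w_e sum_i ((f_ei - y_ei) / sigma_ei)^2

is minimized over global thermodynamic parameters (log10 association
constants, enthalpies, s-values, ...) and per-experiment nuisance ("local")
parameters, which may be linked across experiments.  Bounds are enforced by
reparameterization (log / logit transforms), never by penalty terms, so all
optimizers work on an unconstrained free vector.
"""

from __future__ import annotations

import copy
import math
import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from . import observables as obs
from .equilibria import InteractionModel

__all__ = [
    "Parameter",
    "ParameterSpace",
    "Experiment",
    "FitResult",
    "predict",
    "global_chisq",
    "resolve_links",
    "fit_global",
    "auto_local_parameters",
]

TECHNIQUES = ("itc", "spr", "spr_competition", "sv_sw", "anisotropy", "signal")


@dataclass(eq=False)
class Experiment:
    """One technique's data set: design points, observations and errors.

    ``data`` holds one row per observation; composition columns are named
    ``total_<component>`` (molar).  ITC experiments instead carry an
    :class:`~gmma.observables.ItcProtocol` and an ``injection_volume``
    column.  ``meta`` holds non-numeric technique configuration (analyte,
    probe, signal name); ``locals`` the numeric nuisance parameters.
    """

    technique: str
    data: pd.DataFrame
    y: np.ndarray
    sigma: np.ndarray
    weight: float = 1.0
    locals: dict[str, float] = field(default_factory=dict)
    meta: dict[str, str] = field(default_factory=dict)
    protocol: obs.ItcProtocol | None = None
    calibration: obs.SprCalibration | None = None
    subgroup: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique tag {self.technique!r}")
        self.y = np.asarray(self.y, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if len(self.y) != len(self.data):
            raise ValueError("observation count does not match design points")
        if len(self.sigma) != len(self.y):
            raise ValueError("sigma count does not match observations")
        if np.any(self.sigma <= 0):
            raise ValueError("all standard deviations must be positive")
        if self.weight < 0:
            raise ValueError("experiment weight must be non-negative")
        if self.technique == "itc" and self.protocol is None:
            raise ValueError("ITC experiment requires a protocol")

    @property
    def n_points(self) -> int:
        return len(self.y)

    def compositions(self) -> dict[str, np.ndarray]:
        out = {}
        for col in self.data.columns:
            if col.startswith("total_"):
                out[col[len("total_"):]] = self.data[col].to_numpy(dtype=float)
        return out


def predict(model: InteractionModel, experiment: Experiment) -> np.ndarray:
    """Forward model f_{e,i} for one experiment under the current model."""
    t = experiment.technique
    loc = experiment.locals
    if t == "itc":
        return obs.itc_heats(model, experiment.protocol, loc)
    comps = experiment.compositions()
    if t == "spr":
        return obs.spr_steady_isotherm(model, comps, loc, experiment.meta["analyte"])
    if t == "spr_competition":
        cal = experiment.calibration
        if cal is None:
            # calibration carried through locals (fitted or fixed)
            cal = obs.SprCalibration(
                r_max=float(loc.get("Rmax", 100.0)),
                kd_surface=float(loc.get("Kd_surf", 1e-6)),
                baseline=float(loc.get("baseline", 0.0)),
            )
        return obs.spr_competition_isotherm(
            model, comps, cal, experiment.meta["analyte"], loc
        )
    if t == "sv_sw":
        return obs.sw_isotherm(model, comps, loc)
    if t == "anisotropy":
        return obs.anisotropy_isotherm(model, comps, loc, experiment.meta["probe"])
    if t == "signal":
        return obs.generic_signal_isotherm(model, comps, loc, experiment.meta["signal"])
    raise ValueError(f"no forward model for technique {t!r}")


# -- parameters ----------------------------------------------------------------


@dataclass
class Parameter:
    """One adjustable quantity, addressed by a path.

    Paths: ``species.<name>.<attr>`` (attr: log10beta, dH, s, anisotropy, or
    ``signal.<signame>``), ``component.<name>.<attr>`` likewise, and
    ``exp[<index>].<local key>`` for per-experiment nuisance parameters.
    Linked parameters share a ``link`` group id and are fitted as one value.
    """

    name: str
    value: float
    fixed: bool = True
    lower: float = -np.inf
    upper: float = np.inf
    link: str | None = None

    def __post_init__(self) -> None:
        if not self.lower <= self.value <= self.upper:
            raise ValueError(
                f"parameter {self.name}: value {self.value} outside bounds "
                f"[{self.lower}, {self.upper}]"
            )


class ParameterSpace:
    """Ordered collection of parameters with link resolution and transforms."""

    def __init__(self, parameters: Sequence[Parameter] = ()) -> None:
        self._params: dict[str, Parameter] = {}
        for p in parameters:
            self.add(p)

    def add(self, p: Parameter) -> None:
        if p.name in self._params:
            raise ValueError(f"duplicate parameter {p.name}")
        self._params[p.name] = p

    def set(
        self,
        name: str,
        value: float | None = None,
        fixed: bool | None = None,
        bounds: tuple[float, float] | None = None,
        link: str | None = None,
    ) -> Parameter:
        """Add or update a parameter in place."""
        if name in self._params:
            p = self._params[name]
            if value is not None:
                p.value = float(value)
            if fixed is not None:
                p.fixed = fixed
            if bounds is not None:
                p.lower, p.upper = map(float, bounds)
            if link is not None:
                p.link = link
        else:
            p = Parameter(
                name,
                float(value if value is not None else 0.0),
                fixed=True if fixed is None else fixed,
                lower=-np.inf if bounds is None else float(bounds[0]),
                upper=np.inf if bounds is None else float(bounds[1]),
                link=link,
            )
            self._params[name] = p
        if not p.lower <= p.value <= p.upper:
            raise ValueError(f"parameter {name}: value outside bounds")
        return p

    def __getitem__(self, name: str) -> Parameter:
        return self._params[name]

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __iter__(self):
        return iter(self._params.values())

    def __len__(self) -> int:
        return len(self._params)

    def copy(self) -> "ParameterSpace":
        return copy.deepcopy(self)

    # -- link resolution -------------------------------------------------------

    def free_groups(self) -> list[list[Parameter]]:
        """Free parameters grouped by link id (singletons for unlinked).

        A group mixing fixed and free members is contradictory and rejected;
        members of one group must share bounds so the shared transform is
        well defined.
        """
        groups: dict[str, list[Parameter]] = {}
        order: list[str] = []
        for p in self._params.values():
            key = p.link if p.link is not None else f"__solo__{p.name}"
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(p)
        out = []
        for key in order:
            members = groups[key]
            fixed_flags = {m.fixed for m in members}
            if len(fixed_flags) > 1:
                raise ValueError(
                    f"link group {key!r} mixes fixed and free parameters"
                )
            if fixed_flags == {False}:
                if len({(m.lower, m.upper) for m in members}) > 1:
                    raise ValueError(f"link group {key!r} has mismatched bounds")
                out.append(members)
        return out

    def group_names(self) -> list[str]:
        return [
            g[0].link if g[0].link is not None else g[0].name
            for g in self.free_groups()
        ]

    # -- bound transforms ------------------------------------------------------

    @staticmethod
    def _to_unconstrained(value: float, lo: float, hi: float) -> float:
        if np.isfinite(lo) and np.isfinite(hi):
            x = (value - lo) / (hi - lo)
            x = min(max(x, 1e-12), 1 - 1e-12)
            return math.log(x / (1 - x))
        if np.isfinite(lo):
            return math.log(max(value - lo, 1e-300))
        if np.isfinite(hi):
            return -math.log(max(hi - value, 1e-300))
        return value

    @staticmethod
    def _from_unconstrained(u: float, lo: float, hi: float) -> float:
        if np.isfinite(lo) and np.isfinite(hi):
            return lo + (hi - lo) / (1.0 + math.exp(-u))
        if np.isfinite(lo):
            return lo + math.exp(u)
        if np.isfinite(hi):
            return hi - math.exp(-u)
        return u

    def to_free_vector(self) -> np.ndarray:
        return np.array(
            [
                self._to_unconstrained(g[0].value, g[0].lower, g[0].upper)
                for g in self.free_groups()
            ]
        )

    def from_free_vector(self, u: np.ndarray) -> None:
        groups = self.free_groups()
        if len(u) != len(groups):
            raise ValueError("free-vector length mismatch")
        for ui, g in zip(u, groups):
            val = self._from_unconstrained(float(ui), g[0].lower, g[0].upper)
            for m in g:
                m.value = val

    def free_values(self) -> np.ndarray:
        return np.array([g[0].value for g in self.free_groups()])

    def set_free_values(self, values: np.ndarray) -> None:
        groups = self.free_groups()
        if len(values) != len(groups):
            raise ValueError("free-value length mismatch")
        for v, g in zip(values, groups):
            for m in g:
                m.value = float(v)

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": p.name,
                    "value": p.value,
                    "fixed": p.fixed,
                    "lower": p.lower,
                    "upper": p.upper,
                    "link": p.link,
                }
                for p in self._params.values()
            ]
        )


def resolve_links(params: ParameterSpace) -> tuple[np.ndarray, Callable]:
    """Flatten free parameters (one slot per link group) and return the
    inverse mapping; round-trip is the identity."""
    vec = params.to_free_vector()

    def back(u: np.ndarray, target: ParameterSpace | None = None) -> ParameterSpace:
        t = target if target is not None else params
        t.from_free_vector(np.asarray(u, dtype=float))
        return t

    return vec, back


_EXP_RE = re.compile(r"^exp\[(\d+)\]\.(.+)$")


def apply_parameters(
    params: ParameterSpace,
    model: InteractionModel,
    experiments: Sequence[Experiment],
) -> None:
    """Push current parameter values into the model and experiment locals."""
    for p in params:
        parts = p.name.split(".")
        m = _EXP_RE.match(p.name)
        if m is not None:
            idx, key = int(m.group(1)), m.group(2)
            experiments[idx].locals[key] = p.value
        elif parts[0] == "species":
            sp = model.get_species(parts[1])
            if parts[2] == "signal":
                sp.signals[parts[3]] = p.value
            else:
                setattr(sp, parts[2], p.value)
        elif parts[0] == "component":
            c = model.component(parts[1])
            if parts[2] == "signal":
                c.signals[parts[3]] = p.value
            else:
                setattr(c, parts[2], p.value)
        else:
            raise ValueError(f"unrecognized parameter path {p.name!r}")


def auto_local_parameters(
    params: ParameterSpace,
    model: InteractionModel,
    experiments: Sequence[Experiment],
) -> None:
    """Register every experiment's nuisance parameters that are not yet in
    the space, fixed at their current values.

    This mirrors the automatic local-parameter management of the global
    analysis: adding a data set brings its technique's locals along without
    user intervention; the user then frees or links the ones of interest.
    """
    for i, e in enumerate(experiments):
        defaults = obs.default_locals(e.technique, model)
        for key, val in defaults.items():
            e.locals.setdefault(key, val)
        for key, val in e.locals.items():
            name = f"exp[{i}].{key}"
            if name not in params:
                params.add(Parameter(name, float(val), fixed=True))


# -- objective -----------------------------------------------------------------


def weighted_residuals(
    experiments: Sequence[Experiment], model: InteractionModel
) -> list[np.ndarray]:
    """Per-experiment residual vectors sqrt(w_e) * (f - y) / sigma."""
    out = []
    for e in experiments:
        f = predict(model, e)
        out.append(math.sqrt(e.weight) * (f - e.y) / e.sigma)
    return out


def global_chisq(
    experiments: Sequence[Experiment],
    model: InteractionModel,
    params: ParameterSpace | None = None,
) -> dict:
    """Weighted global chi-square and its per-experiment decomposition.

    chi2_glob = sum_e w_e chi2_e; the reduced form divides by
    (sum_e w_e N_e - P) with P the number of free parameters after link
    resolution, so E[chi2_r] is ~1 for correct sigmas at unit weights.
    """
    n_free = 0
    if params is not None:
        apply_parameters(params, model, experiments)
        n_free = len(params.free_groups())
    per_exp = []
    chisq = 0.0
    n_eff = 0.0
    for e in experiments:
        f = predict(model, e)
        r = (f - e.y) / e.sigma
        c = float(np.sum(r * r))
        per_exp.append(
            {
                "name": e.name,
                "technique": e.technique,
                "n": e.n_points,
                "weight": e.weight,
                "chisq": c,
                "weighted_chisq": e.weight * c,
                "rmsd": float(np.sqrt(np.mean((f - e.y) ** 2))),
            }
        )
        chisq += e.weight * c
        n_eff += e.weight * e.n_points
    dof = n_eff - n_free
    return {
        "chisq": chisq,
        "chisq_reduced": chisq / dof if dof > 0 else np.nan,
        "n_eff": n_eff,
        "n_free": n_free,
        "per_experiment": per_exp,
    }


# -- fit result ----------------------------------------------------------------


@dataclass
class FitResult:
    params: ParameterSpace
    model: InteractionModel
    experiments: list[Experiment]
    chisq: float
    chisq_reduced: float
    n_eff: float
    n_free: int
    per_experiment: list[dict]
    free_names: list[str]
    method: str
    success: bool
    message: str
    n_eval: int
    trace: list[tuple[int, float]] = field(default_factory=list)
    covariance: np.ndarray | None = None

    def free_dict(self) -> dict[str, float]:
        return dict(zip(self.free_names, self.params.free_values()))


def _objective_factory(experiments, model, params, trace):
    state = {"n": 0}

    def residual_vec(u):
        params.from_free_vector(u)
        apply_parameters(params, model, experiments)
        r = np.concatenate(weighted_residuals(experiments, model))
        state["n"] += 1
        trace.append((state["n"], float(np.dot(r, r))))
        return r

    def chisq_of(u):
        r = residual_vec(u)
        return float(np.dot(r, r))

    return residual_vec, chisq_of, state


def fit_global(
    experiments: Sequence[Experiment],
    model: InteractionModel,
    params: ParameterSpace,
    method: str = "marquardt-levenberg",
    seed: int | None = None,
    max_iter: int = 2000,
    auto_locals: bool = True,
) -> FitResult:
    """Minimize the weighted global chi-square.

    ``method`` is one of ``marquardt-levenberg`` (aliases ``ml``, ``lm``),
    ``simplex`` (Nelder-Mead with one restart from the converged point) or
    ``simulated-annealing`` (seeded exponential-cooling Metropolis followed
    by a simplex polish; ``seed`` is mandatory).  The returned chi-square is
    never above the starting one.
    """
    model = copy.deepcopy(model)
    experiments = [copy.deepcopy(e) for e in experiments]
    params = params.copy()
    if auto_locals:
        auto_local_parameters(params, model, experiments)
    groups = params.free_groups()
    if not groups:
        raise ValueError("all parameters fixed: nothing to fit")
    trace: list[tuple[int, float]] = []
    residual_vec, chisq_of, state = _objective_factory(
        experiments, model, params, trace
    )
    u0 = params.to_free_vector()
    chisq0 = chisq_of(u0)
    if not np.isfinite(chisq0):
        raise ValueError("objective is not finite at the starting parameters")

    method = method.lower()
    if method in ("marquardt-levenberg", "ml", "lm", "marquardt"):
        n_res = sum(e.n_points for e in experiments)
        ls_method = "lm" if n_res >= len(u0) else "trf"
        sol = least_squares(
            residual_vec, u0, method=ls_method, diff_step=1e-6, max_nfev=max_iter
        )
        u_best, success, msg = sol.x, sol.success, sol.message
        canonical = "marquardt-levenberg"
    elif method in ("simplex", "nelder-mead", "nm"):
        res = minimize(chisq_of, u0, method="Nelder-Mead",
                       options={"maxiter": max_iter, "xatol": 1e-10, "fatol": 1e-12})
        # one restart from the converged point guards against premature collapse
        res2 = minimize(chisq_of, res.x, method="Nelder-Mead",
                        options={"maxiter": max_iter, "xatol": 1e-10, "fatol": 1e-12})
        u_best = res2.x if res2.fun <= res.fun else res.x
        success, msg = bool(res2.success or res.success), res2.message
        canonical = "simplex"
    elif method in ("simulated-annealing", "anneal", "sa"):
        if seed is None:
            raise ValueError("simulated annealing requires a seed for reproducibility")
        u_best = _anneal(chisq_of, u0, seed=seed, n_steps=max_iter)
        res = minimize(chisq_of, u_best, method="Nelder-Mead",
                       options={"maxiter": max_iter})
        if res.fun <= chisq_of(u_best):
            u_best = res.x
        success, msg = True, "annealing complete"
        canonical = "simulated-annealing"
    else:
        raise ValueError(f"unknown optimizer {method!r}")

    if chisq_of(u_best) > chisq0:
        u_best = u0  # never accept a worse point than the start
    chisq_best = chisq_of(u_best)
    params.from_free_vector(u_best)
    apply_parameters(params, model, experiments)
    breakdown = global_chisq(experiments, model)
    n_free = len(groups)
    dof = breakdown["n_eff"] - n_free
    return FitResult(
        params=params,
        model=model,
        experiments=experiments,
        chisq=chisq_best,
        chisq_reduced=chisq_best / dof if dof > 0 else np.nan,
        n_eff=breakdown["n_eff"],
        n_free=n_free,
        per_experiment=breakdown["per_experiment"],
        free_names=params.group_names(),
        method=canonical,
        success=bool(success),
        message=str(msg),
        n_eval=state["n"],
        trace=trace,
    )


def _anneal(chisq_of, u0, seed, n_steps=2000, t0=None, cooling=0.995, step=0.3):
    """Minimal seeded Metropolis annealer with exponential cooling."""
    rng = np.random.default_rng(seed)
    u = np.asarray(u0, dtype=float).copy()
    f = chisq_of(u)
    if t0 is None:
        t0 = max(f, 1.0)
    u_best, f_best = u.copy(), f
    temp = t0
    for _ in range(int(n_steps)):
        cand = u + rng.normal(scale=step, size=u.shape)
        fc = chisq_of(cand)
        if fc < f or rng.random() < math.exp(-(fc - f) / max(temp, 1e-12)):
            u, f = cand, fc
            if f < f_best:
                u_best, f_best = u.copy(), f
        temp *= cooling
    return u_best
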