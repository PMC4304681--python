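"""Experiment planning in concentration space.

Two-dimensional maps over log10 total concentrations of two components
(predicted signal, fractional signal contribution per complex, fractional
population per complex, or differential parameter-sensitivity), feasibility
cropping by stock concentrations and signal bounds, log-equidistant
trajectory sampling, pipetting recipes, and in-silico dataset generation
that feeds straight back into the global fit.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import observables as obs
from .equilibria import InteractionModel, solve_batch
from .fitting import Experiment, predict

__all__ = [
    "MapAxes",
    "DesignMap",
    "TitrationPlan",
    "concentration_map",
    "crop_map",
    "differential_map",
    "trajectory_points",
    "mixing_recipes",
    "simulate_dataset",
]

#: techniques whose signal is a per-composition point function
_MAPPABLE = ("sv_sw", "anisotropy", "signal", "spr")


@dataclass
class MapAxes:
    """Axes of a concentration-space map: two varied components on log10
    molar grids, all other components held at a fixed background."""

    comp_x: str
    log10_min_x: float
    log10_max_x: float
    comp_y: str
    log10_min_y: float
    log10_max_y: float
    n_x: int = 25
    n_y: int = 25
    background: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.comp_x == self.comp_y:
            raise ValueError("map axes must vary two distinct components")
        if self.n_x < 2 or self.n_y < 2:
            raise ValueError("need at least 2 nodes per axis")

    def grids(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.logspace(self.log10_min_x, self.log10_max_x, self.n_x),
            np.logspace(self.log10_min_y, self.log10_max_y, self.n_y),
        )


@dataclass
class DesignMap:
    axes: MapAxes
    mode: str  # signal | fractional-signal | population | differential
    technique: str | None
    #: (n_x, n_y) signal or sensitivity matrix (signal/differential modes)
    values: np.ndarray | None
    #: per-species (n_x, n_y) fraction matrices (fractional modes)
    fractions: dict[str, np.ndarray] | None
    mask: np.ndarray

    def masked_values(self) -> np.ndarray:
        out = np.array(self.values, dtype=float)
        out[~self.mask] = np.nan
        return out


@dataclass
class TitrationPlan:
    """Mixture compositions with one-step pipetting recipes from stocks."""

    compositions: pd.DataFrame  # molar, one column per component
    recipes: pd.DataFrame  # volumes (same unit as total_volume) per stock + buffer
    total_volume: float
    stocks: dict[str, float]


def _node_compositions(model: InteractionModel, axes: MapAxes):
    gx, gy = axes.grids()
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    comps = {}
    for c in model.component_names:
        if c == axes.comp_x:
            comps[c] = X.ravel()
        elif c == axes.comp_y:
            comps[c] = Y.ravel()
        else:
            comps[c] = np.full(X.size, axes.background.get(c, 0.0))
    return comps, X.shape


def _signal_at(model, technique, locals, meta, comps):
    if technique == "sv_sw":
        return obs.sw_isotherm(model, comps, locals)
    if technique == "anisotropy":
        return obs.anisotropy_isotherm(model, comps, locals, meta["probe"])
    if technique == "signal":
        return obs.generic_signal_isotherm(model, comps, locals, meta["signal"])
    if technique == "spr":
        return obs.spr_steady_isotherm(model, comps, locals, meta["analyte"])
    raise ValueError(
        f"technique {technique!r} has no per-composition signal map"
    )


def concentration_map(
    model: InteractionModel,
    axes: MapAxes,
    mode: str = "signal",
    technique: str | None = None,
    locals: Mapping[str, float] | None = None,
    meta: Mapping[str, str] | None = None,
    reference_component: str | None = None,
) -> DesignMap:
    """Map a model over a 2-D grid of total concentrations.

    Modes: ``signal`` (technique-specific predicted signal),
    ``fractional-signal`` (each complex's share of the total signal),
    ``population`` (technique-independent fraction of the reference
    component found in each species, free form included; sums to 1).
    """
    locals = dict(locals or {})
    meta = dict(meta or {})
    comps, shape = _node_compositions(model, axes)

    if mode == "signal":
        vals = _signal_at(model, technique, locals, meta, comps).reshape(shape)
        return DesignMap(axes, mode, technique, vals, None,
                         np.ones(shape, dtype=bool))

    totals = np.column_stack([comps[c] for c in model.component_names])
    free, conc = solve_batch(model, totals)
    S = model.stoich_matrix()
    names = model.component_names

    if mode == "population":
        ref = reference_component or axes.comp_x
        j = names.index(ref)
        T = totals[:, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            fr = {
                f"free {ref}": np.where(T > 0, free[:, j] / T, np.nan).reshape(shape)
            }
            for i, sp in enumerate(model.species):
                if S[i, j] > 0:
                    fr[sp.name] = np.where(
                        T > 0, S[i, j] * conc[:, i] / T, np.nan
                    ).reshape(shape)
        return DesignMap(axes, mode, None, None, fr, np.ones(shape, dtype=bool))

    if mode == "fractional-signal":
        if technique in ("sv_sw",):
            comp_eps = np.array([locals.get(f"eps.{c}", 0.0) for c in names])
            sp_eps = S @ comp_eps
        else:
            signame = meta.get("signal", "")
            comp_eps = np.array([c.signals.get(signame, 0.0) for c in model.components])
            sp_eps = model.species_signal_coefficients(signame)
        total_sig = free @ comp_eps + conc @ sp_eps
        with np.errstate(divide="ignore", invalid="ignore"):
            fr = {
                sp.name: np.where(
                    total_sig > 0, sp_eps[i] * conc[:, i] / total_sig, np.nan
                ).reshape(shape)
                for i, sp in enumerate(model.species)
            }
        return DesignMap(axes, mode, technique, None, fr, np.ones(shape, dtype=bool))

    raise ValueError(f"unknown map mode {mode!r}")


def crop_map(
    dmap: DesignMap,
    stocks: Mapping[str, float] | None = None,
    min_signal: float | None = None,
    max_signal: float | None = None,
) -> DesignMap:
    """Restrict a map to experimentally feasible nodes.

    A node is feasible if its mixture can be pipetted in one step from the
    component stocks plus buffer (sum of volume fractions <= 1) and, when
    signal bounds are given, its mapped signal lies within them.  The mask
    only ever removes nodes.
    """
    axes = dmap.axes
    gx, gy = axes.grids()
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    mask = dmap.mask.copy()
    if stocks:
        for comp, stock in stocks.items():
            if stock <= 0:
                raise ValueError(f"stock concentration for {comp} must be positive")
        vf = np.zeros_like(X)
        for comp, stock in stocks.items():
            if comp == axes.comp_x:
                vf += X / stock
            elif comp == axes.comp_y:
                vf += Y / stock
            else:
                vf += axes.background.get(comp, 0.0) / stock
        mask &= vf <= 1.0 + 1e-12
    if min_signal is not None or max_signal is not None:
        if dmap.values is None:
            raise ValueError("signal bounds require a signal-mode map")
        v = dmap.values
        if min_signal is not None:
            mask &= v >= min_signal
        if max_signal is not None:
            mask &= v <= max_signal
    if not mask.any():
        raise ValueError(
            "no feasible nodes remain: check stock concentrations "
            f"(stocks={dict(stocks or {})}) and signal bounds "
            f"[{min_signal}, {max_signal}]"
        )
    return replace(dmap, mask=mask)


def differential_map(
    model: InteractionModel,
    axes: MapAxes,
    parameter: str,
    technique: str,
    locals: Mapping[str, float] | None = None,
    meta: Mapping[str, str] | None = None,
    rel_step: float = 0.05,
) -> DesignMap:
    """Sensitivity map |d(signal)/d(log parameter)| by central differences.

    ``parameter`` is a model-parameter path (``species.AB.log10beta``,
    ``species.ABB.dH``, ...).  Parameters that are already logarithmic
    (log10beta) are stepped additively; all others are stepped in their
    natural log, so the map is a per-decade sensitivity either way.
    """
    if rel_step <= 0 or rel_step < 1e-12:
        raise ValueError("relative step underflow")
    locals = dict(locals or {})
    meta = dict(meta or {})
    comps, shape = _node_compositions(model, axes)

    def perturbed(sign: float) -> np.ndarray:
        m = copy.deepcopy(model)
        _step_model_parameter(m, parameter, sign * rel_step)
        return _signal_at(m, technique, locals, meta, comps)

    hi = perturbed(+1.0)
    lo = perturbed(-1.0)
    vals = np.abs(hi - lo) / (2.0 * rel_step)
    return DesignMap(axes, "differential", technique, vals.reshape(shape), None,
                     np.ones(shape, dtype=bool))


def _step_model_parameter(model: InteractionModel, path: str, step: float) -> None:
    parts = path.split(".")
    if parts[0] == "species":
        target = model.get_species(parts[1])
    elif parts[0] == "component":
        target = model.component(parts[1])
    else:
        raise ValueError(f"{path!r} is not a model parameter path")
    if parts[2] == "signal":
        cur = target.signals.get(parts[3], 0.0)
        target.signals[parts[3]] = cur * np.exp(step) if cur != 0 else step
        return
    cur = getattr(target, parts[2])
    if parts[2].startswith("log10"):
        setattr(target, parts[2], cur + step)  # already a log quantity
    elif cur != 0:
        setattr(target, parts[2], cur * float(np.exp(step)))
    else:
        setattr(target, parts[2], step)


def trajectory_points(
    axes: MapAxes,
    start: tuple[float, float],
    end: tuple[float, float],
    n: int,
) -> pd.DataFrame:
    """n log-equidistant compositions along a segment in the map's log10
    concentration coordinates, endpoints included."""
    if n < 2:
        raise ValueError("need at least 2 trajectory points")
    lstart = np.log10(np.asarray(start, dtype=float))
    lend = np.log10(np.asarray(end, dtype=float))
    for (lx, ly) in (lstart, lend):
        if not (axes.log10_min_x - 1e-9 <= lx <= axes.log10_max_x + 1e-9):
            raise ValueError("trajectory endpoint outside the map's x-axis")
        if not (axes.log10_min_y - 1e-9 <= ly <= axes.log10_max_y + 1e-9):
            raise ValueError("trajectory endpoint outside the map's y-axis")
    t = np.linspace(0.0, 1.0, n)
    logs = lstart[None, :] + t[:, None] * (lend - lstart)[None, :]
    out = pd.DataFrame(10.0 ** logs, columns=[axes.comp_x, axes.comp_y])
    for comp, conc in axes.background.items():
        out[comp] = conc
    return out


def mixing_recipes(
    compositions: pd.DataFrame,
    stocks: Mapping[str, float],
    total_volume: float,
) -> TitrationPlan:
    """One-step pipetting recipes: v_component = c * V / stock, buffer fills
    to V.  Exact by construction; an infeasible mixture raises, naming the
    dominant violating component."""
    if total_volume <= 0:
        raise ValueError("total volume must be positive")
    vols = {}
    for comp in compositions.columns:
        c = compositions[comp].to_numpy(dtype=float)
        if np.all(c == 0):
            vols[f"v_{comp}"] = np.zeros(len(compositions))
            continue
        if comp not in stocks:
            raise ValueError(f"no stock concentration given for component {comp}")
        if stocks[comp] <= 0:
            raise ValueError(f"stock concentration for {comp} must be positive")
        vols[f"v_{comp}"] = c * total_volume / stocks[comp]
    recipes = pd.DataFrame(vols)
    v_buffer = total_volume - recipes.sum(axis=1)
    if (v_buffer < -1e-12 * total_volume).any():
        row = int(v_buffer.idxmin())
        shares = {
            comp: compositions[comp].iloc[row] / stocks[comp]
            for comp in compositions.columns
            if comp in stocks and stocks[comp] > 0
        }
        worst = max(shares, key=shares.get)
        raise ValueError(
            f"mixture {row} infeasible from the given stocks "
            f"(volume fractions sum to {1 - v_buffer.iloc[row] / total_volume:.3f}); "
            f"largest contribution from component {worst}"
        )
    recipes["v_buffer"] = np.clip(v_buffer, 0.0, None)
    return TitrationPlan(
        compositions=compositions.reset_index(drop=True),
        recipes=recipes,
        total_volume=float(total_volume),
        stocks=dict(stocks),
    )


_REJECTED_TECHNIQUES = {
    "se": "sedimentation-equilibrium profiles",
    "sv": "sedimentation-velocity boundary data",
}


def simulate_dataset(
    model: InteractionModel,
    technique: str,
    plan: pd.DataFrame | obs.ItcProtocol,
    locals: Mapping[str, float],
    sigma: float | np.ndarray,
    seed: int | None = None,
    meta: Mapping[str, str] | None = None,
    weight: float = 1.0,
    subgroup: str | None = None,
    name: str = "",
) -> Experiment:
    """Generate one in-silico experiment: forward model plus i.i.d. Gaussian
    noise at the given sigma, ready to be added to a global fit.

    ``plan`` is a composition table (one column per component, molar) for
    isotherm techniques, or an :class:`~gmma.observables.ItcProtocol` for
    ITC.  Likely values of the technique's local parameters must be given.
    """
    if technique in _REJECTED_TECHNIQUES:
        raise ValueError(
            f"technique {technique!r} ({_REJECTED_TECHNIQUES[technique]}) is "
            "not supported in this artifact; isotherm-level data only"
        )
    locals = dict(locals)
    meta = dict(meta or {})
    if technique == "itc":
        if not isinstance(plan, obs.ItcProtocol):
            raise ValueError("ITC simulation requires an ItcProtocol")
        data = pd.DataFrame(
            {"injection_volume": np.asarray(plan.injection_volumes, dtype=float)}
        )
        protocol = plan
    else:
        if isinstance(plan, obs.ItcProtocol):
            raise ValueError(f"technique {technique!r} takes a composition table")
        data = pd.DataFrame(
            {f"total_{c}": plan[c].to_numpy(dtype=float) for c in plan.columns}
        )
        protocol = None
    exp = Experiment(
        technique=technique,
        data=data,
        y=np.zeros(len(data)),
        sigma=np.ones(len(data)),
        weight=weight,
        locals=locals,
        meta=meta,
        protocol=protocol,
        subgroup=subgroup,
        name=name or f"sim_{technique}",
    )
    f = predict(model, exp)
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), f.shape).copy()
    if np.any(sig < 0):
        raise ValueError("noise sigma must be non-negative")
    rng = np.random.default_rng(seed)
    exp.y = f + rng.normal(size=f.shape) * sig
    # recorded sigma must stay positive even for noise-free simulations
    exp.sigma = np.where(sig > 0, sig, np.maximum(1e-12, 1e-6 * np.abs(f).max()))
    return exp
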