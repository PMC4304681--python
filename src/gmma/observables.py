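"""Per-technique forward models.

Each function projects one :class:`~gmma.equilibria.InteractionModel` into an
experiment's observable space: ITC injection heats, steady-state or
competition SPR responses, signal-weighted average sedimentation coefficients
(s_w), fluorescence anisotropy, or a generic linear spectroscopic signal.

Compositions are passed as a mapping ``{component: array_of_molar_totals}``;
technique-specific nuisance parameters ("locals") are plain float mappings
keyed like ``gamma.A``, ``incompetent.B``, ``baseline``, ``Rmax`` so that
they can be addressed uniformly by the fitting layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .equilibria import InteractionModel, solve_batch

__all__ = [
    "ItcProtocol",
    "SprCalibration",
    "default_locals",
    "effective_totals",
    "itc_heats",
    "spr_steady_isotherm",
    "fit_spr_calibration",
    "spr_competition_isotherm",
    "sw_isotherm",
    "anisotropy_isotherm",
    "generic_signal_isotherm",
]


@dataclass
class ItcProtocol:
    """Injection schedule and cell geometry of a titration calorimetry run.

    Volumes in litres, concentrations molar.  ``injectant`` names the
    component whose injected moles normalize the heats; defaults to the most
    concentrated syringe component.
    """

    cell_volume: float
    syringe_concentrations: dict[str, float]
    initial_cell_concentrations: dict[str, float]
    injection_volumes: Sequence[float]
    temperature: float = 298.15
    injectant: str | None = None

    def __post_init__(self) -> None:
        if self.cell_volume <= 0:
            raise ValueError("cell_volume must be positive")
        vols = np.asarray(self.injection_volumes, dtype=float)
        if len(vols) == 0 or np.any(vols <= 0):
            raise ValueError("injection volumes must be positive")
        if self.injectant is None:
            if not self.syringe_concentrations:
                raise ValueError("syringe is empty")
            self.injectant = max(
                self.syringe_concentrations, key=self.syringe_concentrations.get
            )


@dataclass
class SprCalibration:
    """Empirical 1:1 Langmuir calibration of an SPR surface.

    Obtained from a direct binding series; thereafter the surface is used
    solely as a probe of the free concentration of the surface-binding
    partner in solution mixtures.
    """

    r_max: float
    kd_surface: float
    baseline: float = 0.0
    free_min: float = 0.0
    free_max: float = np.inf

    def response(self, free: np.ndarray) -> np.ndarray:
        free = np.asarray(free, dtype=float)
        return self.r_max * free / (self.kd_surface + free) + self.baseline


_LOCAL_DEFAULTS = {
    "itc": {"baseline": 0.0, "q_dil": 0.0},
    "spr": {"Rmax": 100.0, "Kd_surf": 1e-6, "baseline": 0.0},
    "spr_competition": {"Rmax": 100.0, "Kd_surf": 1e-6, "baseline": 0.0},
    "sv_sw": {"pathlength": 1.2},
    "anisotropy": {"baseline": 0.0},
    "signal": {"baseline": 0.0},
}


def default_locals(technique: str, model: InteractionModel) -> dict[str, float]:
    """Default nuisance-parameter registry for a technique.

    Every component gets a concentration-error factor gamma (default 1) and
    an incompetent fraction (default 0); technique-specific entries are added
    on top.  The fitting layer auto-populates these so users only override
    what they want to float or change.
    """
    if technique not in _LOCAL_DEFAULTS:
        raise ValueError(f"unknown technique {technique!r}")
    out: dict[str, float] = {}
    for c in model.component_names:
        out[f"gamma.{c}"] = 1.0
        out[f"incompetent.{c}"] = 0.0
    out.update(_LOCAL_DEFAULTS[technique])
    if technique == "sv_sw":
        for c in model.components:
            out[f"eps.{c.name}"] = 1.0
    if technique == "anisotropy":
        out["r_free"] = 0.0
    return out


def effective_totals(
    nominal: Mapping[str, float | np.ndarray], locals: Mapping[str, float]
) -> dict[str, np.ndarray]:
    """Competent totals: nominal * gamma * (1 - incompetent fraction).

    The reaction stoichiometry itself is never rescaled; concentration error
    and inactive material are handled exclusively through these bounded
    nuisance parameters.
    """
    out = {}
    for comp, val in nominal.items():
        gamma = float(locals.get(f"gamma.{comp}", 1.0))
        incomp = float(locals.get(f"incompetent.{comp}", 0.0))
        if gamma <= 0:
            raise ValueError(f"gamma.{comp} must be positive (got {gamma})")
        if not 0.0 <= incomp <= 1.0:
            raise ValueError(f"incompetent.{comp} must lie in [0, 1]")
        out[comp] = np.asarray(val, dtype=float) * gamma * (1.0 - incomp)
    return out


def _composition_matrix(
    model: InteractionModel, compositions: Mapping[str, np.ndarray]
) -> np.ndarray:
    arrays = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in compositions.items()}
    n = max(len(a) for a in arrays.values())
    out = np.zeros((n, len(model.components)))
    for j, comp in enumerate(model.component_names):
        if comp in arrays:
            a = arrays[comp]
            out[:, j] = a if len(a) == n else np.full(n, a[0])
    return out


def _solve_compositions(model, compositions, locals):
    eff = effective_totals(compositions, locals)
    totals = _composition_matrix(model, eff)
    return solve_batch(model, totals)


# -- ITC ----------------------------------------------------------------------


def itc_heats(
    model: InteractionModel,
    protocol: ItcProtocol,
    locals: Mapping[str, float],
) -> np.ndarray:
    """Normalized injection heats (kcal per mole of injectant).

    Standard perfusion-cell bookkeeping: each injection of volume v dilutes
    the pre-injection cell content by (1 - v/V0) and adds syringe material at
    v/V0.  The enthalpy content of the cell is H = V0 * sum_s dH_s [s]; the
    observed raw heat of injection i is

        q_i = H(i) - H(i-1) + (v_i/V0) * (H(i) + H(i-1)) / 2

    where the last term is the mean-value correction for reaction enthalpy
    carried out with the displaced volume.  A per-mole heat of dilution
    (``q_dil``) and baseline offset add to the normalized heats.
    """
    V0 = protocol.cell_volume
    comp_names = model.component_names
    cell_eff = effective_totals(
        {c: protocol.initial_cell_concentrations.get(c, 0.0) for c in comp_names},
        locals,
    )
    syr_eff = effective_totals(
        {c: protocol.syringe_concentrations.get(c, 0.0) for c in comp_names},
        locals,
    )
    vols = np.asarray(protocol.injection_volumes, dtype=float)
    n_inj = len(vols)

    # build the composition after every injection, then solve as one batch
    cell = np.array([float(cell_eff[c]) for c in comp_names])
    syr = np.array([float(syr_eff[c]) for c in comp_names])
    comps = np.empty((n_inj + 1, len(comp_names)))
    comps[0] = cell
    for i, v in enumerate(vols):
        f = v / V0
        cell = cell * (1.0 - f) + syr * f
        comps[i + 1] = cell
    _, conc = solve_batch(model, comps)
    dH = np.array([sp.dH for sp in model.species])
    H = V0 * conc @ dH  # enthalpy content per state, kcal

    inj_conc = protocol.syringe_concentrations.get(protocol.injectant, 0.0)
    inj_gamma = float(locals.get(f"gamma.{protocol.injectant}", 1.0))
    moles = vols * inj_conc * inj_gamma
    if np.any(moles <= 0):
        raise ValueError("injectant moles per injection must be positive")

    frac = vols / V0
    q_raw = H[1:] - H[:-1] + frac * (H[1:] + H[:-1]) / 2.0
    q_norm = q_raw / moles
    q_norm = q_norm + float(locals.get("q_dil", 0.0)) + float(locals.get("baseline", 0.0))
    return q_norm


# -- SPR ----------------------------------------------------------------------


def spr_steady_isotherm(
    model: InteractionModel,
    compositions: Mapping[str, np.ndarray],
    locals: Mapping[str, float],
    analyte: str,
    surface_valency: int = 1,
) -> np.ndarray:
    """Steady-state SPR response of the free analyte over a 1:1 surface.

    R = Rmax * [free analyte] / (Kd_surf + [free analyte]) + baseline, with
    the free concentration obtained from the solution equilibrium of the
    injected mixture.  Multivalent surface binding is rejected: it cannot be
    modeled reliably and is outside this artifact's scope.
    """
    if analyte not in model.component_names:
        raise ValueError(f"analyte {analyte!r} is not a model component")
    if surface_valency != 1:
        raise ValueError("multivalent surface binding models are not supported")
    free, _ = _solve_compositions(model, compositions, locals)
    f_analyte = free[:, model.component_names.index(analyte)]
    r_max = float(locals.get("Rmax", 100.0))
    kd = float(locals.get("Kd_surf", 1e-6))
    base = float(locals.get("baseline", 0.0))
    return r_max * f_analyte / (kd + f_analyte) + base


def fit_spr_calibration(
    free_concentrations: np.ndarray, responses: np.ndarray
) -> SprCalibration:
    """Fit the empirical 1:1 Langmuir surface calibration to a direct series."""
    free = np.asarray(free_concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if len(free) < 3:
        raise ValueError("need at least 3 calibration points")
    r0 = max(resp.max() * 1.2, 1e-6)
    k0 = np.median(free[free > 0]) if np.any(free > 0) else 1e-6

    def resid(p):
        r_max, log_kd, base = p
        return r_max * free / (np.exp(log_kd) + free) + base - resp

    sol = least_squares(resid, [r0, np.log(k0), 0.0])
    r_max, log_kd, base = sol.x
    return SprCalibration(
        r_max=float(r_max),
        kd_surface=float(np.exp(log_kd)),
        baseline=float(base),
        free_min=float(free.min()),
        free_max=float(free.max()),
    )


def spr_competition_isotherm(
    model: InteractionModel,
    compositions: Mapping[str, np.ndarray],
    calibration: SprCalibration,
    analyte: str,
    locals: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Competition SPR: solution mixtures deplete the free surface-binding
    partner, which the calibrated surface reads out.

    Free analyte concentrations outside the calibrated range trigger an
    extrapolation warning.
    """
    if calibration is None:
        raise ValueError("surface calibration must be fitted first")
    if analyte not in model.component_names:
        raise ValueError(f"analyte {analyte!r} is not a model component")
    locals = locals or {}
    free, _ = _solve_compositions(model, compositions, locals)
    f_analyte = free[:, model.component_names.index(analyte)]
    if np.any(f_analyte < calibration.free_min * (1 - 1e-9)) or np.any(
        f_analyte > calibration.free_max * (1 + 1e-9)
    ):
        warnings.warn(
            "free analyte concentration outside the calibrated range; "
            "responses are extrapolated",
            stacklevel=2,
        )
    return calibration.response(f_analyte)


# -- AUC ----------------------------------------------------------------------


def sw_isotherm(
    model: InteractionModel,
    compositions: Mapping[str, np.ndarray],
    locals: Mapping[str, float],
) -> np.ndarray:
    """Signal-weighted average sedimentation coefficients s_w (Svedberg).

    s_w = sum_s eps_s c_s s_s / sum_s eps_s c_s over free and complex
    species, with complex signal coefficients additive over components
    (eps_complex = sum_k eps_k * stoichiometry_k).
    """
    free, conc = _solve_compositions(model, compositions, locals)
    comp_eps = np.array(
        [float(locals.get(f"eps.{c}", 0.0)) for c in model.component_names]
    )
    S = model.stoich_matrix()
    sp_eps = S @ comp_eps
    comp_s = np.array([c.s for c in model.components])
    sp_s = np.array([sp.s for sp in model.species])
    numer = free @ (comp_eps * comp_s) + conc @ (sp_eps * sp_s)
    denom = free @ comp_eps + conc @ sp_eps
    if np.any(denom <= 0):
        raise ValueError("total signal is zero at some composition; s_w undefined")
    return numer / denom


# -- fluorescence --------------------------------------------------------------


def anisotropy_isotherm(
    model: InteractionModel,
    compositions: Mapping[str, np.ndarray],
    locals: Mapping[str, float],
    probe: str,
) -> np.ndarray:
    """Steady-state fluorescence anisotropy of a designated probe component.

    Population-weighted average over probe-containing species (equal quantum
    yields by default; per-species yield ratios may be supplied as locals
    ``yield.<species>``).
    """
    if probe not in model.component_names:
        raise ValueError(f"probe {probe!r} is not a model component")
    free, conc = _solve_compositions(model, compositions, locals)
    j = model.component_names.index(probe)
    r_free = float(locals.get("r_free", model.component(probe).anisotropy))
    S = model.stoich_matrix()
    nu_probe = S[:, j]
    yields = np.array(
        [float(locals.get(f"yield.{sp.name}", 1.0)) for sp in model.species]
    )
    w_free = free[:, j]
    w_sp = conc * (nu_probe * yields)[None, :]
    numer = w_free * r_free + w_sp @ np.array([sp.anisotropy for sp in model.species])
    denom = w_free + w_sp.sum(axis=1)
    if np.any(denom <= 0):
        raise ValueError("probe absent at some composition; anisotropy undefined")
    return numer / denom + float(locals.get("baseline", 0.0))


# -- generic linear spectroscopy ----------------------------------------------


def generic_signal_isotherm(
    model: InteractionModel,
    compositions: Mapping[str, np.ndarray],
    locals: Mapping[str, float],
    signal: str,
) -> np.ndarray:
    """Generic linear signal: baseline + sum_s coeff_s * c_s.

    Covers steady-state fluorescence quenching, absorbance (Beer-Lambert with
    coeff = extinction * pathlength), NMR chemical shift isotherms, etc.
    Species without an explicit coefficient inherit the additive sum of their
    components' coefficients.
    """
    free, conc = _solve_compositions(model, compositions, locals)
    comp_coeff = np.array(
        [c.signals.get(signal, 0.0) for c in model.components]
    )
    sp_coeff = model.species_signal_coefficients(signal)
    return (
        free @ comp_coeff + conc @ sp_coeff + float(locals.get("baseline", 0.0))
    )
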