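"""Mass-action equilibrium core.

Defines interaction models (components plus complex species with cumulative
association constants) and solves for free and complex concentrations at any
total composition.  All concentrations are molar; association constants are
stored as log10 of the cumulative association constant beta (dimensionless
against a 1 M standard state); energies are kcal/mol.

The solver works on log free concentrations with damped Newton iteration,
which keeps concentrations positive by construction and is robust over the
~12 orders of magnitude of affinity encountered in practice (picomolar to
millimolar dissociation constants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.987e-3
LN10 = math.log(10.0)

__all__ = [
    "R_KCAL",
    "Component",
    "Species",
    "InteractionModel",
    "SolutionState",
    "ConvergenceError",
    "build_model",
    "solve_free_concentrations",
    "solve_batch",
    "delta_g_from_log10beta",
    "log10beta_from_delta_g",
    "two_site_summary",
]


class ConvergenceError(RuntimeError):
    """Raised when the equilibrium solver cannot satisfy mass balance."""


@dataclass
class Component:
    """A free macromolecular component (implicit species with log10beta = 0)."""

    name: str
    s: float = 0.0  # sedimentation coefficient, Svedberg
    anisotropy: float = 0.0
    signals: dict[str, float] = field(default_factory=dict)


@dataclass
class Species:
    """A complex species defined by an integer stoichiometry over components.

    ``log10beta`` is the cumulative association constant of forming the
    complex from free components; ``dH`` is its molar enthalpy relative to
    the free components (kcal/mol).
    """

    name: str
    stoichiometry: dict[str, int]
    log10beta: float
    dH: float = 0.0
    s: float = 0.0
    anisotropy: float = 0.0
    signals: dict[str, float] = field(default_factory=dict)


@dataclass
class InteractionModel:
    components: list[Component]
    species: list[Species]
    mode: str = "macroscopic"
    temperature: float = 298.15
    #: original microscopic parameterization (log10k, log10alpha), kept for
    #: round-tripping model files written in microscopic mode.
    microscopic: dict | None = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("duplicate component names")
        snames = [s.name for s in self.species]
        if len(set(snames)) != len(snames):
            raise ValueError("duplicate species names")
        if set(snames) & set(names):
            raise ValueError("species name collides with a component name")
        for sp in self.species:
            if not sp.stoichiometry:
                raise ValueError(f"species {sp.name} has empty stoichiometry")
            for comp, nu in sp.stoichiometry.items():
                if comp not in names:
                    raise ValueError(
                        f"species {sp.name} references unknown component {comp!r}"
                    )
                if not float(nu).is_integer() or nu < 0:
                    raise ValueError(
                        f"species {sp.name}: stoichiometry must be non-negative integers"
                    )
            if sum(sp.stoichiometry.values()) < 1:
                raise ValueError(f"species {sp.name} has all-zero stoichiometry")
            if not np.isfinite(sp.log10beta):
                raise ValueError(f"species {sp.name}: log10beta must be finite")

    # -- convenience accessors -------------------------------------------------

    @property
    def component_names(self) -> list[str]:
        return [c.name for c in self.components]

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def component(self, name: str) -> Component:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def get_species(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def stoich_matrix(self) -> np.ndarray:
        """(n_species, n_components) integer stoichiometry matrix."""
        names = self.component_names
        out = np.zeros((len(self.species), len(names)), dtype=float)
        for i, sp in enumerate(self.species):
            for comp, nu in sp.stoichiometry.items():
                out[i, names.index(comp)] = nu
        return out

    def log10betas(self) -> np.ndarray:
        return np.array([s.log10beta for s in self.species], dtype=float)

    def species_signal_coefficients(self, signal: str) -> np.ndarray:
        """Molar signal coefficient per complex species.

        A species with an explicit entry for ``signal`` uses it; otherwise the
        coefficient is additive over its constituent components.
        """
        comp_eps = np.array(
            [c.signals.get(signal, 0.0) for c in self.components], dtype=float
        )
        S = self.stoich_matrix()
        out = S @ comp_eps
        for i, sp in enumerate(self.species):
            if signal in sp.signals:
                out[i] = sp.signals[signal]
        return out


@dataclass
class SolutionState:
    """Free and complex concentrations at one total composition (molar)."""

    totals: dict[str, float]
    free: dict[str, float]
    species_conc: dict[str, float]

    def mass_balance_error(self, model: InteractionModel) -> float:
        """Maximum relative mass-balance violation across components."""
        worst = 0.0
        for j, comp in enumerate(model.component_names):
            tot = self.totals[comp]
            if tot <= 0:
                continue
            acc = self.free[comp]
            for sp in model.species:
                acc += sp.stoichiometry.get(comp, 0) * self.species_conc[sp.name]
            worst = max(worst, abs(acc - tot) / tot)
        return worst


# -- model construction --------------------------------------------------------


def build_model(spec: Mapping) -> InteractionModel:
    """Build and validate an :class:`InteractionModel` from a configuration dict.

    In ``microscopic`` mode the configuration carries per-site parameters
    (``log10k``, ``log10alpha``) for a two-identical-site system A + 2B; the
    stored macroscopic constants then satisfy the statistical-factor identity
    K1 = 2k and K2 = alpha*k/2 exactly.
    """
    mode = spec.get("mode", "macroscopic")
    temperature = float(spec.get("temperature", 298.15))
    components = []
    for c in spec["components"]:
        if isinstance(c, str):
            c = {"name": c}
        components.append(
            Component(
                name=c["name"],
                s=float(c.get("s", 0.0)),
                anisotropy=float(c.get("anisotropy", 0.0)),
                signals={k: float(v) for k, v in (c.get("signals") or {}).items()},
            )
        )
    species = []
    for s in spec["species"]:
        stoich = {}
        for k, v in s["stoichiometry"].items():
            if float(v) != int(v):
                raise ValueError(
                    f"species {s['name']}: stoichiometry for {k} must be an integer"
                )
            stoich[k] = int(v)
        log10beta = s.get("log10beta")
        if "stat_factor" in s and log10beta is not None:
            # user-supplied symmetry factor multiplying beta
            log10beta = float(log10beta) + math.log10(float(s["stat_factor"]))
        species.append(
            Species(
                name=s["name"],
                stoichiometry=stoich,
                log10beta=0.0 if log10beta is None else float(log10beta),
                dH=float(s.get("dH", 0.0)),
                s=float(s.get("s", 0.0)),
                anisotropy=float(s.get("anisotropy", 0.0)),
                signals={k: float(v) for k, v in (s.get("signals") or {}).items()},
            )
        )
    micro = None
    if mode == "microscopic":
        micro_spec = spec.get("microscopic")
        if micro_spec is None:
            raise ValueError("microscopic mode requires a 'microscopic' block")
        log10k = float(micro_spec["log10k"])
        log10alpha = float(micro_spec.get("log10alpha", 0.0))
        _apply_two_site_statistics(species, log10k, log10alpha)
        micro = {"log10k": log10k, "log10alpha": log10alpha}
    model = InteractionModel(
        components=components,
        species=species,
        mode=mode,
        temperature=temperature,
        microscopic=micro,
    )
    return model


def _apply_two_site_statistics(
    species: list[Species], log10k: float, log10alpha: float
) -> None:
    """Set macroscopic log10beta for the A + 2B two-identical-site pattern.

    Macroscopic stepwise constants: K1 = 2k (two ways to bind the first
    ligand), K2 = alpha*k/2 (one way in, two ways out); cumulative constants
    beta1 = 2k and beta2 = K1*K2 = alpha*k^2.
    """
    singly = [
        sp for sp in species if sorted(sp.stoichiometry.values()) == [1, 1]
    ]
    doubly = [
        sp for sp in species if sorted(sp.stoichiometry.values()) == [1, 2]
    ]
    if len(singly) != 1 or len(doubly) != 1:
        raise ValueError(
            "microscopic mode supports the two-identical-site pattern "
            "(one 1:1 and one 1:2 species); use macroscopic mode with "
            "explicit statistical factors for other symmetries"
        )
    singly[0].log10beta = math.log10(2.0) + log10k
    doubly[0].log10beta = log10alpha + 2.0 * log10k


# -- equilibrium solving -------------------------------------------------------


def solve_batch(
    model: InteractionModel,
    totals: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve mass-action equilibrium for a batch of total compositions.

    Parameters
    ----------
    totals : (n_points, n_components) array of molar totals, all >= 0.

    Returns
    -------
    free : (n_points, n_components) free molar concentrations
    conc : (n_points, n_species) complex molar concentrations
    """
    totals = np.atleast_2d(np.asarray(totals, dtype=float))
    if np.any(totals < 0) or not np.all(np.isfinite(totals)):
        raise ValueError("totals must be finite and non-negative")
    n_pts, n_c = totals.shape
    if n_c != len(model.components):
        raise ValueError("totals shape does not match component count")
    S = model.stoich_matrix()
    lnbeta = model.log10betas() * LN10
    free = np.zeros_like(totals)
    conc = np.zeros((n_pts, S.shape[0]))

    present = totals > 0.0
    # group points by which components are absent: species containing an
    # absent component have zero concentration and drop out of the system
    patterns = {}
    for p in range(n_pts):
        patterns.setdefault(present[p].tobytes(), []).append(p)
    for key, idx in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        if not mask.any():
            continue
        active_sp = np.where((S[:, ~mask] == 0).all(axis=1))[0]
        idx = np.asarray(idx)
        f_sub, c_sub = _newton_log_solve(
            S[np.ix_(active_sp, np.where(mask)[0])],
            lnbeta[active_sp],
            totals[np.ix_(idx, np.where(mask)[0])],
            tol,
            max_iter,
        )
        free[np.ix_(idx, np.where(mask)[0])] = f_sub
        conc[np.ix_(idx, active_sp)] = c_sub
    return free, conc


def _newton_log_solve(S, lnbeta, T, tol, max_iter):
    """Damped Newton on x = ln(free) for strictly positive totals T."""
    n_pts, n_c = T.shape
    if S.shape[0] == 0:
        return T.copy(), np.zeros((n_pts, 0))
    x = np.log(T)
    eye = np.eye(n_c)

    def residual(xx):
        c = np.exp(lnbeta[None, :] + xx @ S.T)
        f = np.exp(xx)
        g = (f + c @ S - T) / T
        return g, f, c

    g, f, c = residual(x)
    err = np.abs(g).max(axis=1)
    for _ in range(max_iter):
        if err.max() < tol:
            break
        # J[p, j, k] = d(total_j)/d(x_k) / T_j
        J = np.einsum("ps,sj,sk->pjk", c, S, S)
        J += eye[None, :, :] * f[:, None, :]
        J /= T[:, :, None]
        try:
            step = -np.linalg.solve(J, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError as exc:  # pragma: no cover - J is PD
            raise ConvergenceError("singular Jacobian in equilibrium solve") from exc
        np.clip(step, -6.0, 6.0, out=step)
        lam = np.ones(n_pts)
        for _bt in range(40):
            x_new = x + lam[:, None] * step
            g_new, f_new, c_new = residual(x_new)
            err_new = np.abs(g_new).max(axis=1)
            bad = (err_new > err) & (err >= tol)
            if not bad.any():
                break
            lam[bad] *= 0.5
        x, g, f, c, err = x_new, g_new, f_new, c_new, err_new
    if err.max() >= 1e-9:
        worst = int(np.argmax(err))
        raise ConvergenceError(
            f"equilibrium solver failed: relative mass-balance error "
            f"{err.max():.3e} at totals {T[worst]}"
        )
    return f, c


def solve_free_concentrations(
    model: InteractionModel, totals: Mapping[str, float] | Sequence[float]
) -> SolutionState:
    """Solve for the free and complex concentrations at one composition."""
    if isinstance(totals, Mapping):
        vec = np.array(
            [float(totals.get(c, 0.0)) for c in model.component_names]
        )
    else:
        vec = np.asarray(totals, dtype=float)
    free, conc = solve_batch(model, vec[None, :])
    return SolutionState(
        totals=dict(zip(model.component_names, vec)),
        free=dict(zip(model.component_names, free[0])),
        species_conc=dict(zip(model.species_names, conc[0])),
    )


# -- thermodynamic transforms --------------------------------------------------


def delta_g_from_log10beta(
    log10beta: float | np.ndarray, temperature: float = 298.15
) -> float | np.ndarray:
    """Binding free energy in kcal/mol: dG = -R T ln(10) log10beta."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return -R_KCAL * temperature * LN10 * np.asarray(log10beta, dtype=float) + 0.0


def log10beta_from_delta_g(
    delta_g: float | np.ndarray, temperature: float = 298.15
) -> float | np.ndarray:
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return -np.asarray(delta_g, dtype=float) / (R_KCAL * temperature * LN10) + 0.0


def two_site_summary(
    log10beta1: float, log10beta2: float, temperature: float = 298.15
) -> dict[str, float]:
    """Stepwise constants and cooperativity energies for a two-site system.

    ``log10beta1``/``log10beta2`` are cumulative constants of the 1:1 and 1:2
    complexes.  Cooperativity is reported in both conventions: the raw
    macroscopic difference ddG_macroscopic = dG(step2) - dG(step1), and
    ddG_corrected with the two-identical-site statistical factor 4 removed
    (alpha = 4 K2 / K1, ddG_corrected = -RT ln alpha), which vanishes for
    independent identical sites.
    """
    RT = R_KCAL * temperature
    log10K1 = log10beta1
    log10K2 = log10beta2 - log10beta1
    dG1 = delta_g_from_log10beta(log10K1, temperature)
    dG2 = delta_g_from_log10beta(log10K2, temperature)
    log10alpha = math.log10(4.0) + log10K2 - log10K1
    return {
        "log10K1": log10K1,
        "log10K2": log10K2,
        "K1": 10.0 ** log10K1,
        "K2": 10.0 ** log10K2,
        "Kd1": 10.0 ** -log10K1,
        "Kd2": 10.0 ** -log10K2,
        "dG1": float(dG1),
        "dG2": float(dG2),
        "ddG_macroscopic": float(dG2 - dG1),
        "log10alpha": log10alpha,
        "ddG_corrected": float(-RT * LN10 * log10alpha),
    }
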