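"""Bundled synthetic demonstration suite.

A two-site heteroassociation A + B <-> AB <-> ABB probed by four techniques
in eleven data sets — one SPR competition isotherm, four ITC titrations at
different cell concentrations, five sedimentation-velocity s_w series
(dilution and titration designs) and one fluorescence-anisotropy titration.
The structure mirrors the classic multi-method study layout for a two-site
system; all data are generated in silico with Gaussian noise at ~1% of each
signal's magnitude, deterministically from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import simulate_dataset
from .equilibria import Component, InteractionModel, Species
from .fitting import Experiment, Parameter, ParameterSpace
from .observables import ItcProtocol

__all__ = ["FixtureSuite", "two_site_model", "make_fixture_suite", "write_demo_session"]

#: ground-truth global parameters of the demo system
TRUTH = {
    "species.AB.log10beta": 7.0,   # K1 = 1e7 /M  (Kd1 = 100 nM)
    "species.ABB.log10beta": 13.0, # K1*K2 = 1e13 /M^2 (Kd2 = 1 uM)
    "species.AB.dH": -10.0,        # kcal/mol
    "species.ABB.dH": -16.0,       # cumulative: second step contributes -6
}


def two_site_model() -> InteractionModel:
    """The demo model: A with two non-equivalent sites for B."""
    return InteractionModel(
        components=[
            Component("A", s=3.5, anisotropy=0.05, signals={"abs280": 1.5}),
            Component("B", s=2.0, anisotropy=0.08, signals={"abs280": 1.0}),
        ],
        species=[
            Species("AB", {"A": 1, "B": 1}, log10beta=TRUTH["species.AB.log10beta"],
                    dH=TRUTH["species.AB.dH"], s=4.6, anisotropy=0.18),
            Species("ABB", {"A": 1, "B": 2}, log10beta=TRUTH["species.ABB.log10beta"],
                    dH=TRUTH["species.ABB.dH"], s=5.4, anisotropy=0.22),
        ],
        mode="macroscopic",
    )


@dataclass
class FixtureSuite:
    model: InteractionModel
    experiments: list[Experiment]
    truth: dict[str, float]
    start_parameters: ParameterSpace
    seed: int

    @property
    def technique_tags(self) -> set[str]:
        return {e.technique for e in self.experiments}


def _start_parameters() -> ParameterSpace:
    """Deliberately offset starting values with generous bounds."""
    return ParameterSpace(
        [
            Parameter("species.AB.log10beta", 6.5, fixed=False, lower=4.0, upper=10.0),
            Parameter("species.ABB.log10beta", 12.0, fixed=False, lower=8.0, upper=17.0),
            Parameter("species.AB.dH", -8.0, fixed=False, lower=-30.0, upper=10.0),
            Parameter("species.ABB.dH", -13.0, fixed=False, lower=-40.0, upper=10.0),
        ]
    )


def make_fixture_suite(seed: int = 0, noise: float = 0.01) -> FixtureSuite:
    """Generate the 11-dataset / 4-technique demo suite.

    ``noise`` is the relative noise level: each experiment's per-point sigma
    is ``noise`` times the magnitude of its signal range.  Identical seeds
    give byte-identical suites.
    """
    model = two_site_model()
    sub = np.random.default_rng(seed).integers(0, 2**31 - 1, size=16)
    experiments: list[Experiment] = []

    def _sigma(exp_y: np.ndarray) -> float:
        scale = float(np.max(np.abs(exp_y)))
        return noise * scale if scale > 0 else noise

    def _simulate(technique, plan, locals, meta, sub_seed, name, subgroup, ref_sigma):
        # simulate noise-free first to scale sigma from the clean signal
        clean = simulate_dataset(
            model, technique, plan, locals, 0.0, seed=0, meta=meta, name=name
        )
        sig = ref_sigma if ref_sigma is not None else _sigma(clean.y)
        exp = simulate_dataset(
            model, technique, plan, locals, sig, seed=int(sub_seed),
            meta=meta, name=name, subgroup=subgroup,
        )
        experiments.append(exp)

    # 1 SPR competition isotherm: surface reads free B in A/B mixtures
    a_series = np.concatenate([[0.0], np.logspace(-7.5, -4.5, 11)])
    spr_plan = pd.DataFrame({"A": a_series, "B": np.full(len(a_series), 5e-7)})
    spr_locals = {"Rmax": 120.0, "Kd_surf": 2e-7, "baseline": 2.0}
    _simulate("spr_competition", spr_plan, spr_locals, {"analyte": "B"},
              sub[0], "spr_competition_B", "spr", None)

    # 4 ITC titrations of B into A at different cell concentrations
    for k, a0 in enumerate((2e-6, 5e-6, 1e-5, 2e-5)):
        protocol = ItcProtocol(
            cell_volume=200e-6,
            syringe_concentrations={"A": 0.0, "B": 15.0 * a0},
            initial_cell_concentrations={"A": a0, "B": 0.0},
            injection_volumes=[2e-6] * 20,
        )
        _simulate("itc", protocol, {}, {}, sub[1 + k],
                  f"itc_titration_{k + 1}", "itc", None)

    # 5 SV s_w series: three dilution lines and two titration lines
    sv_locals = {"eps.A": 1.5, "eps.B": 1.0}
    dil = np.logspace(-7.3, -4.7, 10)
    sv_plans = [
        ("sv_dilution_1to1", pd.DataFrame({"A": dil, "B": dil})),
        ("sv_dilution_1to2", pd.DataFrame({"A": dil, "B": 2 * dil})),
        ("sv_dilution_2to1", pd.DataFrame({"A": 2 * dil, "B": dil})),
        ("sv_titration_fixedA", pd.DataFrame(
            {"A": np.full(10, 2e-6), "B": np.logspace(-7.5, -4.3, 10)})),
        ("sv_titration_fixedB", pd.DataFrame(
            {"A": np.logspace(-7.5, -4.3, 10), "B": np.full(10, 2e-6)})),
    ]
    for k, (name, plan) in enumerate(sv_plans):
        _simulate("sv_sw", plan, dict(sv_locals), {}, sub[5 + k],
                  name, "sv", 0.05)

    # 1 fluorescence-anisotropy titration of A into the probe B
    aniso_plan = pd.DataFrame(
        {"A": np.logspace(-8.5, -4.5, 12), "B": np.full(12, 1e-7)}
    )
    _simulate("anisotropy", aniso_plan, {"r_free": 0.08}, {"probe": "B"},
              sub[10], "anisotropy_titration", "anisotropy", 0.002)

    return FixtureSuite(
        model=model,
        experiments=experiments,
        truth=dict(TRUTH),
        start_parameters=_start_parameters(),
        seed=seed,
    )


def write_demo_session(directory: str | Path, seed: int = 0, noise: float = 0.01) -> Path:
    """Write the demo suite as a ready-to-fit session directory; returns the
    session file path."""
    from .io import write_experiment, write_model, write_session

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suite = make_fixture_suite(seed=seed, noise=noise)
    write_model(suite.model, directory / "model.yaml")
    entries = []
    for exp in suite.experiments:
        fname = f"{exp.name}.tsv"
        write_experiment(exp, directory / fname)
        entries.append((fname, exp.weight, exp.subgroup))
    parameters = [
        {
            "name": p.name,
            "value": p.value,
            "fixed": p.fixed,
            "bounds": [p.lower, p.upper],
        }
        for p in suite.start_parameters
    ]
    session = directory / "session.yaml"
    write_session(
        session,
        "model.yaml",
        entries,
        parameters,
        optimizer={"method": "marquardt-levenberg"},
        seed=seed,
    )
    return session
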