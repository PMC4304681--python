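"""Plain-text file formats and session configuration.

All formats are transparent tab-separated or YAML text: concentrations in
molar (plain decimal or scientific notation), one observation per row,
comment/header lines starting with ``#``.  Floats are written with full
``repr`` precision so every file round-trips losslessly.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import DesignMap, TitrationPlan
from .equilibria import InteractionModel, build_model
from .fitting import Experiment, Parameter, ParameterSpace
from .observables import ItcProtocol, SprCalibration

__all__ = [
    "read_model",
    "write_model",
    "read_experiment",
    "write_experiment",
    "SessionConfig",
    "load_session",
    "write_session",
    "map_to_frame",
    "write_map",
    "write_plan",
    "provenance_record",
]


def _fmt(x: float) -> str:
    return repr(float(x))


# -- model configuration -------------------------------------------------------


def model_to_dict(model: InteractionModel) -> dict:
    d: dict = {
        "mode": model.mode,
        "temperature": model.temperature,
        "components": [
            {
                "name": c.name,
                "s": c.s,
                "anisotropy": c.anisotropy,
                "signals": dict(c.signals),
            }
            for c in model.components
        ],
        "species": [
            {
                "name": s.name,
                "stoichiometry": dict(s.stoichiometry),
                "log10beta": s.log10beta,
                "dH": s.dH,
                "s": s.s,
                "anisotropy": s.anisotropy,
                "signals": dict(s.signals),
            }
            for s in model.species
        ],
    }
    if model.microscopic is not None:
        d["microscopic"] = dict(model.microscopic)
    return d


def write_model(model: InteractionModel, path: str | Path) -> None:
    spec = model_to_dict(model)
    if model.mode == "microscopic":
        # stored constants are derived from the microscopic block on read
        for s in spec["species"]:
            if sorted(s["stoichiometry"].values()) in ([1, 1], [1, 2]):
                s.pop("log10beta")
    Path(path).write_text(yaml.safe_dump(spec, sort_keys=False))


def read_model(path: str | Path) -> InteractionModel:
    return build_model(yaml.safe_load(Path(path).read_text()))


# -- experiment files ----------------------------------------------------------


def write_experiment(exp: Experiment, path: str | Path) -> None:
    buf = _io.StringIO()
    buf.write("# gmma-experiment v1\n")
    buf.write(f"# technique: {exp.technique}\n")
    if exp.name:
        buf.write(f"# name: {exp.name}\n")
    buf.write(f"# weight: {_fmt(exp.weight)}\n")
    if exp.subgroup is not None:
        buf.write(f"# subgroup: {exp.subgroup}\n")
    buf.write("# units: M\n")
    if exp.meta:
        buf.write("# meta: " + json.dumps(exp.meta) + "\n")
    if exp.locals:
        buf.write(
            "# locals: "
            + json.dumps({k: float(v) for k, v in exp.locals.items()})
            + "\n"
        )
    if exp.calibration is not None:
        cal = exp.calibration
        buf.write(
            "# calibration: "
            + json.dumps(
                {
                    "r_max": cal.r_max,
                    "kd_surface": cal.kd_surface,
                    "baseline": cal.baseline,
                    "free_min": cal.free_min,
                    "free_max": None if np.isinf(cal.free_max) else cal.free_max,
                }
            )
            + "\n"
        )
    if exp.protocol is not None:
        p = exp.protocol
        buf.write(
            "# protocol: "
            + json.dumps(
                {
                    "cell_volume": p.cell_volume,
                    "syringe_concentrations": p.syringe_concentrations,
                    "initial_cell_concentrations": p.initial_cell_concentrations,
                    "temperature": p.temperature,
                    "injectant": p.injectant,
                }
            )
            + "\n"
        )
    cols = list(exp.data.columns) + ["y", "sigma"]
    buf.write("\t".join(cols) + "\n")
    for i in range(len(exp.y)):
        row = [_fmt(exp.data[c].iloc[i]) for c in exp.data.columns]
        row += [_fmt(exp.y[i]), _fmt(exp.sigma[i])]
        buf.write("\t".join(row) + "\n")
    Path(path).write_text(buf.getvalue())


def read_experiment(path: str | Path) -> Experiment:
    path = Path(path)
    header: dict = {}
    rows: list[list[str]] = []
    columns: list[str] | None = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                header[key.strip()] = val.strip()
            continue
        if columns is None:
            columns = line.split("\t")
        else:
            rows.append(line.split("\t"))
    if columns is None:
        raise ValueError(f"{path}: no column header found")
    if "technique" not in header:
        raise ValueError(f"{path}: header must name the technique")
    units = header.get("units", "M")
    if units not in ("M", "molar"):
        raise ValueError(f"{path}: only molar concentration units are supported")
    if "sigma" not in columns:
        raise ValueError(f"{path}: required column 'sigma' is missing")
    if "y" not in columns:
        raise ValueError(f"{path}: required column 'y' is missing")
    try:
        table = pd.DataFrame(
            np.array([[float(v) for v in r] for r in rows]), columns=columns
        )
    except ValueError as exc:
        raise ValueError(f"{path}: malformed number in data table") from exc

    def _json(key, default):
        return json.loads(header[key]) if key in header else default

    protocol = None
    if "protocol" in header:
        p = json.loads(header["protocol"])
        protocol = ItcProtocol(
            cell_volume=p["cell_volume"],
            syringe_concentrations=p["syringe_concentrations"],
            initial_cell_concentrations=p["initial_cell_concentrations"],
            injection_volumes=table["injection_volume"].to_numpy(),
            temperature=p.get("temperature", 298.15),
            injectant=p.get("injectant"),
        )
    calibration = None
    if "calibration" in header:
        c = json.loads(header["calibration"])
        calibration = SprCalibration(
            r_max=c["r_max"],
            kd_surface=c["kd_surface"],
            baseline=c.get("baseline", 0.0),
            free_min=c.get("free_min", 0.0),
            free_max=np.inf if c.get("free_max") is None else c["free_max"],
        )
    data = table[[c for c in columns if c not in ("y", "sigma")]]
    return Experiment(
        technique=header["technique"],
        data=data,
        y=table["y"].to_numpy(),
        sigma=table["sigma"].to_numpy(),
        weight=float(header.get("weight", 1.0)),
        locals=_json("locals", {}),
        meta=_json("meta", {}),
        protocol=protocol,
        calibration=calibration,
        subgroup=header.get("subgroup"),
        name=header.get("name", path.stem),
    )


# -- fit sessions --------------------------------------------------------------


@dataclass
class SessionConfig:
    """A fit session: model file, experiment entries, parameter table,
    optimizer settings.  Paths are relative to the session file."""

    model_path: Path
    experiment_entries: list[dict]
    parameters: list[dict] = field(default_factory=list)
    optimizer: dict = field(default_factory=dict)
    output: str | None = None
    seed: int | None = None
    root: Path = Path(".")


def write_session(
    path: str | Path,
    model_file: str,
    experiments: Sequence[tuple[str, float, str | None]],
    parameters: Sequence[Mapping],
    optimizer: Mapping | None = None,
    seed: int | None = None,
) -> None:
    doc = {
        "model": model_file,
        "experiments": [
            {"file": f, "weight": w, **({"subgroup": g} if g else {})}
            for f, w, g in experiments
        ],
        "parameters": [dict(p) for p in parameters],
        "optimizer": dict(optimizer or {"method": "marquardt-levenberg"}),
    }
    if seed is not None:
        doc["seed"] = int(seed)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_session(
    path: str | Path,
) -> tuple[InteractionModel, list[Experiment], ParameterSpace, SessionConfig]:
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    root = path.parent
    model_path = root / doc["model"]
    if not model_path.exists():
        raise FileNotFoundError(f"model file {model_path} does not exist")
    model = read_model(model_path)
    experiments = []
    entries = []
    for entry in doc.get("experiments", []):
        epath = root / entry["file"]
        if not epath.exists():
            raise FileNotFoundError(f"experiment file {epath} does not exist")
        exp = read_experiment(epath)
        w = float(entry.get("weight", exp.weight))
        if w < 0:
            raise ValueError("experiment weight must be non-negative")
        exp.weight = w
        if "subgroup" in entry:
            exp.subgroup = entry["subgroup"]
        experiments.append(exp)
        entries.append(dict(entry))
    params = ParameterSpace()
    for p in doc.get("parameters", []):
        bounds = p.get("bounds")
        params.add(
            Parameter(
                name=p["name"],
                value=float(p["value"]),
                fixed=bool(p.get("fixed", False)),
                lower=-np.inf if bounds is None else float(bounds[0]),
                upper=np.inf if bounds is None else float(bounds[1]),
                link=p.get("link"),
            )
        )
    cfg = SessionConfig(
        model_path=model_path,
        experiment_entries=entries,
        parameters=doc.get("parameters", []),
        optimizer=doc.get("optimizer", {}),
        output=doc.get("output"),
        seed=doc.get("seed"),
        root=root,
    )
    return model, experiments, params, cfg


# -- tabular exports -----------------------------------------------------------


def map_to_frame(dmap: DesignMap) -> pd.DataFrame:
    """Tidy long-form table of a design map (one row per node)."""
    gx, gy = dmap.axes.grids()
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    out = {
        f"total_{dmap.axes.comp_x}": X.ravel(),
        f"total_{dmap.axes.comp_y}": Y.ravel(),
        "feasible": dmap.mask.ravel().astype(int),
    }
    if dmap.values is not None:
        out["value"] = dmap.values.ravel()
    if dmap.fractions is not None:
        for name, mat in dmap.fractions.items():
            out[f"fraction_{name}"] = mat.ravel()
    return pd.DataFrame(out)


def write_map(dmap: DesignMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# gmma-design-map mode={dmap.mode} technique={dmap.technique}\n")
        map_to_frame(dmap).to_csv(fh, sep="\t", index=False)


def write_plan(plan: TitrationPlan, path: str | Path) -> None:
    table = pd.concat(
        [plan.compositions.add_prefix("total_"), plan.recipes], axis=1
    )
    with open(path, "w") as fh:
        fh.write(f"# gmma-titration-plan total_volume={_fmt(plan.total_volume)}\n")
        fh.write("# stocks: " + json.dumps(plan.stocks) + "\n")
        table.to_csv(fh, sep="\t", index=False)


# -- provenance ----------------------------------------------------------------


def provenance_record(
    config_path: str | Path | None,
    seed: int | None,
    inputs: Sequence[str | Path] = (),
) -> dict:
    """Machine-readable record sufficient to reproduce a run exactly."""
    from . import __version__

    def _sha(p):
        return hashlib.sha256(Path(p).read_bytes()).hexdigest()

    return {
        "gmma_version": __version__,
        "seed": seed,
        "config": None
        if config_path is None
        else {"path": str(config_path), "sha256": _sha(config_path)},
        "inputs": {str(p): _sha(p) for p in inputs},
    }
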