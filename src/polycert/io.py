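"""Readers/writers: model configs (YAML), measurement/input CSVs, result JSON.

Model config schema (YAML):

.. code-block:: yaml

    name: mm
    species: [S, C, E]
    parameters: [p1, p2, p3]
    inputs: []                      # optional
    constants: {C0: 0.33}           # optional, referenced by name below
    reactions:
      - reactants: {E: 1, S: 1}
        products: {C: 1}
        forward: p1
        reverse: p2                 # optional
        prefactor: {"1": C0mi, X4: -1.0}   # optional affine factor
        input: u                    # optional input multiplier
    substitutions:                  # optional moiety eliminations
      E: {"1": 1.0, C: -1.0}
    h: 0.1
    param_box: {p1: [0.0, 2.0], ...}
    state_box: {S: [0.0, 1.0], ...}
    reference:                      # optional reference setup
      parameters: {p1: 1.0, ...}
      x0: {S: 0.999, C: 0.001}
      inputs: {u: 1.0}
      horizon: 20

Measurement CSV columns: ``time_index, observable, lower, upper``.
Input CSV columns: ``time_index, input, lower, upper``.
Time indexes are 0-based integers; units are fixed by the model config
(concentrations in μM, time in seconds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from .model import Reaction, ReactionNetwork
from .poly import Interval, Polynomial, RationalExpression
from .sets import Box, InputSequence, MeasurementSequence


@dataclass
class ReferenceSetup:
    """Ground-truth simulation setup for generating synthetic data."""

    parameters: Dict[str, float]
    x0: Dict[str, float]
    horizon: int
    inputs: Dict[str, float] = field(default_factory=dict)


@dataclass
class ModelConfig:
    name: str
    network: ReactionNetwork
    h: float
    param_box: Box
    state_box: Box
    constants: Dict[str, float] = field(default_factory=dict)
    reference: Optional[ReferenceSetup] = None


class ConfigError(ValueError):
    pass


def _resolve(value, constants: Dict[str, float], where: str) -> float:
    if isinstance(value, str):
        if value not in constants:
            raise ConfigError(f"{where}: unknown constant '{value}'")
        return float(constants[value])
    return float(value)


def _affine(d: dict, constants: Dict[str, float], where: str
            ) -> Dict[str, float]:
    return {str(k): _resolve(v, constants, f"{where}.{k}")
            for k, v in d.items()}


def _box(d: dict, where: str) -> Box:
    out = {}
    for name, pair in d.items():
        if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
            raise ConfigError(f"{where}.{name}: expected [lower, upper]")
        out[str(name)] = Interval(float(pair[0]), float(pair[1]))
    return Box(out)


def parse_model_config(doc: dict) -> ModelConfig:
    try:
        name = str(doc.get("name", "model"))
        species = [str(s) for s in doc["species"]]
        parameters = [str(p) for p in doc["parameters"]]
        inputs = [str(u) for u in doc.get("inputs", [])]
        constants = {str(k): float(v)
                     for k, v in doc.get("constants", {}).items()}
        substitutions = {
            str(sp): _affine(aff, constants, f"substitutions.{sp}")
            for sp, aff in doc.get("substitutions", {}).items()}

        reactions: List[Reaction] = []
        states_guess = tuple(s for s in species if s not in substitutions)
        pf_vars = states_guess + tuple(parameters) + tuple(inputs)
        for i, r in enumerate(doc["reactions"]):
            prefactor = None
            if "prefactor" in r:
                aff = _affine(r["prefactor"], constants,
                              f"reactions[{i}].prefactor")
                num = Polynomial.zero(pf_vars)
                for k, v in aff.items():
                    if k == "1":
                        num = num + v
                    else:
                        num = num + Polynomial.variable(pf_vars, k) * v
                prefactor = RationalExpression.from_polynomial(num)
            reactions.append(Reaction(
                reactants={str(k): int(v)
                           for k, v in (r.get("reactants") or {}).items()},
                products={str(k): int(v)
                          for k, v in (r.get("products") or {}).items()},
                forward=str(r["forward"]),
                reverse=(str(r["reverse"]) if r.get("reverse") else None),
                prefactor=prefactor,
                input_multiplier=(str(r["input"]) if r.get("input")
                                  else None),
                name=str(r.get("name", f"R{i}"))))

        network = ReactionNetwork(
            species=tuple(species), reactions=reactions,
            parameters=tuple(parameters), inputs=tuple(inputs),
            substitutions=substitutions, name=name)

        param_box = _box(doc["param_box"], "param_box")
        state_box = _box(doc["state_box"], "state_box")
        reference = None
        if "reference" in doc:
            ref = doc["reference"]
            reference = ReferenceSetup(
                parameters={str(k): float(v)
                            for k, v in ref["parameters"].items()},
                x0={str(k): float(v) for k, v in ref["x0"].items()},
                horizon=int(ref["horizon"]),
                inputs={str(k): float(v)
                        for k, v in ref.get("inputs", {}).items()})
        return ModelConfig(name=name, network=network,
                           h=float(doc["h"]), param_box=param_box,
                           state_box=state_box, constants=constants,
                           reference=reference)
    except KeyError as exc:
        raise ConfigError(f"missing config field {exc}") from exc


def load_model_config(path: "str | Path") -> ModelConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: not a mapping")
    return parse_model_config(doc)


def model_config_to_dict(cfg: ModelConfig) -> dict:
    doc: dict = {
        "name": cfg.name,
        "species": list(cfg.network.species),
        "parameters": list(cfg.network.parameters),
    }
    if cfg.network.inputs:
        doc["inputs"] = list(cfg.network.inputs)
    if cfg.constants:
        doc["constants"] = dict(cfg.constants)
    doc["reactions"] = []
    for r in cfg.network.reactions:
        rd: dict = {"reactants": dict(r.reactants),
                    "products": dict(r.products),
                    "forward": r.forward}
        if r.reverse:
            rd["reverse"] = r.reverse
        if r.input_multiplier:
            rd["input"] = r.input_multiplier
        if r.prefactor is not None:
            aff = {}
            num = r.prefactor.numerator
            for exps, coeff in num.terms.items():
                deg = sum(exps)
                if deg == 0:
                    aff["1"] = coeff
                elif deg == 1:
                    aff[num.variables[exps.index(1)]] = coeff
                else:
                    raise ConfigError("only affine prefactors round-trip")
            rd["prefactor"] = aff
        if r.name:
            rd["name"] = r.name
        doc["reactions"].append(rd)
    if cfg.network.substitutions:
        doc["substitutions"] = {sp: dict(aff) for sp, aff
                                in cfg.network.substitutions.items()}
    doc["h"] = cfg.h
    doc["param_box"] = {v: [iv.lower, iv.upper]
                        for v, iv in cfg.param_box.bounds.items()}
    doc["state_box"] = {v: [iv.lower, iv.upper]
                        for v, iv in cfg.state_box.bounds.items()}
    if cfg.reference is not None:
        doc["reference"] = {
            "parameters": dict(cfg.reference.parameters),
            "x0": dict(cfg.reference.x0),
            "horizon": cfg.reference.horizon,
        }
        if cfg.reference.inputs:
            doc["reference"]["inputs"] = dict(cfg.reference.inputs)
    return doc


def save_model_config(cfg: ModelConfig, path: "str | Path") -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_config_to_dict(cfg), fh, sort_keys=False)


# -- measurement / input CSV ------------------------------------------


def load_measurements(path: "str | Path") -> MeasurementSequence:
    df = pd.read_csv(path)
    required = {"time_index", "observable", "lower", "upper"}
    if not required.issubset(df.columns):
        raise ConfigError(
            f"{path}: measurement CSV needs columns {sorted(required)}")
    if len(df) == 0:
        raise ConfigError(f"{path}: no measurements")
    sets: Dict[int, Dict[str, Interval]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        lo, hi = float(row.lower), float(row.upper)
        if lo > hi:
            raise ConfigError(
                f"{path}: row {row_no}: lower {lo} > upper {hi}")
        sets.setdefault(int(row.time_index), {})[str(row.observable)] = \
            Interval(lo, hi)
    return MeasurementSequence(sets)


def save_measurements(data: MeasurementSequence, path: "str | Path") -> None:
    rows = []
    for k in data.indexes:
        mset = data.sets[k]
        if not isinstance(mset, dict):
            raise ConfigError("only interval measurements export to CSV")
        for obs, iv in mset.items():
            rows.append({"time_index": k, "observable": obs,
                         "lower": iv.lower, "upper": iv.upper})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_inputs(path: "str | Path") -> InputSequence:
    df = pd.read_csv(path)
    required = {"time_index", "input", "lower", "upper"}
    if not required.issubset(df.columns):
        raise ConfigError(
            f"{path}: input CSV needs columns {sorted(required)}")
    sets: Dict[int, Dict[str, Interval]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        lo, hi = float(row.lower), float(row.upper)
        if lo > hi:
            raise ConfigError(f"{path}: row {row_no}: lower > upper")
        sets.setdefault(int(row.time_index), {})[str(row.input)] = \
            Interval(lo, hi)
    return InputSequence(sets=sets)


# -- result JSON -------------------------------------------------------


def approximation_to_dict(approx, model_id: str = "") -> dict:
    from .bisection import OuterApproximation, project_bounds
    assert isinstance(approx, OuterApproximation)
    bounds = project_bounds(approx)
    names = list(approx.initial_box.variables)
    return {
        "model_id": model_id or str(approx.provenance.get("model", "")),
        "eps": approx.eps,
        "initial_box": {v: [approx.initial_box[v].lower,
                            approx.initial_box[v].upper] for v in names},
        "kept": [{"lower": [kb.box[v].lower for v in names],
                  "upper": [kb.box[v].upper for v in names],
                  "status": kb.status} for kb in approx.kept],
        "discarded_count": len(approx.discarded),
        "sdp_solves": approx.sdp_solves,
        "per_parameter_bounds": (
            {v: [iv.lower, iv.upper] for v, iv in bounds.items()}
            if bounds is not None else None),
        "invalidated": approx.invalidated,
        "budget_exhausted": approx.budget_exhausted,
    }


def save_result_json(result: dict, path: "str | Path") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=False)
        fh.write("\n")
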