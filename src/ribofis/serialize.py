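"""Lossless YAML/JSON serialisation of fuzzy models and variable catalogs.

Documents are plain mappings so they stay hand-editable; the file suffix
selects the format (``.json`` → JSON, anything else → YAML). ``load ∘ save``
is the identity on models and catalogs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import yaml

from .errors import FuzzyDefinitionError
from .fuzzy import (
    FuzzyVariable,
    LinguisticTerm,
    MamdaniModel,
    Operators,
    Rule,
    TriangularMF,
)

MODEL_KIND = "mamdani_model"

__all__ = [
    "variable_to_dict",
    "variable_from_dict",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]


def variable_to_dict(var: FuzzyVariable) -> dict:
    return {
        "name": var.name,
        "universe": [var.universe[0], var.universe[1]],
        "terms": [
            {"label": t.label, "mf": [t.mf.a, t.mf.b, t.mf.c]} for t in var.terms
        ],
    }


def variable_from_dict(d: dict) -> FuzzyVariable:
    terms = tuple(
        LinguisticTerm(label=t["label"], mf=TriangularMF(*map(float, t["mf"])))
        for t in d["terms"]
    )
    return FuzzyVariable(name=d["name"], universe=tuple(d["universe"]), terms=terms)


def model_to_dict(model: MamdaniModel) -> dict:
    return {
        "kind": MODEL_KIND,
        "operators": {
            "and": model.operators.and_op,
            "implication": model.operators.implication,
            "aggregation": model.operators.aggregation,
            "defuzzifier": model.operators.defuzzifier,
        },
        "grid_points": model.grid_points,
        "inputs": [variable_to_dict(v) for v in model.inputs],
        "output": variable_to_dict(model.output),
        "rules": [
            {"if": dict(r.antecedent), "then": r.consequent, "weight": r.weight}
            for r in model.rules
        ],
    }


def model_from_dict(d: dict) -> MamdaniModel:
    if d.get("kind") != MODEL_KIND:
        raise FuzzyDefinitionError(
            f"not a {MODEL_KIND} document (kind={d.get('kind')!r})"
        )
    ops = d.get("operators", {})
    operators = Operators(
        and_op=ops.get("and", "min"),
        implication=ops.get("implication", "min"),
        aggregation=ops.get("aggregation", "max"),
        defuzzifier=ops.get("defuzzifier", "centroid"),
    )
    rules = tuple(
        Rule(
            antecedent=dict(r["if"]),
            consequent=r["then"],
            weight=float(r.get("weight", 1.0)),
        )
        for r in d.get("rules", [])
    )
    return MamdaniModel(
        inputs=tuple(variable_from_dict(v) for v in d["inputs"]),
        output=variable_from_dict(d["output"]),
        rules=rules,
        operators=operators,
        grid_points=int(d.get("grid_points", 1001)),
    )


def _dump(doc: dict, path: Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def _load(path: Path) -> dict:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_model(model: MamdaniModel, path) -> None:
    _dump(model_to_dict(model), Path(path))


def load_model(path) -> MamdaniModel:
    return model_from_dict(_load(Path(path)))
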