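"""The concrete riboflavin-production fuzzy variables and model builders.

Four medium components of the semi-defined medium (SDM) drive the model:

====================  =================  =======================
variable              universe           low / medium / high peak
====================  =================  =======================
casamino acid         5–20 g/L           5 / 12.5 / 20
GTP                   0.01–0.04 g/L      0.01 / 0.025 / 0.04
sodium acetate        5–15 g/L           5 / 10 / 15
glycine               5–15 g/L           5 / 10 / 15
riboflavin (output)   340–440 µg/L       340 / 390 / 440
====================  =================  =======================

Each variable carries three triangular terms built on the peak-anchored
pattern low = (p1, p1, p2), medium = (p1, p2, p3), high = (p2, p3, p3):
the extreme terms are degenerate shoulders sitting on the universe edges,
which makes the three memberships a partition of unity (they sum to one
everywhere on the universe).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import FuzzyDefinitionError
from .fuzzy import FuzzyVariable, LinguisticTerm, MamdaniModel, Rule, TriangularMF

CASAMINO = "casamino"
GTP = "gtp"
SODIUM_ACETATE = "sodium_acetate"
GLYCINE = "glycine"
RIBOFLAVIN = "riboflavin"

#: The four medium-component inputs, in pipeline order.
FACTORS: tuple[str, ...] = (CASAMINO, GTP, SODIUM_ACETATE, GLYCINE)

TERM_LABELS: tuple[str, ...] = ("low", "medium", "high")

#: low / medium / high membership peaks per variable (g/L; µg/L for output).
PEAKS: dict[str, tuple[float, float, float]] = {
    CASAMINO: (5.0, 12.5, 20.0),
    GTP: (0.01, 0.025, 0.04),
    SODIUM_ACETATE: (5.0, 10.0, 15.0),
    GLYCINE: (5.0, 10.0, 15.0),
    RIBOFLAVIN: (340.0, 390.0, 440.0),
}

__all__ = [
    "CASAMINO",
    "GTP",
    "SODIUM_ACETATE",
    "GLYCINE",
    "RIBOFLAVIN",
    "FACTORS",
    "TERM_LABELS",
    "PEAKS",
    "VariableCatalog",
    "three_term_variable",
    "build_variables",
    "build_single_factor_model",
    "build_joint_model",
    "baseline_levels",
]


def three_term_variable(name: str, peaks: Sequence[float]) -> FuzzyVariable:
    """Low/medium/high variable with shoulder terms anchored at ``peaks``.

    The universe is [peaks[0], peaks[2]] and the terms partition unity.
    """
    p1, p2, p3 = (float(p) for p in peaks)
    terms = (
        LinguisticTerm("low", TriangularMF(p1, p1, p2)),
        LinguisticTerm("medium", TriangularMF(p1, p2, p3)),
        LinguisticTerm("high", TriangularMF(p2, p3, p3)),
    )
    return FuzzyVariable(name=name, universe=(p1, p3), terms=terms)


@dataclass(frozen=True)
class VariableCatalog:
    """The five model variables: four medium-component inputs plus the output."""

    casamino: FuzzyVariable
    gtp: FuzzyVariable
    sodium_acetate: FuzzyVariable
    glycine: FuzzyVariable
    riboflavin: FuzzyVariable

    def __getitem__(self, name: str) -> FuzzyVariable:
        if name in FACTORS + (RIBOFLAVIN,):
            return getattr(self, name)
        raise FuzzyDefinitionError(f"unknown variable '{name}'")

    @property
    def inputs(self) -> tuple[FuzzyVariable, ...]:
        return (self.casamino, self.gtp, self.sodium_acetate, self.glycine)

    @property
    def variables(self) -> tuple[FuzzyVariable, ...]:
        return self.inputs + (self.riboflavin,)


def load_bundled_catalog() -> VariableCatalog:
    """Load the catalog from the YAML fixture shipped with the package.

    Equal to :func:`build_variables`; exists so the model definition is also
    available as a hand-editable structured text document.
    """
    from importlib import resources

    import yaml

    from .serialize import variable_from_dict

    doc = yaml.safe_load(
        resources.files("ribofis.data")
        .joinpath("riboflavin_catalog.yaml")
        .read_text(encoding="utf-8")
    )
    if doc.get("kind") != "variable_catalog":
        raise FuzzyDefinitionError("bundled catalog file is not a variable_catalog document")
    variables = {v["name"]: variable_from_dict(v) for v in doc["variables"]}
    return VariableCatalog(
        casamino=variables[CASAMINO],
        gtp=variables[GTP],
        sodium_acetate=variables[SODIUM_ACETATE],
        glycine=variables[GLYCINE],
        riboflavin=variables[RIBOFLAVIN],
    )


def build_variables() -> VariableCatalog:
    """Construct the catalog of riboflavin-model variables (table above)."""
    return VariableCatalog(
        **{name: three_term_variable(name, PEAKS[name]) for name in FACTORS},
        riboflavin=three_term_variable(RIBOFLAVIN, PEAKS[RIBOFLAVIN]),
    )


def baseline_levels(catalog: VariableCatalog | None = None) -> dict[str, float]:
    """Held-fixed level of each factor in an OFAT run: its low-term peak.

    These coincide with the unsupplemented SDM baseline (e.g. sodium acetate
    5 g/L in the base recipe).
    """
    catalog = catalog or build_variables()
    return {v.name: v.terms[0].mf.b for v in catalog.inputs}


def _as_rules(rules) -> tuple[Rule, ...]:
    rules = tuple(getattr(rules, "rules", rules))
    if not rules:
        raise FuzzyDefinitionError("empty rule base")
    return rules


def build_single_factor_model(
    factor: str,
    rules,
    *,
    catalog: VariableCatalog | None = None,
    grid_points: int = 1001,
) -> MamdaniModel:
    """Single-input Mamdani model predicting riboflavin from one factor.

    ``rules`` is a sequence of :class:`~ribofis.fuzzy.Rule` (or anything with
    a ``.rules`` attribute, e.g. an induced rule base) whose antecedents may
    reference only ``factor``.
    """
    if factor not in FACTORS:
        raise FuzzyDefinitionError(f"unknown factor '{factor}'; expected one of {FACTORS}")
    catalog = catalog or build_variables()
    rules = _as_rules(rules)
    for rule in rules:
        extra = set(rule.antecedent) - {factor}
        if extra:
            raise FuzzyDefinitionError(
                f"single-factor model for '{factor}' got rule referencing {sorted(extra)}"
            )
    return MamdaniModel(
        inputs=(catalog[factor],),
        output=catalog.riboflavin,
        rules=rules,
        grid_points=grid_points,
    )


def build_joint_model(
    rules,
    *,
    catalog: VariableCatalog | None = None,
    grid_points: int = 1001,
) -> MamdaniModel:
    """Four-input Mamdani model; rules may reference any subset of factors.

    Fixing three factors at their baseline (low-peak) levels recovers the
    corresponding single-factor model's predictions exactly, because rules
    not referencing a variable are unaffected by its value.
    """
    catalog = catalog or build_variables()
    return MamdaniModel(
        inputs=catalog.inputs,
        output=catalog.riboflavin,
        rules=_as_rules(rules),
        grid_points=grid_points,
    )
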