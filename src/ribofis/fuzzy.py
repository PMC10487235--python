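"""Generic Mamdani fuzzy-inference engine on triangular membership functions.

The engine implements the classical Mamdani pipeline:

1. *fuzzification* — a crisp input is mapped to a degree of membership in
   each linguistic term of its variable;
2. *rule firing* — the AND of a rule's antecedent clauses is taken as the
   minimum of the clause memberships, scaled by the rule weight;
3. *implication* — each rule's consequent fuzzy set is clipped (min) at the
   rule's firing strength;
4. *aggregation* — clipped consequents are combined pointwise with max on a
   uniform grid over the output universe;
5. *defuzzification* — the aggregated surface is collapsed to a crisp value
   by its discrete centroid.

Only the classical operator triple (min AND, min implication, max
aggregation) and the centroid defuzzifier are supported; the
:class:`Operators` record exists so alternatives could be added without
changing the model contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    FuzzyDefinitionError,
    MissingInputError,
    NoRuleFiredError,
    OutOfRangeError,
)

__all__ = [
    "TriangularMF",
    "LinguisticTerm",
    "FuzzyVariable",
    "Rule",
    "Operators",
    "AggregatedOutput",
    "MamdaniModel",
    "membership",
    "fuzzify",
    "firing_strength",
    "infer",
    "defuzzify_centroid",
    "predict",
]


@dataclass(frozen=True)
class TriangularMF:
    """Triangular membership function with feet ``a``, ``c`` and peak ``b``.

    Degenerate shoulders are legal: ``a == b`` yields a left shoulder whose
    rising edge collapses to degree 1 at the peak, and ``b == c`` the
    mirror-image right shoulder. Zero-width triangles (``a == c``) are
    rejected at construction.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c):
            raise FuzzyDefinitionError(
                f"triangular MF requires a <= b <= c, got ({self.a}, {self.b}, {self.c})"
            )
        if not self.a < self.c:
            raise FuzzyDefinitionError(
                f"zero-width membership function: a == c == {self.a}"
            )

    @property
    def support(self) -> tuple[float, float]:
        return (self.a, self.c)

    def __call__(self, x):
        """Membership degree of ``x`` (scalar or array) in [0, 1]."""
        xs = np.asarray(x, dtype=float)
        with np.errstate(over="ignore"):
            left = (xs - self.a) / (self.b - self.a) if self.b > self.a else np.ones_like(xs)
            right = (self.c - xs) / (self.c - self.b) if self.c > self.b else np.ones_like(xs)
        deg = np.clip(np.minimum(left, right), 0.0, 1.0)
        deg = np.where((xs < self.a) | (xs > self.c), 0.0, deg)
        if np.ndim(x) == 0:
            return float(deg)
        return deg


def membership(mf: TriangularMF, x):
    """Degree of membership of ``x`` under ``mf`` (total on the real line)."""
    return mf(x)


@dataclass(frozen=True)
class LinguisticTerm:
    """A named fuzzy set (e.g. ``low``) attached to a variable."""

    label: str
    mf: TriangularMF


@dataclass(frozen=True)
class FuzzyVariable:
    """A named input or output with a universe of discourse and ordered terms.

    Invariants enforced at construction: the universe is a proper interval,
    term labels are unique, term peaks strictly increase with term order,
    every term's support lies inside the universe, and the terms jointly
    cover the universe (every point has positive membership somewhere).
    """

    name: str
    universe: tuple[float, float]
    terms: tuple[LinguisticTerm, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "universe", (float(self.universe[0]), float(self.universe[1])))
        object.__setattr__(self, "terms", tuple(self.terms))
        umin, umax = self.universe
        if not umin < umax:
            raise FuzzyDefinitionError(f"variable '{self.name}': empty universe [{umin}, {umax}]")
        if not self.terms:
            raise FuzzyDefinitionError(f"variable '{self.name}': needs at least one term")
        labels = [t.label for t in self.terms]
        if len(set(labels)) != len(labels):
            raise FuzzyDefinitionError(f"variable '{self.name}': duplicate term labels {labels}")
        peaks = [t.mf.b for t in self.terms]
        if any(p2 <= p1 for p1, p2 in zip(peaks, peaks[1:])):
            raise FuzzyDefinitionError(
                f"variable '{self.name}': term peaks must strictly increase, got {peaks}"
            )
        for t in self.terms:
            if t.mf.a < umin or t.mf.c > umax:
                raise FuzzyDefinitionError(
                    f"variable '{self.name}': term '{t.label}' support {t.mf.support} "
                    f"outside universe [{umin}, {umax}]"
                )
        # Coverage: positive membership at both ends, and consecutive supports
        # must properly overlap so no interior gap can open up.
        if self.terms[0].mf(umin) <= 0.0:
            raise FuzzyDefinitionError(f"variable '{self.name}': universe minimum uncovered")
        if self.terms[-1].mf(umax) <= 0.0:
            raise FuzzyDefinitionError(f"variable '{self.name}': universe maximum uncovered")
        for t1, t2 in zip(self.terms, self.terms[1:]):
            if t2.mf.a >= t1.mf.c:
                raise FuzzyDefinitionError(
                    f"variable '{self.name}': gap between terms '{t1.label}' and '{t2.label}'"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.terms)

    def term(self, label: str) -> LinguisticTerm:
        for t in self.terms:
            if t.label == label:
                return t
        raise FuzzyDefinitionError(f"variable '{self.name}' has no term '{label}'")

    def contains(self, x: float) -> bool:
        return self.universe[0] <= x <= self.universe[1]

    def assert_in_range(self, x: float) -> None:
        if not self.contains(x):
            raise OutOfRangeError(
                f"value {x} outside universe [{self.universe[0]}, {self.universe[1]}] "
                f"of variable '{self.name}'"
            )

    def fuzzify(self, x: float) -> np.ndarray:
        """Vector of term memberships at crisp ``x`` (must lie in the universe)."""
        self.assert_in_range(x)
        return np.array([t.mf(x) for t in self.terms])


def fuzzify(variable: FuzzyVariable, x: float) -> np.ndarray:
    return variable.fuzzify(x)


@dataclass
class Rule:
    """IF–THEN rule: antecedent term labels per input variable → output term.

    The antecedent maps input-variable names to term labels (one clause per
    variable by construction of the mapping); ``weight`` scales the firing
    strength and lies in (0, 1].
    """

    antecedent: dict[str, str]
    consequent: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.antecedent = dict(self.antecedent)
        if not self.antecedent:
            raise FuzzyDefinitionError("rule antecedent may not be empty")
        if not 0.0 < self.weight <= 1.0:
            raise FuzzyDefinitionError(f"rule weight must be in (0, 1], got {self.weight}")


@dataclass(frozen=True)
class Operators:
    """Operator choices; only the classical Mamdani triple is implemented."""

    and_op: str = "min"
    implication: str = "min"
    aggregation: str = "max"
    defuzzifier: str = "centroid"

    def __post_init__(self) -> None:
        expected = ("min", "min", "max", "centroid")
        got = (self.and_op, self.implication, self.aggregation, self.defuzzifier)
        if got != expected:
            raise FuzzyDefinitionError(
                f"unsupported operator set {got}; only {expected} is implemented"
            )


@dataclass(frozen=True)
class AggregatedOutput:
    """Sampled fuzzy output surface: ascending grid + membership degrees."""

    grid: np.ndarray
    degrees: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        degrees = np.asarray(self.degrees, dtype=float)
        if grid.shape != degrees.shape or grid.ndim != 1:
            raise FuzzyDefinitionError("grid and degrees must be 1-D arrays of equal length")
        if np.any(np.diff(grid) <= 0):
            raise FuzzyDefinitionError("output grid must be strictly ascending")
        if degrees.min() < 0.0 or degrees.max() > 1.0:
            raise FuzzyDefinitionError("aggregated degrees must lie in [0, 1]")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "degrees", degrees)


@dataclass
class MamdaniModel:
    """Complete Mamdani predictive model: variables, rule base, operators.

    ``grid_points`` controls the discretisation of the output universe used
    for aggregation and centroid defuzzification (default 1001 → 0.1 µg/L
    resolution over a 100 µg/L output span).
    """

    inputs: tuple[FuzzyVariable, ...]
    output: FuzzyVariable
    rules: tuple[Rule, ...]
    operators: Operators = field(default_factory=Operators)
    grid_points: int = 1001

    def __post_init__(self) -> None:
        self.inputs = tuple(self.inputs)
        self.rules = tuple(self.rules)
        if not self.inputs:
            raise FuzzyDefinitionError("model needs at least one input variable")
        if not self.rules:
            raise FuzzyDefinitionError("model needs at least one rule (empty rule base)")
        if self.grid_points < 2:
            raise FuzzyDefinitionError("grid_points must be >= 2")
        names = [v.name for v in self.inputs]
        if len(set(names)) != len(names):
            raise FuzzyDefinitionError(f"duplicate input variable names {names}")
        by_name = {v.name: v for v in self.inputs}
        seen: dict[frozenset, str] = {}
        for rule in self.rules:
            for var, label in rule.antecedent.items():
                if var not in by_name:
                    raise FuzzyDefinitionError(
                        f"rule references unknown input variable '{var}'"
                    )
                by_name[var].term(label)  # raises if the term is unknown
            self.output.term(rule.consequent)
            key = frozenset(rule.antecedent.items())
            if key in seen and seen[key] != rule.consequent:
                raise FuzzyDefinitionError(
                    f"conflicting rules: antecedent {dict(rule.antecedent)} maps to both "
                    f"'{seen[key]}' and '{rule.consequent}'"
                )
            seen[key] = rule.consequent

    # -- lookups -----------------------------------------------------------

    @property
    def input_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.inputs)

    def variable(self, name: str) -> FuzzyVariable:
        for v in self.inputs:
            if v.name == name:
                return v
        raise FuzzyDefinitionError(f"model has no input variable '{name}'")

    def output_grid(self) -> np.ndarray:
        return np.linspace(self.output.universe[0], self.output.universe[1], self.grid_points)

    # -- inference ---------------------------------------------------------

    def firing_strength(self, rule: Rule, inputs: Mapping[str, float]) -> float:
        """min over antecedent clause memberships, scaled by the rule weight."""
        degree = 1.0
        for var, label in rule.antecedent.items():
            if var not in inputs:
                raise MissingInputError(
                    f"no crisp value supplied for antecedent variable '{var}'"
                )
            degree = min(degree, self.variable(var).term(label).mf(inputs[var]))
        return degree * rule.weight

    def infer(self, inputs: Mapping[str, float]) -> AggregatedOutput:
        """Aggregated fuzzy output surface for crisp ``inputs``.

        Raises :class:`NoRuleFiredError` when every rule fires at strength
        zero — a silent all-zero surface would defuzzify outside the model's
        contract.
        """
        for name, value in inputs.items():
            for v in self.inputs:
                if v.name == name:
                    v.assert_in_range(value)
        grid = self.output_grid()
        surface = np.zeros_like(grid)
        for rule in self.rules:
            strength = self.firing_strength(rule, inputs)
            if strength <= 0.0:
                continue
            clipped = np.minimum(strength, self.output.term(rule.consequent).mf(grid))
            surface = np.maximum(surface, clipped)
        if not np.any(surface > 0.0):
            raise NoRuleFiredError(
                f"no rule fired for inputs {dict(inputs)}; prediction undefined"
            )
        return AggregatedOutput(grid=grid, degrees=surface)

    def predict(self, inputs: Mapping[str, float]) -> float:
        """Crisp prediction: centroid of the aggregated output surface."""
        return defuzzify_centroid(self.infer(inputs))


def firing_strength(rule: Rule, inputs: Mapping[str, float], model: MamdaniModel) -> float:
    return model.firing_strength(rule, inputs)


def infer(model: MamdaniModel, inputs: Mapping[str, float]) -> AggregatedOutput:
    return model.infer(inputs)


def defuzzify_centroid(agg: AggregatedOutput) -> float:
    """Discrete centroid Σ(grid·degree)/Σ(degree) of an aggregated surface."""
    total = float(np.sum(agg.degrees))
    if total <= 0.0:
        raise NoRuleFiredError("cannot defuzzify an all-zero surface")
    return float(np.sum(agg.grid * agg.degrees) / total)


def predict(model: MamdaniModel, inputs: Mapping[str, float]) -> float:
    return model.predict(inputs)
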