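"""Wang–Mendel rule induction from OFAT dose–response data.

The rule base of the riboflavin model is reconstructed from data with the
classical one-pass Wang–Mendel procedure:

1. fuzzify each observation's concentration and response;
2. assign each its maximum-membership term (ties break toward the
   lower-order term, a deterministic and yield-conservative choice);
3. form the candidate rule ``level-term → response-term`` with degree equal
   to the product of the two memberships;
4. among candidates sharing an antecedent keep the highest-degree
   consequent, ties again breaking toward the lower-order term.

Responses outside the output universe are clamped to the nearest edge with
a logged warning (the unoptimised baseline sits near the universe floor, so
noisy data occasionally crosses it); observation levels outside the input
universe are excluded from induction with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .catalog import FACTORS, VariableCatalog, build_variables
from .errors import DataError, InsufficientCoverageError
from .fuzzy import FuzzyVariable, Rule
from .ofat import OFATDataset, OFATObservation

logger = logging.getLogger(__name__)

__all__ = ["RuleProvenance", "InducedRuleBase", "induce_rules", "induce_all"]


@dataclass(frozen=True)
class RuleProvenance:
    """The winning observation behind one induced rule, with its degrees."""

    observation: OFATObservation
    antecedent_term: str
    antecedent_degree: float
    consequent_term: str
    consequent_degree: float
    degree: float  # product of the two memberships


@dataclass(frozen=True)
class InducedRuleBase:
    """Rules induced from one OFAT dataset plus per-rule provenance."""

    rules: tuple[Rule, ...]
    provenance: tuple[RuleProvenance, ...]

    def __post_init__(self) -> None:
        antecedents = [tuple(sorted(r.antecedent.items())) for r in self.rules]
        if len(set(antecedents)) != len(antecedents):
            raise DataError("induced rule base has duplicate antecedents")

    @property
    def consequent_of(self) -> dict[str, str]:
        """Antecedent term label → consequent term label."""
        return {next(iter(r.antecedent.values())): r.consequent for r in self.rules}


def _max_membership_term(variable: FuzzyVariable, x: float) -> tuple[int, float]:
    """Index and degree of the max-membership term; ties go to the lower term."""
    degrees = variable.fuzzify(x)
    idx = int(np.argmax(degrees))  # argmax returns the first (lowest) maximiser
    return idx, float(degrees[idx])


def induce_rules(
    dataset: OFATDataset,
    input_var: FuzzyVariable,
    output_var: FuzzyVariable,
) -> InducedRuleBase:
    """Induce a single-factor rule base from one OFAT dataset."""
    if dataset.factor != input_var.name:
        raise DataError(
            f"dataset factor '{dataset.factor}' does not match variable '{input_var.name}'"
        )
    usable: list[OFATObservation] = []
    for obs in dataset.observations:
        if not input_var.contains(obs.level):
            logger.warning(
                "excluding %s observation at %g g/L: outside fuzzy universe %s",
                dataset.factor, obs.level, list(input_var.universe),
            )
            continue
        usable.append(obs)
    if not usable:
        raise InsufficientCoverageError(
            f"dataset '{dataset.factor}': no observations inside the fuzzy universe"
        )

    omin, omax = output_var.universe
    # best candidate per antecedent term index
    best: dict[int, tuple[float, int, RuleProvenance]] = {}
    covered: set[int] = set()
    for obs in usable:
        ant_idx, ant_deg = _max_membership_term(input_var, obs.level)
        covered.update(
            i for i, d in enumerate(input_var.fuzzify(obs.level)) if d > 0.0
        )
        response = obs.response
        if not omin <= response <= omax:
            clamped = min(max(response, omin), omax)
            logger.warning(
                "clamping %s response %g to output universe edge %g",
                dataset.factor, response, clamped,
            )
            response = clamped
        con_idx, con_deg = _max_membership_term(output_var, response)
        degree = ant_deg * con_deg
        prov = RuleProvenance(
            observation=obs,
            antecedent_term=input_var.terms[ant_idx].label,
            antecedent_degree=ant_deg,
            consequent_term=output_var.terms[con_idx].label,
            consequent_degree=con_deg,
            degree=degree,
        )
        incumbent = best.get(ant_idx)
        if (
            incumbent is None
            or degree > incumbent[0]
            or (degree == incumbent[0] and con_idx < incumbent[1])
        ):
            best[ant_idx] = (degree, con_idx, prov)

    if len(covered) < 2:
        raise InsufficientCoverageError(
            f"dataset '{dataset.factor}' activates {len(covered)} input term(s); "
            "need nonzero membership in at least 2 to induce a rule base"
        )

    rules, provenance = [], []
    for ant_idx in sorted(best):
        degree, con_idx, prov = best[ant_idx]
        rules.append(
            Rule(
                antecedent={input_var.name: input_var.terms[ant_idx].label},
                consequent=output_var.terms[con_idx].label,
            )
        )
        provenance.append(prov)
    return InducedRuleBase(rules=tuple(rules), provenance=tuple(provenance))


def induce_all(
    datasets: Sequence[OFATDataset],
    catalog: VariableCatalog | None = None,
) -> dict[str, InducedRuleBase]:
    """Induce one rule base per factor; requires exactly one dataset per factor."""
    catalog = catalog or build_variables()
    by_factor: dict[str, OFATDataset] = {}
    for ds in datasets:
        if ds.factor in by_factor:
            raise DataError(f"duplicate dataset for factor '{ds.factor}'")
        by_factor[ds.factor] = ds
    missing = [f for f in FACTORS if f not in by_factor]
    if missing:
        raise DataError(f"missing OFAT dataset(s) for factor(s): {missing}")
    unknown = set(by_factor) - set(FACTORS)
    if unknown:
        raise DataError(f"datasets for unknown factor(s): {sorted(unknown)}")
    return {
        factor: induce_rules(by_factor[factor], catalog[factor], catalog.riboflavin)
        for factor in FACTORS
    }
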