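"""Synthetic OFAT dose–response generator for the riboflavin pipeline.

Fermentation responses are emulated with two two-parameter curve families
chosen to mirror the qualitative dose–response behaviour of the four medium
components:

* *saturating* (casamino acid, GTP) — a Hill curve with fixed exponent 2,
  ``floor + (ceiling − floor) · L² / (L² + half_point²)``;
* *unimodal* (glycine, sodium acetate, which rise to an optimum and then
  fall) — a Gaussian bump,
  ``floor + (ceiling − floor) · exp(−(L − peak_location)² / (2 · width²))``.

Measurement error is additive Gaussian noise on the response, clamped to
stay positive; every generator call is reproducible from its mandatory seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .catalog import FACTORS, VariableCatalog, build_variables, baseline_levels
from .errors import DataError
from .ofat import OFATDataset, OFATObservation

SATURATING = "saturating"
UNIMODAL = "unimodal"

#: Hill exponent of the saturating family (fixed; steep enough to span the
#: observed response range over a four-fold concentration window).
HILL_EXPONENT = 2.0

__all__ = [
    "SATURATING",
    "UNIMODAL",
    "HILL_EXPONENT",
    "ResponseCurve",
    "SimulationConfig",
    "true_response",
    "generate_ofat",
    "default_config",
    "config_to_dict",
    "config_from_dict",
    "save_config",
    "load_config",
]


@dataclass(frozen=True)
class ResponseCurve:
    """Noise-free dose–response curve of one factor (µg/L over g/L)."""

    shape: str
    floor: float
    ceiling: float
    half_point: float | None = None     # saturating: level of half-maximal gain
    peak_location: float | None = None  # unimodal: level of maximal response
    width: float | None = None          # unimodal: Gaussian width

    def __post_init__(self) -> None:
        if self.shape not in (SATURATING, UNIMODAL):
            raise DataError(f"unknown curve shape '{self.shape}'")
        if not 340.0 <= self.floor < self.ceiling <= 440.0:
            raise DataError(
                f"curve floor/ceiling ({self.floor}, {self.ceiling}) must satisfy "
                "340 <= floor < ceiling <= 440"
            )
        if self.shape == SATURATING and (self.half_point is None or self.half_point <= 0):
            raise DataError("saturating curve needs half_point > 0")
        if self.shape == UNIMODAL and (
            self.peak_location is None or self.width is None or self.width <= 0
        ):
            raise DataError("unimodal curve needs peak_location and width > 0")


def true_response(curve: ResponseCurve, level: float) -> float:
    """Deterministic response of ``curve`` at concentration ``level``."""
    span = curve.ceiling - curve.floor
    if curve.shape == SATURATING:
        num = level ** HILL_EXPONENT
        return curve.floor + span * num / (num + curve.half_point ** HILL_EXPONENT)
    z = (level - curve.peak_location) / curve.width
    return curve.floor + span * math.exp(-0.5 * z * z)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to regenerate a synthetic OFAT campaign.

    ``curves`` and ``levels`` share the same factor keys; levels must lie in
    each factor's fuzzy universe; the seed is mandatory so every stochastic
    run is replayable.
    """

    curves: tuple[tuple[str, ResponseCurve], ...]
    levels: tuple[tuple[str, tuple[float, ...]], ...]
    seed: int
    noise_sd: float = 3.0
    replicates: int = 3

    def __post_init__(self) -> None:
        curves = dict(self.curves)
        levels = {k: tuple(float(x) for x in v) for k, v in dict(self.levels).items()}
        object.__setattr__(self, "curves", tuple(curves.items()))
        object.__setattr__(self, "levels", tuple(levels.items()))
        if self.seed is None:
            raise DataError("simulation seed is mandatory")
        if set(curves) != set(levels):
            raise DataError(
                f"curves ({sorted(curves)}) and levels ({sorted(levels)}) "
                "must cover the same factors"
            )
        if self.noise_sd < 0:
            raise DataError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.replicates < 1:
            raise DataError(f"replicates must be >= 1, got {self.replicates}")
        catalog = build_variables()
        for factor, lvls in levels.items():
            if len(lvls) < 2:
                raise DataError(f"factor '{factor}' needs >= 2 levels")
            if factor in FACTORS:
                for lvl in lvls:
                    catalog[factor].assert_in_range(lvl)

    @property
    def curves_dict(self) -> dict[str, ResponseCurve]:
        return dict(self.curves)

    @property
    def levels_dict(self) -> dict[str, tuple[float, ...]]:
        return dict(self.levels)


def default_config(
    seed: int,
    *,
    noise_sd: float = 3.0,
    replicates: int = 3,
    levels: Mapping[str, Sequence[float]] | None = None,
) -> SimulationConfig:
    """Study-default simulation: curve shapes and magnitudes per factor.

    Casamino acid and GTP saturate with the half-point at the middle
    membership peak, so their attained responses span 360–420 µg/L over the
    universe (the 340/440 asymptotes are never reached — a Hill-2 curve over
    a four-fold concentration window covers at most 60% of its asymptotic
    span, and this placement keeps every response ≥5 µg/L clear of the
    output-term crossovers at 365/415 µg/L, which rule induction needs to be
    stable under noise). Glycine and sodium acetate peak at 10 g/L and fall
    beyond; the sodium-acetate ceiling anchors the observed 429–430 µg/L
    maximum. Default levels are the concentrations tested in the OFAT
    campaign; measurement noise defaults to 3 µg/L with triplicates.
    """
    curves = {
        "casamino": ResponseCurve(SATURATING, floor=340.0, ceiling=440.0, half_point=10.0),
        "gtp": ResponseCurve(SATURATING, floor=340.0, ceiling=440.0, half_point=0.02),
        "sodium_acetate": ResponseCurve(
            UNIMODAL, floor=346.0, ceiling=430.0, peak_location=10.0, width=2.5
        ),
        "glycine": ResponseCurve(
            UNIMODAL, floor=346.0, ceiling=425.0, peak_location=10.0, width=2.5
        ),
    }
    if levels is None:
        levels = {
            "casamino": (5.0, 10.0, 20.0),
            "gtp": (0.01, 0.02, 0.04),
            "sodium_acetate": (5.0, 10.0, 15.0),
            "glycine": (5.0, 10.0, 15.0),
        }
    return SimulationConfig(
        curves=tuple(curves.items()),
        levels=tuple((k, tuple(v)) for k, v in levels.items()),
        seed=int(seed),
        noise_sd=noise_sd,
        replicates=replicates,
    )


def generate_ofat(config: SimulationConfig) -> list[OFATDataset]:
    """Generate one OFAT dataset per configured factor.

    Per factor, level and replicate the response is the curve value plus
    Gaussian(0, noise_sd) measurement error, clamped to stay positive.
    Identical configs (including seed) yield identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    base = baseline_levels()
    datasets = []
    for factor, curve in config.curves:
        observations = []
        for level in config.levels_dict[factor]:
            for rep in range(1, config.replicates + 1):
                response = true_response(curve, level)
                if config.noise_sd > 0:
                    response += rng.normal(0.0, config.noise_sd)
                observations.append(
                    OFATObservation(
                        factor=factor,
                        level=level,
                        response=max(response, 1e-9),
                        replicate=rep,
                    )
                )
        baseline = tuple(
            (other, base[other]) for other in FACTORS if other != factor and other in base
        )
        datasets.append(
            OFATDataset(factor=factor, observations=tuple(observations), baseline=baseline)
        )
    return datasets


# -- config serialisation --------------------------------------------------


def config_to_dict(config: SimulationConfig) -> dict:
    def curve_doc(c: ResponseCurve) -> dict:
        doc = {"shape": c.shape, "floor": c.floor, "ceiling": c.ceiling}
        if c.shape == SATURATING:
            doc["half_point"] = c.half_point
        else:
            doc["peak_location"] = c.peak_location
            doc["width"] = c.width
        return doc

    return {
        "kind": "ofat_simulation",
        "seed": config.seed,
        "noise_sd": config.noise_sd,
        "replicates": config.replicates,
        "curves": {k: curve_doc(c) for k, c in config.curves},
        "levels": {k: list(v) for k, v in config.levels},
    }


def config_from_dict(doc: Mapping) -> SimulationConfig:
    if doc.get("kind") != "ofat_simulation":
        raise DataError(f"not an ofat_simulation document (kind={doc.get('kind')!r})")
    curves = {
        k: ResponseCurve(
            shape=c["shape"],
            floor=float(c["floor"]),
            ceiling=float(c["ceiling"]),
            half_point=c.get("half_point"),
            peak_location=c.get("peak_location"),
            width=c.get("width"),
        )
        for k, c in doc["curves"].items()
    }
    return SimulationConfig(
        curves=tuple(curves.items()),
        levels=tuple((k, tuple(v)) for k, v in doc["levels"].items()),
        seed=int(doc["seed"]),
        noise_sd=float(doc.get("noise_sd", 3.0)),
        replicates=int(doc.get("replicates", 3)),
    )


def save_config(config: SimulationConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=False), encoding="utf-8"
    )


def load_config(path) -> SimulationConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))
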