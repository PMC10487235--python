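"""One-factor-at-a-time (OFAT) dose–response data: containers, CSV I/O, fixture.

An OFAT experiment varies a single medium component while the other
components stay at baseline. Observations are stored long-form, one row per
measurement, in plain UTF-8 CSV with header ``factor,level,response,replicate``
(levels in g/L, responses in µg/L). Each dataset's baseline levels travel in
``# baseline`` comment lines above the header so write → read round-trips
losslessly.

:func:`load_reference_fixture` returns the published validation
measurements for *Lactiplantibacillus plantarum* MTCC 25432 bundled with
the package: six (factor, level, experimental, model-predicted) pairs, the
unoptimised baseline production (346 µg/L) and the optimised production
(429 µg/L).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .catalog import FACTORS
from .errors import DataError

#: Factor ranges explored in the OFAT design. The casamino-acid OFAT range
#: starts below its fuzzy universe (2 vs 5 g/L); points below the universe
#: are legal data but are excluded from rule induction.
OFAT_RANGES: dict[str, tuple[float, float]] = {
    "casamino": (2.0, 20.0),
    "gtp": (0.01, 0.04),
    "sodium_acetate": (5.0, 15.0),
    "glycine": (5.0, 15.0),
}

CSV_COLUMNS = ("factor", "level", "response", "replicate")

__all__ = [
    "OFAT_RANGES",
    "OFATObservation",
    "OFATDataset",
    "ReferencePair",
    "ReferenceFixture",
    "read_ofat_csv",
    "write_ofat_csv",
    "load_reference_fixture",
]


@dataclass(frozen=True)
class OFATObservation:
    """One measurement: ``factor`` at ``level`` g/L produced ``response`` µg/L."""

    factor: str
    level: float
    response: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.response <= 0:
            raise DataError(
                f"non-positive riboflavin response {self.response} for factor "
                f"'{self.factor}' at level {self.level}"
            )
        if self.replicate < 1 or int(self.replicate) != self.replicate:
            raise DataError(f"replicate must be a positive integer, got {self.replicate}")
        lo_hi = OFAT_RANGES.get(self.factor)
        if lo_hi is not None and not (lo_hi[0] <= self.level <= lo_hi[1]):
            raise DataError(
                f"level {self.level} outside OFAT range {lo_hi} of factor '{self.factor}'"
            )


@dataclass(frozen=True)
class OFATDataset:
    """All observations of one factor, other factors held at ``baseline``."""

    factor: str
    observations: tuple[OFATObservation, ...]
    baseline: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        object.__setattr__(
            self, "baseline", tuple((k, float(v)) for k, v in dict(self.baseline).items())
        )
        if any(o.factor != self.factor for o in self.observations):
            raise DataError(f"dataset '{self.factor}' contains foreign-factor observations")
        if len(self.levels) < 2:
            raise DataError(
                f"dataset '{self.factor}' needs observations at >= 2 distinct levels"
            )
        if self.factor in dict(self.baseline):
            raise DataError(f"baseline of dataset '{self.factor}' references itself")

    @property
    def levels(self) -> tuple[float, ...]:
        return tuple(sorted({o.level for o in self.observations}))

    @property
    def baseline_dict(self) -> dict[str, float]:
        return dict(self.baseline)


def read_ofat_csv(path) -> list[OFATDataset]:
    """Read OFAT datasets (one per factor) from a long-form CSV file.

    Required columns: factor, level, response; ``replicate`` is optional and
    defaults to 1. Parse failures are reported with their data-row number.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    baselines: dict[str, dict[str, float]] = {}
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("# baseline "):
            parts = line[len("# baseline "):].split()
            factor, pairs = parts[0], parts[1:]
            baselines[factor] = {
                k: float(v) for k, v in (p.split("=", 1) for p in pairs)
            }
    try:
        df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty file, no OFAT data") from None
    missing = {"factor", "level", "response"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing required column(s) {sorted(missing)}")
    if df.empty:
        raise DataError(f"{path}: header only, no observations")

    observations: dict[str, list[OFATObservation]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict()

        def _num(col: str, caster):
            try:
                return caster(rec[col])
            except (TypeError, ValueError):
                raise DataError(
                    f"{path}: data row {i}: non-numeric {col} {rec[col]!r}"
                ) from None

        factor = str(rec["factor"]).strip()
        level = _num("level", float)
        response = _num("response", float)
        replicate = 1
        if "replicate" in rec and not pd.isna(rec["replicate"]):
            replicate = _num("replicate", lambda v: int(float(v)))
        try:
            obs = OFATObservation(factor, level, response, replicate)
        except DataError as exc:
            raise DataError(f"{path}: data row {i}: {exc}") from None
        observations.setdefault(factor, []).append(obs)

    datasets = []
    for factor, obs in observations.items():
        try:
            datasets.append(
                OFATDataset(
                    factor=factor,
                    observations=tuple(obs),
                    baseline=tuple(baselines.get(factor, {}).items()),
                )
            )
        except DataError as exc:
            raise DataError(f"{path}: {exc}") from None
    return datasets


def write_ofat_csv(datasets, path) -> None:
    """Write datasets to CSV; inverse of :func:`read_ofat_csv`."""
    datasets = list(datasets)
    if not datasets:
        raise DataError("refusing to write an empty dataset list")
    path = Path(path)
    lines = []
    for ds in datasets:
        if ds.baseline:
            fixed = " ".join(f"{k}={v!r}" for k, v in ds.baseline)
            lines.append(f"# baseline {ds.factor} {fixed}")
    lines.append(",".join(CSV_COLUMNS))
    for ds in datasets:
        for o in ds.observations:
            lines.append(f"{o.factor},{o.level!r},{o.response!r},{o.replicate}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class ReferencePair:
    """One published (experimental, model-predicted) riboflavin pair."""

    factor: str
    level: float
    experimental: float
    predicted: float
    source: str  # "validation" (held-out check) or "dose_response" (curve point)


@dataclass(frozen=True)
class ReferenceFixture:
    """Published reference measurements bundled with the package."""

    pairs: tuple[ReferencePair, ...]
    baseline_production: float
    optimized_production: float

    @property
    def validation_pairs(self) -> tuple[ReferencePair, ...]:
        return tuple(p for p in self.pairs if p.source == "validation")

    @property
    def dose_response_pairs(self) -> tuple[ReferencePair, ...]:
        return tuple(p for p in self.pairs if p.source == "dose_response")


def load_reference_fixture() -> ReferenceFixture:
    """Load the bundled reference validation measurements."""
    text = (
        resources.files("ribofis.data")
        .joinpath("reference_validation.json")
        .read_text(encoding="utf-8")
    )
    doc = json.loads(text)
    pairs = tuple(
        ReferencePair(
            factor=p["factor"],
            level=float(p["level"]),
            experimental=float(p["experimental"]),
            predicted=float(p["predicted"]),
            source=p["source"],
        )
        for p in doc["pairs"]
    )
    return ReferenceFixture(
        pairs=pairs,
        baseline_production=float(doc["baseline_production"]),
        optimized_production=float(doc["optimized_production"]),
    )
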