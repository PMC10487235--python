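"""Model-validation arithmetic: percent variation, RMSE, Pearson correlation.

Percent variation follows the convention

    (experimental − predicted) / experimental × 100

rounded half-up to two decimals — the only convention that reproduces the
published validation table from its own printed inputs. The headline percent
increase between unoptimised and optimised production rounds half-up to the
nearest integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .ofat import ReferenceFixture

__all__ = [
    "percent_variation",
    "percent_increase",
    "rmse",
    "pearson_r",
    "ValidationRecord",
    "ValidationReport",
    "build_report",
    "records_from_fixture",
    "report_to_dataframe",
    "write_report_csv",
    "format_report",
]


def _round_half_up(value: float, exponent: str) -> Decimal:
    return Decimal(repr(value)).quantize(Decimal(exponent), rounding=ROUND_HALF_UP)


def percent_variation(experimental: float, predicted: float) -> float:
    """Signed percent deviation of prediction from experiment (2 decimals)."""
    if experimental <= 0:
        raise DataError(f"experimental value must be positive, got {experimental}")
    raw = (experimental - predicted) / experimental * 100.0
    return float(_round_half_up(raw, "0.01"))


def percent_increase(baseline: float, optimized: float) -> int:
    """Headline percent improvement over baseline (rounded to an integer)."""
    if baseline <= 0:
        raise DataError(f"baseline value must be positive, got {baseline}")
    raw = (optimized - baseline) / baseline * 100.0
    return int(_round_half_up(raw, "1"))


def rmse(pairs: Sequence[tuple[float, float]]) -> float:
    """Root-mean-square error over (experimental, predicted) pairs (µg/L)."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise DataError("rmse needs at least one pair")
    return float(np.sqrt(np.mean((arr[:, 0] - arr[:, 1]) ** 2)))


def pearson_r(pairs: Sequence[tuple[float, float]]) -> float:
    """Product-moment correlation over (experimental, predicted) pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.shape[0] < 2:
        raise DataError("pearson_r needs at least two pairs")
    if np.std(arr[:, 0]) == 0 or np.std(arr[:, 1]) == 0:
        raise DataError("pearson_r undefined: zero variance in a coordinate")
    return float(stats.pearsonr(arr[:, 0], arr[:, 1]).statistic)


@dataclass(frozen=True)
class ValidationRecord:
    """One validation row: factor, level, predicted vs experimental riboflavin.

    ``percent_variation`` is always recomputed from the record's own fields;
    a supplied value that disagrees with the recomputation is rejected.
    """

    factor: str
    level: float
    predicted: float
    experimental: float
    percent_variation: float | None = None

    def __post_init__(self) -> None:
        computed = percent_variation(self.experimental, self.predicted)
        if self.percent_variation is not None and float(self.percent_variation) != computed:
            raise DataError(
                f"stored percent variation {self.percent_variation} inconsistent with "
                f"recomputed {computed} for factor '{self.factor}'"
            )
        object.__setattr__(self, "percent_variation", computed)


@dataclass(frozen=True)
class ValidationReport:
    """Aggregated validation metrics over a set of records."""

    records: tuple[ValidationRecord, ...]
    rmse: float
    pearson_r: float | None
    variation_range: tuple[float, float]


def build_report(
    records: Sequence[ValidationRecord],
    pairs: Sequence[tuple[float, float]] | None = None,
) -> ValidationReport:
    """Aggregate records into a report.

    ``pairs`` optionally supplies the (experimental, predicted) pairs for the
    RMSE/correlation metrics — e.g. a larger dose–response set than the
    held-out validation records; by default the records' own pairs are used.
    Pearson's r is reported as None when fewer than two pairs are available.
    """
    records = tuple(records)
    if not records:
        raise DataError("validation report needs at least one record")
    if pairs is None:
        pairs = [(r.experimental, r.predicted) for r in records]
    pairs = list(pairs)
    variations = [r.percent_variation for r in records]
    r_value = pearson_r(pairs) if len(pairs) >= 2 else None
    return ValidationReport(
        records=records,
        rmse=rmse(pairs),
        pearson_r=r_value,
        variation_range=(min(variations), max(variations)),
    )


def records_from_fixture(
    fixture: ReferenceFixture, source: str = "validation"
) -> list[ValidationRecord]:
    """Build records from the bundled reference pairs of the given source."""
    return [
        ValidationRecord(
            factor=p.factor,
            level=p.level,
            predicted=p.predicted,
            experimental=p.experimental,
        )
        for p in fixture.pairs
        if p.source == source
    ]


def report_to_dataframe(report: ValidationReport) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "factor": r.factor,
                "level": r.level,
                "predicted": r.predicted,
                "experimental": r.experimental,
                "percent_variation": r.percent_variation,
            }
            for r in report.records
        ],
        columns=["factor", "level", "predicted", "experimental", "percent_variation"],
    )


def write_report_csv(report: ValidationReport, path) -> None:
    report_to_dataframe(report).to_csv(Path(path), index=False)


def format_report(report: ValidationReport) -> str:
    """Human-readable table plus the aggregate metrics."""
    lines = [report_to_dataframe(report).to_string(index=False)]
    lines.append("")
    lines.append(f"RMSE: {report.rmse:.4f} ug/L")
    if report.pearson_r is not None:
        lines.append(f"Pearson r: {report.pearson_r:.4f}")
    lo, hi = report.variation_range
    lines.append(f"Percent-variation range: {lo:.2f}% to {hi:.2f}%")
    return "\n".join(lines)
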