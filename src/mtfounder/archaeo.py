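"""Genetic founder ages versus radiocarbon settlement evidence.

The package ships a fixture table of Pacific regions with genetic
founder ages (point estimate and 95% CI, years BP) and the published
2-sigma calibrated radiocarbon ranges for the local appearance of
Lapita (or, beyond the Lapita horizon, first settlement).  Comparison
uses closed-interval overlap — a genetic CI merely touching a
radiocarbon range counts as consistent — and a region with several
radiocarbon sources is consistent if any of them overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clock import AgeEstimate

EVIDENCE_CLASSES = ("Lapita", "frontier-Lapita", "red-slipped", "first-settlement")


class IntervalError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class RadiocarbonRange:
    region: str
    cal_bp: tuple[float, float]  # (older, younger)
    evidence_class: str = "Lapita"
    source_ref: str = ""

    def __post_init__(self):
        older, younger = self.cal_bp
        if not older >= younger >= 0:
            raise IntervalError(f"{self.region}: need older >= younger >= 0, got {self.cal_bp}")


@dataclass(frozen=True)
class ComparisonRow:
    region: str
    genetic: AgeEstimate
    archaeological: tuple[RadiocarbonRange, ...]
    lon: float = float("nan")

    @property
    def overlap(self) -> bool:
        return any(
            interval_overlap(self.genetic.ci95, r.cal_bp) for r in self.archaeological
        )


def interval_overlap(genetic_ci: tuple[float, float], c14: tuple[float, float]) -> bool:
    """Closed-interval overlap between a genetic 95% CI (lo, hi) and a
    radiocarbon range (older, younger); touching endpoints overlap."""
    lo, hi = genetic_ci
    if lo > hi:
        raise IntervalError(f"genetic interval reversed: {genetic_ci}")
    older, younger = max(c14), min(c14)  # normalise endpoint order
    return lo <= older and hi >= younger


def exception_count(rows: Sequence[ComparisonRow]) -> tuple[int, list[str]]:
    """Regions whose genetic CI is disjoint from *all* their radiocarbon
    ranges.  Rows without archaeological evidence are not compared."""
    exceptions = sorted(
        {r.region for r in rows if r.archaeological and not r.overlap}
    )
    return len(exceptions), exceptions


def correlate(rows: Sequence[ComparisonRow]):
    """Paired genetic/archaeological point estimates (west to east) and
    their Pearson correlation.

    The archaeological point estimate is the midpoint of the 2-sigma
    range (averaged when a region has several sources).
    """
    paired = []
    for row in sorted(rows, key=lambda r: (r.lon, r.region)):
        if not row.archaeological:
            continue
        mid = float(np.mean([(r.cal_bp[0] + r.cal_bp[1]) / 2 for r in row.archaeological]))
        paired.append((row.region, row.genetic.age_bp, mid))
    if len(paired) < 3:
        raise InsufficientDataError("correlation requires >= 3 paired regions")
    genetic = np.array([p[1] for p in paired])
    arch = np.array([p[2] for p in paired])
    r, _ = stats.pearsonr(genetic, arch)
    return paired, float(r)


# ---------------------------------------------------------------------------
# Packaged fixture
# ---------------------------------------------------------------------------


def load_packaged_table() -> pd.DataFrame:
    """The packaged region table (genetic ages, radiocarbon ranges)."""
    with resources.files("mtfounder.data").joinpath("pacific_comparison.csv").open() as fh:
        return pd.read_csv(fh)


def packaged_comparison(exclude: Sequence[str] = ("Micronesia",)) -> list[ComparisonRow]:
    """Comparison rows from the packaged table.

    Micronesia is excluded by default: its source of settlement cannot
    be pinned down without extra assumptions, so only the genetic
    estimate is reported for it.
    """
    df = load_packaged_table()
    rows: list[ComparisonRow] = []
    for region, grp in df.groupby("region", sort=False):
        if region in set(exclude):
            continue
        first = grp.iloc[0]
        genetic = AgeEstimate(
            age_bp=float(first.genetic_age),
            ci95=(float(first.genetic_lo), float(first.genetic_hi)),
            clock_id="selection-corrected",
        )
        ranges = tuple(
            RadiocarbonRange(
                region=region,
                cal_bp=(float(r.c14_older), float(r.c14_younger)),
                evidence_class=str(r.evidence_class),
                source_ref=str(r.source),
            )
            for r in grp.itertuples()
            if pd.notna(r.c14_older)
        )
        rows.append(
            ComparisonRow(
                region=region, genetic=genetic, archaeological=ranges,
                lon=float(first.lon),
            )
        )
    return rows


def comparison_report(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    recs = []
    for row in sorted(rows, key=lambda r: (r.lon, r.region)):
        recs.append(
            {
                "region": row.region,
                "genetic_age": row.genetic.age_bp,
                "genetic_lo": row.genetic.ci95[0],
                "genetic_hi": row.genetic.ci95[1],
                "n_c14_sources": len(row.archaeological),
                "overlap": row.overlap if row.archaeological else "",
            }
        )
    return pd.DataFrame(recs)
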