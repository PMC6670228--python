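"""Screening summary tables and the cross-construct heterogeneity test.

The mutation screen counts, per CRISPR construct, regenerated plants,
Cas9-expressing plants, low transgene-copy plants, and plants/grains whose
gliadin gel profile shows "clear" (band gained or lost) or "any" (clear or
potential) changes. Percentages are displayed rounded half-up; the
heterogeneity test is an uncorrected Pearson chi-square on the 2xk
successes/failures table with k-1 degrees of freedom.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ScreeningCounts:
    """Per-construct screen counts (T0 plants, T1 grains)."""

    construct: str
    regenerated: int = 0
    expressing: int = 0
    low_copy: int = 0
    plants_tested: int = 0
    grains_tested: int = 0
    plants_clear: int = 0
    grains_clear: int = 0
    plants_any: int = 0
    grains_any: int = 0

    def __post_init__(self) -> None:
        for name in (
            "regenerated", "expressing", "low_copy", "plants_tested",
            "grains_tested", "plants_clear", "grains_clear", "plants_any",
            "grains_any",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"ScreeningCounts.{name}: negative count")
        if self.expressing > self.regenerated:
            raise ValueError("ScreeningCounts: expressing > regenerated")
        if not (self.plants_clear <= self.plants_any <= self.plants_tested):
            raise ValueError("ScreeningCounts: need clear <= any <= tested (plants)")
        if not (self.grains_clear <= self.grains_any <= self.grains_tested):
            raise ValueError("ScreeningCounts: need clear <= any <= tested (grains)")


@dataclass(frozen=True)
class StatResult:
    statistic: float
    df: int
    p_value: float
    low_expected: bool = False  # any expected cell < 1
    method: str = "Pearson chi-square, no continuity correction, df=k-1"


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (what printed tables use), not banker's."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(numer: int, denom: int, decimals: int) -> float:
    if denom == 0:
        return float("nan")  # undefined, never 0
    return round_half_up(100.0 * numer / denom, decimals)


#: (column name, numerator field, denominator field)
_DERIVED = (
    ("pct_expressing", "expressing", "regenerated"),
    ("pct_low_copy", "low_copy", "expressing"),
    ("pct_plants_clear", "plants_clear", "plants_tested"),
    ("pct_grains_clear", "grains_clear", "grains_tested"),
    ("pct_plants_any", "plants_any", "plants_tested"),
    ("pct_grains_any", "grains_any", "grains_tested"),
)


def percentage_table(
    counts: Sequence[ScreeningCounts], decimals: int = 1, total_row: bool = True
) -> pd.DataFrame:
    """Derived percentages per construct plus a TOTAL row.

    Rounds half-up to ``decimals``; zero denominators yield NaN cells.
    Raw counts are retained alongside the percentages.
    """
    rows = [dataclasses.asdict(c) for c in counts]
    if total_row:
        total = ScreeningCounts(
            "TOTAL",
            **{
                f: sum(getattr(c, f) for c in counts)
                for f in (
                    "regenerated", "expressing", "low_copy", "plants_tested",
                    "grains_tested", "plants_clear", "grains_clear",
                    "plants_any", "grains_any",
                )
            },
        )
        rows.append(dataclasses.asdict(total))
    df = pd.DataFrame(rows).set_index("construct")
    for col, num, den in _DERIVED:
        df[col] = [_pct(int(r[num]), int(r[den]), decimals) for _, r in df.iterrows()]
    return df


def heterogeneity_chi2(
    successes: Sequence[int], totals: Sequence[int]
) -> StatResult:
    """Pearson chi-square heterogeneity test on a 2xk table.

    Tests whether k binomial proportions share one underlying rate. No
    continuity correction; df = k-1. Expected cells below 1 set the
    ``low_expected`` warning flag.
    """
    successes = list(successes)
    totals = list(totals)
    if len(successes) != len(totals):
        raise ValueError("successes and totals must have equal length")
    if len(successes) < 2:
        raise ValueError("need at least two groups")
    for s, t in zip(successes, totals):
        if t == 0:
            raise ValueError("group with zero total")
        if not 0 <= s <= t:
            raise ValueError("need 0 <= successes <= total")
    table = np.array([successes, [t - s for s, t in zip(successes, totals)]])
    if table.sum(axis=1).min() == 0:
        # all successes or all failures: proportions identical by necessity
        return StatResult(0.0, len(successes) - 1, 1.0)
    res = sps.chi2_contingency(table, correction=False)
    low = bool((np.asarray(res.expected_freq) < 1).any())
    return StatResult(float(res.statistic), len(successes) - 1, float(res.pvalue), low)


def mutation_rate(hits: int, screened: int, decimals: int = 2) -> float:
    """Percentage of screened lines showing a changed profile."""
    if screened <= 0:
        raise ValueError("screened must be positive")
    if hits > screened or hits < 0:
        raise ValueError("need 0 <= hits <= screened")
    return round_half_up(100.0 * hits / screened, decimals)


def load_screen_counts() -> list[ScreeningCounts]:
    """The published four-construct screen counts shipped with the package."""
    ref = resources.files("gliadkit.data").joinpath("screen_counts.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return [ScreeningCounts(**row) for row in df.to_dict("records")]


def load_irradiated_counts() -> tuple[int, int]:
    """(lines with changed profiles, lines tested) for the irradiated screen."""
    ref = resources.files("gliadkit.data").joinpath("irradiated_screen.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    row = df.iloc[0]
    return int(row["lines_changed"]), int(row["lines_tested"])
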