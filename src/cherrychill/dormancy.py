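"""Dormancy-break dating from weekly forcing tests.

A forcing test compares the fresh weight of flower buds sampled directly
from the field with buds weighed after a week in a warm growth chamber
(22 ± 1 °C, 12 h photoperiod). Once a cultivar's chilling requirement is
met, forced buds resume growth and gain weight; endodormancy is declared
broken on the first sampling date whose forced/field mean-weight ratio
reaches the classification threshold (default: a 30% increase, boundary
inclusive). Accumulating chill units from the start of autumn to that date
yields the cultivar's chilling requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, WindowError
from .thermal import Accumulation, ChillTable, HourlyTemperatureSeries, UTAH_TABLE, accumulate

__all__ = [
    "ForcingTest",
    "BreakDetermination",
    "classify_break",
    "estimate_break_date",
    "chilling_requirement",
    "read_forcing_csv",
    "write_break_tsv",
]

DEFAULT_BREAK_THRESHOLD_PCT = 30.0

#: Forcing-chamber protocol metadata (recorded, not simulated).
FORCING_PROTOCOL = {
    "chamber_temp_c": 22.0,
    "chamber_temp_tol_c": 1.0,
    "photoperiod_h": 12,
    "duration_days": 7,
}


@dataclass(frozen=True)
class ForcingTest:
    """Bud weights for one sampling date: field reference vs. forced."""

    date: pd.Timestamp
    field_weights: np.ndarray
    forced_weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "date", pd.Timestamp(self.date))
        for name in ("field_weights", "forced_weights"):
            w = np.asarray(getattr(self, name), dtype=float)
            if w.size < 2:
                raise InputError(f"{name}: at least 2 buds required, got {w.size}")
            if not np.all(np.isfinite(w)) or np.any(w <= 0):
                raise InputError(f"{name}: weights must be finite and positive")
            object.__setattr__(self, name, w)

    @property
    def ratio(self) -> float:
        """Forced/field ratio of mean bud weights."""
        return float(np.mean(self.forced_weights) / np.mean(self.field_weights))


@dataclass
class BreakDetermination:
    """Outcome of scanning an ordered sequence of forcing tests."""

    break_date: pd.Timestamp | None
    ratio_series: list[tuple[pd.Timestamp, float]]
    threshold_pct: float
    chilling_requirement_cu: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def ratio_at_break(self) -> float | None:
        if self.break_date is None:
            return None
        return dict(self.ratio_series)[self.break_date]


def classify_break(test: ForcingTest, threshold_pct: float = DEFAULT_BREAK_THRESHOLD_PCT):
    """Classify one forcing test as broken/not broken.

    Broken iff mean(forced) >= (1 + threshold/100) * mean(field); the
    boundary is inclusive ("increased at least 30%").

    Returns ``(broken: bool, ratio: float)``.
    """
    if threshold_pct < 0:
        raise InputError("threshold_pct must be >= 0")
    ratio = test.ratio
    return ratio >= 1.0 + threshold_pct / 100.0, ratio


def estimate_break_date(
    tests: list[ForcingTest], threshold_pct: float = DEFAULT_BREAK_THRESHOLD_PCT
) -> BreakDetermination:
    """Date endodormancy break as the earliest test classified broken.

    ``tests`` must be strictly ordered by date. If no test reaches the
    threshold, ``break_date`` is None.
    """
    if not tests:
        raise InputError("no forcing tests supplied")
    dates = [t.date for t in tests]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise InputError("forcing tests must be strictly ordered by date")

    ratio_series: list[tuple[pd.Timestamp, float]] = []
    break_date: pd.Timestamp | None = None
    for test in tests:
        broken, ratio = classify_break(test, threshold_pct)
        ratio_series.append((test.date, ratio))
        if broken and break_date is None:
            break_date = test.date
    return BreakDetermination(
        break_date=break_date, ratio_series=ratio_series, threshold_pct=threshold_pct
    )


def chilling_requirement(
    series: HourlyTemperatureSeries,
    det: BreakDetermination,
    *,
    table: ChillTable = UTAH_TABLE,
    floor_at_zero: bool = False,
) -> tuple[float, Accumulation]:
    """CU accumulated from season start up to (excluding) the break date.

    The window covers the hours strictly before the break timestamp, so a
    break 500 h into a constant chilling series yields exactly 500 hourly
    contributions. Returns ``(cu, accumulation)`` and stores ``cu`` on the
    determination. Raises if the determination has no break date or it
    precedes the season start.
    """
    if det.break_date is None:
        raise WindowError("no break date determined; cannot compute chilling requirement")
    if det.break_date <= series.season_start:
        raise WindowError("break date precedes season start")
    end = det.break_date - pd.Timedelta(hours=1)
    if end <= series.season_start:
        raise WindowError("break date too close to season start")
    acc = accumulate(
        series,
        (series.season_start, end),
        "chill",
        table=table,
        floor_at_zero=floor_at_zero,
    )
    det.chilling_requirement_cu = acc.total
    det.metadata.setdefault("season_start", str(series.season_start))
    return acc.total, acc


def read_forcing_csv(path) -> list[ForcingTest]:
    """Read forcing tests from a long CSV: date, condition, bud_id, weight_mg."""
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"date", "condition", "weight_mg"}
    if not required.issubset(df.columns):
        raise InputError(f"forcing CSV must have columns {sorted(required)}")
    bad = set(df["condition"].unique()) - {"field", "forced"}
    if bad:
        raise InputError(f"unknown forcing conditions: {sorted(bad)}")
    tests = []
    for date, grp in df.groupby("date", sort=True):
        tests.append(
            ForcingTest(
                date=date,
                field_weights=grp.loc[grp["condition"] == "field", "weight_mg"].to_numpy(),
                forced_weights=grp.loc[grp["condition"] == "forced", "weight_mg"].to_numpy(),
            )
        )
    return tests


def write_break_tsv(path, rows: list[dict]) -> None:
    """Write ``break_dates.tsv`` (one row per cultivar-year)."""
    cols = ["cultivar", "year", "break_date", "ratio_at_break", "chilling_requirement_CU"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, float_format="%.3f")
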