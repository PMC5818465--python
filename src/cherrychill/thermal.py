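"""Hourly thermal-time models for bud dormancy phenology.

Two classical models are implemented:

* **Utah chill units (CU)** — each hour contributes a piecewise-constant
  weight (0, ±0.5 or ±1) depending on the temperature band it falls in;
  chilling effectiveness peaks in the 2.5–9.2 °C band and warm hours
  (> 16 °C) count against accumulation.
* **Growing degree hours (GDH)** — each hour between a lower threshold of
  6 °C and a cap of 25 °C contributes ``temp − 4.5`` °C·h; temperatures
  above the cap are treated as 25 °C, temperatures below the threshold
  contribute nothing.

Accumulating CU from the start of autumn to the dormancy-break date gives a
cultivar's chilling requirement; accumulating GDH from break to bloom gives
its heat requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .errors import InputError, WindowError

__all__ = [
    "ChillTable",
    "UTAH_TABLE",
    "HourlyTemperatureSeries",
    "Accumulation",
    "chill_units_hourly",
    "gdh_hourly",
    "accumulate",
    "daily_summary",
    "read_temperature_csv",
    "write_daily_tsv",
]

GDH_BASE_C = 4.5
GDH_LOWER_THRESHOLD_C = 6.0
GDH_CAP_C = 25.0

#: Default first day of chill accumulation ("beginning of the autumn").
DEFAULT_SEASON_START = (9, 21)  # month, day


@dataclass(frozen=True)
class ChillTable:
    """Piecewise-constant hourly chill-unit response.

    ``edges`` are the interior temperature breakpoints (°C, strictly
    increasing); ``values`` has one more element than ``edges`` and gives the
    CU/h contribution of each band from coldest to warmest.
    ``edge_in_upper_band[i]`` says whether a temperature exactly equal to
    ``edges[i]`` belongs to the band above (lower-bound-inclusive bands) or
    below the breakpoint.
    """

    edges: tuple[float, ...]
    values: tuple[float, ...]
    edge_in_upper_band: tuple[bool, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.values) != len(self.edges) + 1:
            raise InputError("chill table needs len(values) == len(edges) + 1")
        if len(self.edge_in_upper_band) != len(self.edges):
            raise InputError("edge_in_upper_band must match edges")
        if any(b >= a for a, b in zip(self.edges[1:], self.edges[:-1])):
            raise InputError("chill table edges must be strictly increasing")

    def _search_edges(self) -> np.ndarray:
        # Nudge edges that belong to the *lower* band so that
        # searchsorted(side="right") classifies them correctly.
        ed = np.array(self.edges, dtype=float)
        for i, upper in enumerate(self.edge_in_upper_band):
            if not upper:
                ed[i] = np.nextafter(ed[i], np.inf)
        return ed

    def __call__(self, temp_c):
        t = np.asarray(temp_c, dtype=float)
        if not np.all(np.isfinite(t)):
            raise InputError("temperatures must be finite")
        idx = np.searchsorted(self._search_edges(), t, side="right")
        out = np.asarray(self.values, dtype=float)[idx]
        return float(out) if np.isscalar(temp_c) else out


#: Standard Utah-model table: 0 below 1.5 °C, 0.5 in [1.5, 2.5), full unit in
#: [2.5, 9.2), 0.5 in [9.2, 12.5), 0 in [12.5, 16), −0.5 in [16, 18] and −1
#: above 18 °C.
UTAH_TABLE = ChillTable(
    edges=(1.5, 2.5, 9.2, 12.5, 16.0, 18.0),
    values=(0.0, 0.5, 1.0, 0.5, 0.0, -0.5, -1.0),
    edge_in_upper_band=(True, True, True, True, True, False),
    name="utah",
)


def chill_units_hourly(temp_c, table: ChillTable = UTAH_TABLE):
    """Hourly chill-unit contribution (dimensionless; may be negative)."""
    return table(temp_c)


def gdh_hourly(temp_c):
    """Hourly growing-degree-hour contribution in °C·h (always >= 0).

    0 below 6 °C; ``temp − 4.5`` between 6 and 25 °C; capped at 20.5 °C·h
    for temperatures above 25 °C.
    """
    t = np.asarray(temp_c, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InputError("temperatures must be finite")
    out = np.where(t < GDH_LOWER_THRESHOLD_C, 0.0, np.minimum(t, GDH_CAP_C) - GDH_BASE_C)
    return float(out) if np.isscalar(temp_c) else out


@dataclass(frozen=True)
class HourlyTemperatureSeries:
    """One season of hourly station temperatures.

    ``times`` must be strictly increasing with nominal 1-hour spacing; gaps
    are permitted (they are flagged and handled during accumulation).
    ``season_start`` marks the beginning of autumn, the default origin of
    chill accumulation.
    """

    times: pd.DatetimeIndex
    temps: np.ndarray
    season_start: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        times = pd.DatetimeIndex(self.times)
        temps = np.asarray(self.temps, dtype=float)
        if len(times) != len(temps):
            raise InputError("times and temps must have equal length")
        if len(times) == 0:
            raise InputError("empty temperature series")
        if not times.is_monotonic_increasing or times.has_duplicates:
            raise InputError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(temps)):
            raise InputError("temperatures must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "temps", temps)
        if self.season_start is None:
            first = times[0]
            month, day = DEFAULT_SEASON_START
            start = pd.Timestamp(year=first.year, month=month, day=day)
            if start < first:
                start = first
            object.__setattr__(self, "season_start", start)
        else:
            object.__setattr__(self, "season_start", pd.Timestamp(self.season_start))

    def __len__(self) -> int:
        return len(self.times)

    @property
    def has_gaps(self) -> bool:
        deltas = np.diff(self.times.asi8)
        return bool(np.any(deltas != 3_600_000_000_000))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.times, "temp_c": self.temps})


@dataclass
class Accumulation:
    """Running thermal-time sum over a window.

    ``cumulative`` is indexed on the full hourly grid of the window; its last
    element is the window total. ``metadata`` carries coverage statistics and
    any warnings raised while filling gaps.
    """

    model: Literal["chill", "heat"]
    times: pd.DatetimeIndex
    hourly: np.ndarray
    cumulative: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(self.cumulative[-1])

    def value_at(self, when) -> float:
        """Cumulative value at the last grid hour <= ``when`` (0 before start)."""
        when = pd.Timestamp(when)
        pos = self.times.searchsorted(when, side="right") - 1
        if pos < 0:
            return 0.0
        return float(self.cumulative[min(pos, len(self.cumulative) - 1)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.cumulative, index=self.times, name=self.model)


def accumulate(
    series: HourlyTemperatureSeries,
    window: tuple,
    model: Literal["chill", "heat"],
    *,
    table: ChillTable = UTAH_TABLE,
    floor_at_zero: bool = False,
    max_interp_gap_h: int = 3,
    coverage_warn_frac: float = 0.05,
) -> Accumulation:
    """Accumulate chill units or growing degree hours over ``window``.

    The window ``(start, end)`` is inclusive at both ends and must lie within
    the series extent. Gaps of at most ``max_interp_gap_h`` hours are filled
    by linear interpolation; longer gaps contribute 0 and, if more than
    ``coverage_warn_frac`` of window hours are missing from the source, a
    coverage warning is recorded in ``metadata["warnings"]``.

    With ``floor_at_zero`` (chill only) the running total is reset to 0
    whenever it would go negative; by default negative totals are allowed.
    """
    if model not in ("chill", "heat"):
        raise InputError(f"unknown model {model!r}")
    start, end = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
    if start >= end:
        raise WindowError("window start must precede end")
    if start < series.times[0] or end > series.times[-1]:
        raise WindowError(
            f"window [{start}, {end}] outside series extent "
            f"[{series.times[0]}, {series.times[-1]}]"
        )

    grid = pd.date_range(start.ceil("h"), end.floor("h"), freq="h")
    if len(grid) == 0:
        raise WindowError("window contains no whole hours")
    src = pd.Series(series.temps, index=series.times)
    temps = src.reindex(grid)
    missing = temps.isna().to_numpy()
    n_missing = int(missing.sum())
    # fill only whole gaps of <= max_interp_gap_h hours; longer gaps stay NaN
    filled = temps.copy()
    if n_missing:
        interp = temps.interpolate(method="time", limit_area="inside")
        short_gap = np.zeros(len(grid), dtype=bool)
        i = 0
        while i < len(grid):
            if not missing[i]:
                i += 1
                continue
            j = i
            while j < len(grid) and missing[j]:
                j += 1
            if j - i <= max_interp_gap_h:
                short_gap[i:j] = True
            i = j
        filled[short_gap] = interp[short_gap]

    warnings: list[str] = []
    frac_missing = n_missing / len(grid)
    if frac_missing > coverage_warn_frac:
        warnings.append(
            f"{n_missing}/{len(grid)} window hours ({frac_missing:.1%}) missing "
            "from the temperature record"
        )

    valid = filled.notna().to_numpy()
    vals = filled.to_numpy(dtype=float)
    hourly = np.zeros(len(grid), dtype=float)
    if model == "chill":
        hourly[valid] = table(vals[valid])
    else:
        hourly[valid] = gdh_hourly(vals[valid])

    if model == "chill" and floor_at_zero:
        cumulative = np.empty_like(hourly)
        running = 0.0
        for i, c in enumerate(hourly):
            running = max(running + c, 0.0)
            cumulative[i] = running
    else:
        cumulative = np.cumsum(hourly)

    return Accumulation(
        model=model,
        times=grid,
        hourly=hourly,
        cumulative=cumulative,
        metadata={
            "warnings": warnings,
            "missing_hours": n_missing,
            "coverage": 1.0 - frac_missing,
            "table": table.name if model == "chill" else None,
            "floor_at_zero": floor_at_zero if model == "chill" else None,
        },
    )


def daily_summary(chill: Accumulation, heat: Accumulation | None = None) -> pd.DataFrame:
    """Daily CU/GDH sums and running totals as a tidy frame."""
    cu = pd.Series(chill.hourly, index=chill.times)
    out = pd.DataFrame(
        {
            "daily_cu": cu.resample("D").sum(),
            "cumulative_cu": pd.Series(chill.cumulative, index=chill.times).resample("D").last(),
        }
    )
    if heat is not None:
        gdh = pd.Series(heat.hourly, index=heat.times)
        out["daily_gdh"] = gdh.resample("D").sum()
        out["cumulative_gdh"] = (
            pd.Series(heat.cumulative, index=heat.times).resample("D").last()
        )
    else:
        out["daily_gdh"] = 0.0
        out["cumulative_gdh"] = 0.0
    out.index.name = "date"
    return out.fillna(0.0)


def read_temperature_csv(path, season_start=None) -> HourlyTemperatureSeries:
    """Read an hourly temperature record (columns ``timestamp``, ``temp_c``)."""
    df = pd.read_csv(path)
    required = {"timestamp", "temp_c"}
    if not required.issubset(df.columns):
        raise InputError(f"temperature CSV must have columns {sorted(required)}")
    times = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
    return HourlyTemperatureSeries(
        times=times,
        temps=df["temp_c"].to_numpy(dtype=float),
        season_start=season_start,
    )


def write_daily_tsv(path, chill: Accumulation, heat: Accumulation | None = None) -> None:
    """Write the ``cu_gdh_daily.tsv`` table."""
    df = daily_summary(chill, heat).reset_index()
    df["date"] = df["date"].dt.date
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")
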