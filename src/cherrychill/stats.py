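"""Inference layer: one-way ANOVA, Duncan's multiple-range test, Pearson.

Starch content (and cell-layer counts) are compared across collection dates
by fixed-effects one-way ANOVA; when the F test is significant, dates are
separated into letter groups by Duncan's multiple-range test, whose critical
value for two means p ranks apart in the ordered sequence is

    R_p = q(1 - (1 - alpha)^(p-1); p, df_within) * sqrt(MSE / n)

with q the studentized-range quantile and n the (harmonic-mean) group size.
Two means are declared different iff their absolute difference exceeds the
R_p for their rank separation; letter groups are the maximal contiguous runs
of mutually non-different ordered means.

Starch is correlated with cumulative chill units up to chilling fulfillment
and with cumulative growing degree hours after it (Pearson, two-sided p via
the t transform).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InputError

__all__ = [
    "GroupedMeasurements",
    "AnovaResult",
    "DuncanResult",
    "CorrelationResult",
    "one_way_anova",
    "duncan_mrt",
    "pearson",
    "windowed_correlations",
    "significance_stars",
]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class GroupedMeasurements:
    """Observations grouped by label (typically collection date)."""

    labels: tuple
    values: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise InputError("labels and values must align")
        if len(self.labels) < 2:
            raise InputError("at least 2 groups required")
        vals = []
        for label, v in zip(self.labels, self.values):
            arr = np.asarray(v, dtype=float)
            if arr.size < 2:
                raise InputError(f"group {label!r}: at least 2 observations required")
            if not np.all(np.isfinite(arr)):
                raise InputError(f"group {label!r}: non-finite observation")
            vals.append(arr)
        object.__setattr__(self, "values", tuple(vals))
        object.__setattr__(self, "labels", tuple(self.labels))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_col: str, value_col: str):
        groups = [(lab, g[value_col].to_numpy()) for lab, g in df.groupby(label_col, sort=True)]
        return cls(labels=tuple(l for l, _ in groups), values=tuple(v for _, v in groups))

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([v.size for v in self.values])

    @property
    def balanced(self) -> bool:
        return bool(np.all(self.sizes == self.sizes[0]))

    @property
    def means(self) -> np.ndarray:
        return np.array([v.mean() for v in self.values])


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_between: float
    mse: float
    degenerate: bool = False


def one_way_anova(g: GroupedMeasurements) -> AnovaResult:
    """Classical fixed-effects decomposition; F = MS_between / MS_within."""
    allv = np.concatenate(g.values)
    if np.ptp(allv) == 0:
        raise DegenerateDataError("all observations identical; F undefined")
    grand = allv.mean()
    ss_between = float(sum(v.size * (v.mean() - grand) ** 2 for v in g.values))
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in g.values))
    df_between = g.k - 1
    df_within = allv.size - g.k
    if df_within < 1:
        raise DegenerateDataError("no within-group degrees of freedom")
    ms_between = ss_between / df_between
    mse = ss_within / df_within
    if mse == 0:
        return AnovaResult(
            F=np.inf, df_between=df_between, df_within=df_within,
            p=0.0, ms_between=ms_between, mse=0.0, degenerate=True,
        )
    F = ms_between / mse
    p = float(sps.f.sf(F, df_between, df_within))
    return AnovaResult(F=F, df_between=df_between, df_within=df_within,
                       p=p, ms_between=ms_between, mse=mse)


@dataclass(frozen=True)
class DuncanResult:
    """Ordered means with Duncan letter assignment.

    ``letters`` maps each input group label to its letter string; groups
    sharing any letter are not significantly different.
    """

    order: tuple          # labels sorted by ascending mean
    sorted_means: tuple[float, ...]
    letters: dict
    alpha: float
    r_p: tuple[float, ...]  # critical ranges for p = 2..k
    anova: AnovaResult
    metadata: dict = field(default_factory=dict)


def duncan_critical_ranges(k: int, df_within: int, mse: float, n: float, alpha: float):
    """R_p for p = 2..k using Duncan protection levels 1 - (1-alpha)^(p-1)."""
    if df_within < 1:
        raise DegenerateDataError("df_within must be >= 1")
    ps = np.arange(2, k + 1)
    protection = 1.0 - (1.0 - alpha) ** (ps - 1)
    q = sps.studentized_range.ppf(protection, ps, df_within)
    return q * np.sqrt(mse / n)


def duncan_mrt(
    g: GroupedMeasurements,
    alpha: float = 0.05,
    *,
    anova: AnovaResult | None = None,
    gate_on_anova: bool = True,
) -> DuncanResult:
    """Duncan's multiple-range letter separation of group means.

    Unbalanced designs use the harmonic-mean group size in R_p. With
    ``gate_on_anova`` (default) a non-significant overall F yields a single
    shared letter, as mean separation is only performed after a significant
    ANOVA.
    """
    if anova is None:
        anova = one_way_anova(g)
    order = np.argsort(g.means, kind="stable")
    labels = tuple(g.labels[i] for i in order)
    means = g.means[order]
    k = g.k
    n_h = k / np.sum(1.0 / g.sizes)

    if gate_on_anova and not anova.degenerate and anova.p > alpha:
        letters = {lab: "a" for lab in labels}
        return DuncanResult(
            order=labels, sorted_means=tuple(means), letters=letters, alpha=alpha,
            r_p=(), anova=anova, metadata={"gated": True, "q_method": "scipy.studentized_range"},
        )

    if anova.degenerate and anova.mse == 0:
        # zero within-group variance: any difference in means separates
        r_p = np.zeros(k - 1)
    else:
        r_p = duncan_critical_ranges(k, anova.df_within, anova.mse, n_h, alpha)

    def different(i: int, j: int) -> bool:
        """Pairwise R_p rule on the sorted means (i < j)."""
        span = j - i + 1
        return abs(means[j] - means[i]) > r_p[span - 2]

    # maximal contiguous runs of mutually non-different means
    reach = np.empty(k, dtype=int)
    for a in range(k):
        b = a
        while b + 1 < k and all(not different(i, b + 1) for i in range(a, b + 1)):
            b += 1
        reach[a] = b
    runs = []
    for a in range(k):
        if a > 0 and reach[a] <= reach[a - 1]:
            continue  # contained in an earlier run
        runs.append((a, reach[a]))

    letters = {lab: "" for lab in labels}
    for li, (a, b) in enumerate(runs):
        letter = _LETTERS[li % len(_LETTERS)]
        for i in range(a, b + 1):
            letters[labels[i]] += letter

    return DuncanResult(
        order=labels, sorted_means=tuple(means), letters=letters, alpha=alpha,
        r_p=tuple(r_p), anova=anova,
        metadata={"harmonic_n": float(n_h), "q_method": "scipy.studentized_range",
                  "balanced": g.balanced},
    )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    window: str | None = None

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def pearson(x: Sequence[float], y: Sequence[float], window: str | None = None) -> CorrelationResult:
    """Product-moment correlation with two-sided p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise InputError("at least 3 paired observations required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for a constant vector")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, p=p, n=n, window=window)


def windowed_correlations(
    starch_by_date: Sequence[tuple],
    chill_acc,
    heat_acc,
    break_date,
    *,
    min_dates: int = 3,
) -> tuple[dict, list[str]]:
    """Starch vs. CU before chilling fulfillment, vs. GDH after.

    ``starch_by_date`` pairs (date, per-date starch value); the pre window
    takes dates <= break_date against cumulative CU at each date, the post
    window dates > break_date against cumulative GDH. Windows with fewer
    than ``min_dates`` dates, or with an undefined correlation, are reported
    as None with an explanatory note.

    Returns ``({"pre_fulfillment": ..., "post_fulfillment": ...}, notes)``.
    """
    break_date = pd.Timestamp(break_date)
    pre_pairs, post_pairs = [], []
    for date, starch in starch_by_date:
        date = pd.Timestamp(date)
        if date <= break_date:
            pre_pairs.append((chill_acc.value_at(date), starch))
        elif heat_acc is not None:
            post_pairs.append((heat_acc.value_at(date), starch))

    results: dict[str, CorrelationResult | None] = {}
    notes: list[str] = []
    for name, pairs in (("pre_fulfillment", pre_pairs), ("post_fulfillment", post_pairs)):
        if len(pairs) < min_dates:
            results[name] = None
            notes.append(f"{name}: only {len(pairs)} dates (< {min_dates}); window skipped")
            continue
        xs = [p[0] for p in pairs]
        ys = [p[1] for p in pairs]
        try:
            results[name] = pearson(xs, ys, window=name)
        except DegenerateDataError as exc:
            results[name] = None
            notes.append(f"{name}: {exc}")
    return results, notes
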