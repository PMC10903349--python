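"""Behaviour, nectar-preference and wing-condition statistics.

Composition differences (behaviour categories, nectar plant genera) across
sexes or generations are tested with the chi-squared test of homogeneity;
to avoid pseudoreplication each individual can enter only once with its
first record. Wing wear (ordinal 1-4, an age proxy) is summarized as daily
means per sex -- days with fewer than five specimens are excluded -- and
regressed on time; the difference between two decay slopes is an F-test on
the time-by-group interaction in the pooled linear model. Distance and
wear comparisons between groups use the Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .events import CaptureEvent, dedupe_same_day

__all__ = [
    "DEFAULT_BEHAVIOURS",
    "first_record_table",
    "chi_squared_homogeneity",
    "daily_wing_means",
    "wing_decay_regression",
    "slope_difference_test",
    "mann_whitney_u",
    "protandry_index",
]

DEFAULT_BEHAVIOURS = (
    "flying",
    "nectaring",
    "resting",
    "basking",
    "ovipositing",
    "interacting",
)


def first_record_table(
    events: Iterable[CaptureEvent],
    factor: str = "sex",
    variable: str = "behaviour",
    dedup: bool = True,
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Contingency table of ``variable`` counts by ``factor``.

    With ``dedup`` each individual contributes only its earliest record
    (the convention used for behaviour); without it every capture event
    counts (used for per-event nectar analyses). Rows missing the variable
    (e.g. nectar genus on non-nectaring events) are skipped.
    """
    if factor not in ("sex", "generation"):
        raise ValueError("factor must be 'sex' or 'generation'")
    if variable not in ("behaviour", "nectar_genus"):
        raise ValueError("variable must be 'behaviour' or 'nectar_genus'")
    evs = sorted(events, key=lambda e: (e.individual_id, e.date))
    if variable == "nectar_genus":
        evs = [e for e in evs if e.nectar_genus]
    else:
        evs = [e for e in evs if e.behaviour]
    if dedup:
        seen: set[str] = set()
        kept = []
        for e in evs:
            if e.individual_id not in seen:
                seen.add(e.individual_id)
                kept.append(e)
        evs = kept
    if not evs:
        raise ValueError("no events carry the requested variable")
    values = [getattr(e, variable) for e in evs]
    if categories is not None:
        bad = sorted(set(values) - set(categories))
        if bad:
            raise ValueError(f"unknown {variable} categories: {bad}")
    levels = list(categories) if categories is not None else sorted(set(values))
    fac = [getattr(e, factor) for e in evs]
    tab = pd.crosstab(pd.Series(fac, name=factor), pd.Series(values, name=variable))
    tab = tab.reindex(columns=[c for c in levels if c in tab.columns], fill_value=0)
    return tab


def chi_squared_homogeneity(table: pd.DataFrame | np.ndarray, yates: bool = False) -> dict:
    """Pearson chi-squared test of homogeneity (no continuity correction).

    ``yates`` enables the continuity correction for 2x2 tables. A warning
    is emitted when any expected count is below 5.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need a table with >= 2 rows and >= 2 columns")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero row or column marginal")
    stat, p, dof, expected = stats.chi2_contingency(arr, correction=yates)
    if np.any(expected < 5):
        warnings.warn(
            f"{int((expected < 5).sum())} expected count(s) below 5; "
            "chi-squared approximation may be poor",
            stacklevel=2,
        )
    return {"chi2": float(stat), "df": int(dof), "p": float(p)}


def daily_wing_means(
    events: Iterable[CaptureEvent],
    sex: str | None = None,
    min_count: int = 5,
    dedup_same_day: bool = True,
) -> pd.DataFrame:
    """Per-day mean wing score with inclusion flag (>= ``min_count`` specimens).

    The day index counts days since the first sampling day of the series.
    """
    evs = [e for e in events if e.wing_score is not None]
    if sex is not None:
        evs = [e for e in evs if e.sex == sex]
    if dedup_same_day:
        evs = dedupe_same_day(evs)
    if not evs:
        raise ValueError("no wing scores available")
    day0 = min(e.date for e in evs)
    df = pd.DataFrame(
        {"day": [(e.date - day0).days for e in evs], "score": [e.wing_score for e in evs]}
    )
    out = (
        df.groupby("day")["score"]
        .agg(mean_score="mean", n="count")
        .reset_index()
        .sort_values("day", ignore_index=True)
    )
    out["included"] = out["n"] >= min_count
    return out


def wing_decay_regression(series: pd.DataFrame) -> dict:
    """OLS of daily mean wing score on day index, over included days.

    Returns slope, R^2, residual df, F-test p and the Pearson correlation
    of the same pairs.
    """
    use = series[series["included"]]
    if len(use) < 3:
        raise ValueError("need >= 3 included days")
    x = use["day"].to_numpy(dtype=float)
    y = use["mean_score"].to_numpy(dtype=float)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    flat = np.ptp(y) == 0
    # a constant series has undefined R^2/correlation; report the null values
    r = 0.0 if flat else float(stats.pearsonr(x, y).statistic)
    return {
        "slope": float(res.params[1]),
        "intercept": float(res.params[0]),
        "r2": 0.0 if flat else float(res.rsquared),
        "df": int(res.df_resid),
        "p": 1.0 if flat else float(res.f_pvalue),
        "pearson_r": r,
        "n_days": int(len(use)),
    }


def slope_difference_test(series_a: pd.DataFrame, series_b: pd.DataFrame) -> dict:
    """F-test of the time-by-group interaction between two wing series.

    Pools the included daily means of both series into one linear model
    mean ~ day * group and tests the interaction coefficient.
    """
    frames = []
    for label, s in (("A", series_a), ("B", series_b)):
        use = s[s["included"]]
        if len(use) < 3:
            raise ValueError(f"series {label}: need >= 3 included days")
        frames.append(use.assign(group=label))
    df = pd.concat(frames, ignore_index=True)
    g = (df["group"] == "B").astype(float).to_numpy()
    day = df["day"].to_numpy(dtype=float)
    X = sm.add_constant(np.column_stack([day, g, day * g]))
    res = sm.OLS(df["mean_score"].to_numpy(dtype=float), X).fit()
    ftest = res.f_test(np.array([[0.0, 0.0, 0.0, 1.0]]))
    return {
        "p": float(ftest.pvalue),
        "f": float(ftest.fvalue),
        "df_resid": int(res.df_resid),
        "slope_a": float(res.params[1]),
        "slope_b": float(res.params[1] + res.params[3]),
    }


def mann_whitney_u(sample_a, sample_b) -> dict:
    """Two-sided Mann-Whitney U test.

    Exact p for small untied samples (both n <= 20), normal approximation
    with tie correction otherwise.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p": float(res.pvalue), "method": method}


def _half_recruitment_day(entrants: np.ndarray, days: np.ndarray) -> float:
    """Day at which cumulative recruitment crosses 50% (linear interpolation)."""
    total = entrants.sum()
    if total <= 0:
        raise ValueError("flat/zero recruitment: protandry offset undefined")
    cum = np.cumsum(entrants) / total
    k = int(np.searchsorted(cum, 0.5))
    if k == 0:
        return float(days[0])
    prev = cum[k - 1]
    frac = (0.5 - prev) / (cum[k] - prev)
    return float(days[k - 1] + frac * (days[k] - days[k - 1]))


def protandry_index(abundance_males: pd.DataFrame, abundance_females: pd.DataFrame) -> float:
    """Protandry offset in days: positive when males recruit earlier.

    Both inputs are per-occasion frames with ``occasion`` and ``entrants``
    columns (as returned by ``PopanEstimator.derived_abundance`` subset to
    one group). The offset is the day at which females reach 50% of their
    cumulative recruitment minus the same day for males.
    """
    m = abundance_males.sort_values("occasion")
    f = abundance_females.sort_values("occasion")
    if not np.array_equal(m["occasion"].to_numpy(), f["occasion"].to_numpy()):
        raise ValueError("male and female series must share occasions")
    days = m["occasion"].to_numpy(dtype=float)
    t_m = _half_recruitment_day(m["entrants"].to_numpy(dtype=float), days)
    t_f = _half_recruitment_day(f["entrants"].to_numpy(dtype=float), days)
    return t_f - t_m
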