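"""Stratification of field records.

Three labelling schemes: latitude groups (5-degree bands from 25 to 50 degN),
yield environments (MY 5-10, HY 10-15, VHY >15 Mg ha^-1), and planting-date
windows — either the six fixed DOY map classes or latitude-anchored
VE/ER/MD/LT classes built from the earliest planting in each group.
Also provides the most-frequent-window estimator (shortest smoothed-histogram
interval covering a target fraction of plantings) and stratum summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import Dataset
from .published import FIXED_DOY_CLASSES, LATITUDE_GROUPS

UNASSIGNED = "unassigned"

YIELD_ENV_LABELS = ("MY", "HY", "VHY")

FIXED_WINDOW_LABELS = tuple(
    f"{lo}-{hi}" if hi is not None else f">{lo - 1}" for lo, hi in FIXED_DOY_CLASSES
)

ANCHORED_LABELS = ("VE", "ER", "MD", "LT")


def assign_latitude_group(latitude):
    """5-degree latitude bands; half-open [lo, hi) except 45-50 closed at 50."""
    lat = np.asarray(latitude, dtype=float)
    out = np.full(lat.shape, UNASSIGNED, dtype=object)
    for i, label in enumerate(LATITUDE_GROUPS):
        lo = 25.0 + 5.0 * i
        hi = lo + 5.0
        mask = (lat >= lo) & (lat < hi) if label != "45-50" else (lat >= lo) & (lat <= hi)
        out[mask] = label
    return out if out.ndim else out.item()


def assign_yield_environment(yield_mgha):
    """MY = [5, 10), HY = [10, 15), VHY = >= 15 Mg ha^-1; below 5 unassigned."""
    y = np.asarray(yield_mgha, dtype=float)
    out = np.full(y.shape, UNASSIGNED, dtype=object)
    out[(y >= 5) & (y < 10)] = "MY"
    out[(y >= 10) & (y < 15)] = "HY"
    out[y >= 15] = "VHY"
    return out if out.ndim else out.item()


def assign_window_fixed(planting_doy):
    """Six closed integer DOY classes (42-88, ..., >148); < 42 unassigned."""
    x = np.asarray(planting_doy)
    out = np.full(x.shape, UNASSIGNED, dtype=object)
    for (lo, hi), label in zip(FIXED_DOY_CLASSES, FIXED_WINDOW_LABELS):
        mask = (x >= lo) if hi is None else (x >= lo) & (x <= hi)
        out[mask] = label
    return out if out.ndim else out.item()


def assign_window_anchored(doys, anchor_quantile: float = 0.0):
    """Anchored VE/ER/MD/LT classes for one latitude group.

    The anchor d0 is the ``anchor_quantile`` empirical quantile of the
    group's DOYs, rounded up to an integer day (quantile 0 = earliest
    planting).  VE covers [d0, d0+10], then ER, MD, LT each span the next
    11 days; anything later (or earlier than d0) is unassigned.
    """
    x = np.asarray(doys)
    if x.size == 0:
        raise ValueError("cannot anchor windows on an empty group")
    if not 0 <= anchor_quantile < 1:
        raise ValueError("anchor_quantile must be in [0, 1)")
    d0 = int(np.ceil(np.quantile(x, anchor_quantile)))
    offset = x - d0
    out = np.full(x.shape, UNASSIGNED, dtype=object)
    for i, label in enumerate(ANCHORED_LABELS):
        out[(offset >= 11 * i) & (offset <= 11 * i + 10)] = label
    return out if out.ndim else out.item()


def smoothed_histogram(doys) -> tuple[np.ndarray, np.ndarray]:
    """1-day histogram over the observed DOY range, 7-day moving-average
    smoothed (zero-padded at the edges).  Returns (days, smoothed counts)."""
    x = np.asarray(doys, dtype=int)
    days = np.arange(x.min(), x.max() + 1)
    counts = np.bincount(x - x.min(), minlength=len(days)).astype(float)
    kernel = np.ones(7) / 7.0
    return days, np.convolve(counts, kernel, mode="same")


def most_frequent_window(doys, coverage: float = 0.5) -> tuple[int, int]:
    """Shortest integer DOY interval holding >= ``coverage`` of the smoothed
    planting-frequency mass; ties broken to the earliest interval."""
    x = np.asarray(doys, dtype=int)
    if x.size < 20:
        raise ValueError("need at least 20 observations")
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    days, smooth = smoothed_histogram(x)
    need = coverage * smooth.sum()
    csum = np.concatenate([[0.0], np.cumsum(smooth)])
    m = len(days)
    for width in range(1, m + 1):
        # mass of [i, i+width-1] for all starts i
        mass = csum[width:] - csum[:-width] if width < m else csum[[-1]]
        hits = np.nonzero(mass >= need - 1e-12)[0]
        if hits.size:
            i = int(hits[0])
            return int(days[i]), int(days[i + width - 1])
    return int(days[0]), int(days[-1])


def window_table(dataset: Dataset, coverage: float = 0.5) -> dict[str, tuple[int, int]]:
    """Most-frequent planting window per latitude group (groups with fewer
    than 20 records are skipped)."""
    df = label_dataset(dataset)
    out: dict[str, tuple[int, int]] = {}
    for g in LATITUDE_GROUPS:
        sub = df.loc[df["latitude_group"] == g, "planting_doy"]
        if len(sub) >= 20:
            out[g] = most_frequent_window(sub.to_numpy(), coverage)
    return out


def label_dataset(dataset: Dataset, anchor_quantile: float | None = None) -> pd.DataFrame:
    """Return the record table with stratum label columns appended.

    Columns added: ``latitude_group``, ``yield_env``, ``window_fixed`` and,
    when ``anchor_quantile`` is given, per-latitude-group ``window_anchored``.
    """
    df = dataset.df.copy()
    df["latitude_group"] = assign_latitude_group(df["latitude"].to_numpy())
    df["yield_env"] = assign_yield_environment(df["yield_mgha"].to_numpy())
    df["window_fixed"] = assign_window_fixed(df["planting_doy"].to_numpy())
    if anchor_quantile is not None:
        df["window_anchored"] = UNASSIGNED
        for g in LATITUDE_GROUPS:
            mask = df["latitude_group"] == g
            if mask.any():
                df.loc[mask, "window_anchored"] = assign_window_anchored(
                    df.loc[mask, "planting_doy"].to_numpy(), anchor_quantile)
    return df


STRATIFIERS = ("latitude_group", "yield_env", "window_fixed", "window_anchored")


def stratum_summary(dataset: Dataset, stratifiers, anchor_quantile: float | None = None
                    ) -> pd.DataFrame:
    """Tidy per-stratum table of n, mean, median and sd of yield."""
    strat = [stratifiers] if isinstance(stratifiers, str) else list(stratifiers)
    unknown = set(strat) - set(STRATIFIERS)
    if unknown:
        raise KeyError(f"unknown stratifier(s) {sorted(unknown)}; valid: {STRATIFIERS}")
    if "window_anchored" in strat and anchor_quantile is None:
        anchor_quantile = 0.0
    df = label_dataset(dataset, anchor_quantile)
    out = (df.groupby(strat, observed=True)["yield_mgha"]
             .agg(n="size", mean="mean", median="median", sd="std")
             .reset_index())
    return out
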