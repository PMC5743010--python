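"""Trend modelling: planting-date vs latitude sigmoid, planting-window mean
comparisons with Tukey HSD compact letters, and management profiles.

The sigmoid is the four-parameter logistic
``doy = A + (D - A) / (1 + exp(-B (lat - C)))`` fitted by bounded
least squares from a small multi-start grid.  Mean separation uses fixed-
effect one-way ANOVA with the Tukey-Kramer studentized-range criterion and
an insert-and-absorb compact letter display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares
from scipy.stats import studentized_range

from .io import Dataset
from .stratify import label_dataset, UNASSIGNED, YIELD_ENV_LABELS
from .synth import window_class


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted planting-DOY vs latitude logistic."""

    lower: float      # A, southern asymptote (DOY)
    upper: float      # D, northern asymptote (DOY)
    steepness: float  # B, per degree N
    midpoint: float   # C, degrees N
    r2: float
    n: int

    def predict(self, latitude):
        lat = np.asarray(latitude, dtype=float)
        out = self.lower + (self.upper - self.lower) / (
            1.0 + np.exp(-self.steepness * (lat - self.midpoint)))
        return out if out.ndim else float(out)


class FitError(RuntimeError):
    pass


def fit_sigmoid(latitudes, doys) -> SigmoidFit:
    """Bounded least-squares logistic fit with multi-start initialisation.

    Requires >= 8 points spanning >= 10 degrees of latitude.  Bounds:
    asymptotes in [30, 160] DOY, steepness in (0, 5] per degN, midpoint in
    [20, 55] degN.
    """
    lat = np.asarray(latitudes, dtype=float)
    doy = np.asarray(doys, dtype=float)
    if lat.size < 8:
        raise ValueError("need at least 8 points")
    if lat.max() - lat.min() < 10:
        raise ValueError("need >= 10 degrees of latitude span")

    lo = np.array([30.0, 30.0, 1e-6, 20.0])
    hi = np.array([160.0, 160.0, 5.0, 55.0])

    def resid(p):
        a, d, b, c = p
        return a + (d - a) / (1.0 + np.exp(-b * (lat - c))) - doy

    a0 = float(np.clip(np.quantile(doy, 0.05), 30, 160))
    d0 = float(np.clip(np.quantile(doy, 0.95), 30, 160))
    if d0 <= a0:
        d0 = min(160.0, a0 + 1.0)
    best = None
    for b0 in (0.15, 0.5, 1.5):
        for c0 in np.quantile(lat, [0.3, 0.5, 0.7]):
            x0 = np.clip([a0, d0, b0, c0], lo, hi)
            try:
                res = least_squares(resid, x0, bounds=(lo, hi),
                                    xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
    if best is None:
        raise FitError("sigmoid fit failed from every start")
    a, d, b, c = best.x
    sse = float(2 * best.cost)
    sst = float(np.sum((doy - doy.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return SigmoidFit(lower=a, upper=d, steepness=b, midpoint=c,
                      r2=r2, n=int(lat.size))


# ---------------------------------------------------------------------------
# Tukey HSD with compact letter display


@dataclass
class GroupComparison:
    """Group means with Tukey-HSD significance letters.

    ``table`` has one row per group (mean, se, n, letter) ordered by
    descending mean; groups sharing any letter are not significantly
    different at ``alpha``.
    """

    table: pd.DataFrame
    alpha: float
    significant: dict[tuple[str, str], bool]
    excluded: list[str]

    def shares_letter(self, g1: str, g2: str) -> bool:
        s1 = set(self.table.set_index("group").loc[g1, "letter"])
        s2 = set(self.table.set_index("group").loc[g2, "letter"])
        return bool(s1 & s2)


def _compact_letters(groups: list[str], sig: Mapping[tuple[str, str], bool]
                     ) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``groups`` must be ordered (descending mean); returns letters such that
    two groups share a letter iff their pair is not significant.
    """
    columns: list[set[str]] = [set(groups)]
    for i, gi in enumerate(groups):
        for gj in groups[i + 1:]:
            if not sig.get((gi, gj), sig.get((gj, gi), False)):
                continue
            new_cols: list[set[str]] = []
            for col in columns:
                if gi in col and gj in col:
                    new_cols.extend([col - {gi}, col - {gj}])
                else:
                    new_cols.append(col)
            # absorb: drop empty columns, strict subsets, and duplicates
            columns = []
            for c in new_cols:
                if c and not any(c < other for other in new_cols) and c not in columns:
                    columns.append(c)
    # order columns by the first (highest-mean) member they contain
    rank = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    letters = {g: "" for g in groups}
    for li, col in enumerate(columns):
        ch = chr(ord("a") + li) if li < 26 else f"({li})"
        for g in col:
            letters[g] += ch
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def tukey_compare(values_by_group: Mapping[str, np.ndarray],
                  alpha: float = 0.05) -> GroupComparison:
    """All-pairs Tukey(-Kramer) HSD over group means.

    Groups with n < 2 are excluded with a warning.  The pooled variance is
    the one-way ANOVA within-group mean square; a pair differs when
    ``|mi - mj| > q_crit * sqrt(MSE/2 * (1/ni + 1/nj))``.
    """
    clean = {}
    excluded = []
    for g, v in values_by_group.items():
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 2:
            excluded.append(str(g))
            warnings.warn(f"group {g!r} has n < 2; excluded from comparison")
        else:
            clean[str(g)] = v
    if len(clean) < 2:
        raise ValueError("need at least 2 groups with n >= 2")

    names = list(clean)
    ns = np.array([clean[g].size for g in names])
    means = np.array([clean[g].mean() for g in names])
    ses = np.array([clean[g].std(ddof=1) / np.sqrt(clean[g].size) for g in names])
    ntot = int(ns.sum())
    k = len(names)
    dfw = ntot - k
    ssw = float(sum(np.sum((clean[g] - clean[g].mean()) ** 2) for g in names))
    mse = ssw / dfw
    qcrit = float(studentized_range.ppf(1.0 - alpha, k, dfw)) if mse > 0 else 0.0

    sig: dict[tuple[str, str], bool] = {}
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(means[i] - means[j])
            if mse > 0:
                hsd = qcrit * np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                sig[(names[i], names[j])] = diff > hsd
            else:
                sig[(names[i], names[j])] = diff > 0
    order = np.argsort(-means, kind="stable")
    ordered = [names[i] for i in order]
    letters = _compact_letters(ordered, sig)
    table = pd.DataFrame({
        "group": ordered,
        "mean": means[order],
        "se": ses[order],
        "n": ns[order],
        "letter": [letters[g] for g in ordered],
    })
    return GroupComparison(table=table, alpha=alpha, significant=sig,
                           excluded=excluded)


# ---------------------------------------------------------------------------
# Planting-window effect and management profiles

WINDOW_CLASSES = ("before", "within", "after")


def classify_vs_window(doys, window: tuple[int, int]) -> np.ndarray:
    lo, hi = window
    x = np.asarray(doys)
    out = np.full(x.shape, "within", dtype=object)
    out[x < lo] = "before"
    out[x > hi] = "after"
    return out


def window_effect(dataset: Dataset, window_table: Mapping[str, tuple[int, int]],
                  latitude_group: str, by_env: bool = False, alpha: float = 0.05):
    """Compare yields before / within / after the most-frequent planting
    window of one latitude group (optionally stratified by yield
    environment).  Empty classes are dropped and listed in ``excluded``."""
    df = label_dataset(dataset)
    sub = df[df["latitude_group"] == latitude_group]
    if sub.empty:
        raise ValueError(f"no records in latitude group {latitude_group!r}")
    if latitude_group not in window_table:
        raise KeyError(f"no window for latitude group {latitude_group!r}")
    win = window_table[latitude_group]
    cls = classify_vs_window(sub["planting_doy"].to_numpy(), win)

    def compare(frame, classes):
        groups = {c: frame.loc[classes == c, "yield_mgha"].to_numpy()
                  for c in WINDOW_CLASSES}
        return tukey_compare({c: v for c, v in groups.items() if v.size >= 2},
                             alpha=alpha)

    if not by_env:
        return compare(sub, cls)
    out = {}
    for env in YIELD_ENV_LABELS:
        mask = (sub["yield_env"] == env).to_numpy()
        if mask.sum() >= 4:
            try:
                out[env] = compare(sub[mask], cls[mask])
            except ValueError:
                continue
    return out


@dataclass
class ManagementProfiles:
    """Descriptive management interaction profiles by planting window."""

    tillage: pd.DataFrame | None
    irrigation: pd.DataFrame | None
    seeding: pd.DataFrame | None


def management_profiles(dataset: Dataset, alpha: float = 0.05) -> ManagementProfiles:
    """Mean yield per (window x tillage) and (window x irrigation), plus the
    OLS slope of yield on seeding rate (per 1000 seeds ha^-1) within each
    VE/ER/MD/LT window class, with a (1-alpha) CI.  Profiles with an absent
    covariate are skipped with a warning."""
    df = dataset.df.copy()
    df["window"] = window_class(df["planting_doy"].to_numpy())

    def binned(cov):
        if df[cov].notna().sum() == 0:
            warnings.warn(f"covariate {cov!r} absent; profile skipped")
            return None
        return (df.dropna(subset=[cov])
                  .groupby(["window", cov], observed=True)["yield_mgha"]
                  .agg(n="size", mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
                  .reset_index())

    tillage = binned("tillage")
    irrigation = binned("irrigated")

    seeding = None
    if df["seeding_rate"].notna().sum() >= 3:
        rows = []
        for w in ("VE", "ER", "MD", "LT"):
            sub = df[(df["window"] == w) & df["seeding_rate"].notna()]
            if len(sub) < 3:
                continue
            x = sm.add_constant(sub["seeding_rate"].to_numpy() / 1000.0)
            fit = sm.OLS(sub["yield_mgha"].to_numpy(), x).fit()
            ci = fit.conf_int(alpha)[1]
            rows.append({"window": w, "n": len(sub), "slope_per_1000_seeds": fit.params[1],
                         "ci_lo": ci[0], "ci_hi": ci[1], "pvalue": fit.pvalues[1]})
        seeding = pd.DataFrame(rows) if rows else None
    else:
        warnings.warn("covariate 'seeding_rate' absent; profile skipped")

    return ManagementProfiles(tillage=tillage, irrigation=irrigation, seeding=seeding)
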