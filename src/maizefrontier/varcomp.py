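"""Per-factor variance-component estimation.

Each factor is treated marginally as the grouping variable of an unbalanced
one-way random-effects model and its between-group variance component is
estimated by the method of moments (ANOVA estimator), truncated at zero.
The residual ("error and interaction") row is obtained by subtracting the
factor components from the total sample variance.  Joint mixed-model fitting
is deliberately out of scope; the per-factor framing matches the individual-
effects decomposition this package reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Dataset

#: factors treated as class variables as-is
CATEGORICAL_FACTORS = ("year", "state", "county", "irrigated", "tillage",
                       "planting_doy", "dataset")
#: continuous covariates discretised (default quintiles) before grouping
CONTINUOUS_FACTORS = ("seeding_rate", "row_spacing_cm", "n_kgha", "p_kgha", "k_kgha")

DEFAULT_FACTORS = ("year", "state", "irrigated", "planting_doy", "seeding_rate",
                   "row_spacing_cm", "tillage", "n_kgha", "p_kgha", "k_kgha")


def oneway_varcomp(y, groups) -> float:
    """Unbalanced one-way ANOVA (method-of-moments) variance component.

    MSW = SSW/(N-k), MSB = SSB/(k-1), n0 = (N - sum(n_i^2)/N)/(k-1),
    sigma2_hat = max(0, (MSB - MSW)/n0).  Pairs with a missing group label
    are dropped.
    """
    y = np.asarray(y, dtype=float)
    g = pd.Series(groups)
    keep = g.notna().to_numpy() & np.isfinite(y)
    y, g = y[keep], g[keep]
    codes, levels = pd.factorize(g)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 factor levels")
    n = len(y)
    if n <= k:
        raise ValueError("need more observations than levels")
    counts = np.bincount(codes)
    sums = np.bincount(codes, weights=y)
    means = sums / counts
    grand = y.mean()
    ssw = float(np.sum((y - means[codes]) ** 2))
    ssb = float(np.sum(counts * (means - grand) ** 2))
    msw = ssw / (n - k)
    msb = ssb / (k - 1)
    n0 = (n - np.sum(counts.astype(float) ** 2) / n) / (k - 1)
    return max(0.0, (msb - msw) / n0)


@dataclass
class VarianceTable:
    """Per-factor variance components with percent-of-total shares."""

    factors: list[str]
    components: dict[str, float]
    total_variance: float
    error_component: float
    components_sum: float = field(init=False)

    def __post_init__(self):
        self.components_sum = sum(self.components.values()) + self.error_component

    def share_unrounded(self, factor: str) -> float:
        comp = (self.error_component if factor == "error_interaction"
                else self.components[factor])
        return 100.0 * comp / self.total_variance

    def share_pct(self, factor: str) -> int:
        return int(round(self.share_unrounded(factor)))

    def to_frame(self) -> pd.DataFrame:
        rows = [(f, self.components[f], self.share_unrounded(f), self.share_pct(f))
                for f in self.factors]
        rows.append(("error_interaction", self.error_component,
                     self.share_unrounded("error_interaction"),
                     self.share_pct("error_interaction")))
        return pd.DataFrame(rows, columns=["factor", "component",
                                           "share_pct_unrounded", "share_pct"])


def shares_from_components(components: Mapping[str, float],
                           total_variance: float | None = None) -> VarianceTable:
    """Build a VarianceTable directly from known per-factor components
    (e.g. a published decomposition); the residual row may be supplied as
    ``error_interaction`` or derived by subtraction from the total."""
    comps = dict(components)
    error = comps.pop("error_interaction", None)
    if total_variance is None:
        if error is None:
            raise ValueError("need total_variance or an error_interaction component")
        total_variance = sum(comps.values()) + error
    if error is None:
        error = max(0.0, total_variance - sum(comps.values()))
    return VarianceTable(factors=list(comps), components=comps,
                         total_variance=float(total_variance),
                         error_component=float(error))


def build_variance_table(dataset: Dataset,
                         factors: Sequence[str] = DEFAULT_FACTORS,
                         bins: int = 5) -> VarianceTable:
    """Marginal variance decomposition of yield over the given factors.

    Continuous covariates are discretised into ``bins`` quantile bins before
    grouping; a factor with a single observed level contributes 0 with a
    warning.  The residual row is total sample variance minus the factor
    components, floored at 0.
    """
    df = dataset.df
    y = df["yield_mgha"].to_numpy(dtype=float)
    total = float(np.var(y, ddof=1))
    comps: dict[str, float] = {}
    for f in factors:
        if f not in df.columns:
            raise KeyError(f"unknown factor {f!r}")
        col = df[f]
        if f in CONTINUOUS_FACTORS and col.nunique(dropna=True) > bins:
            col = pd.qcut(col.astype(float), q=bins, duplicates="drop")
        if col.nunique(dropna=True) < 2:
            warnings.warn(f"factor {f!r} has a single level; component set to 0")
            comps[f] = 0.0
            continue
        comps[f] = oneway_varcomp(y, col)
    error = max(0.0, total - sum(comps.values()))
    return VarianceTable(factors=list(factors), components=comps,
                         total_variance=total, error_component=error)
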