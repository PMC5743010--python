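"""Synthetic field-record generator.

The contest-winner database behind the original synthesis is not publicly
deposited, so every downstream stage here is exercised on synthetic data that
reproduces its documented statistical structure:

* a sigmoidal planting-DOY vs latitude relation (~60 DOY in the mid-20s degN
  rising to ~120 DOY by 50 degN), with Gaussian planting-date scatter;
* an upper yield frontier that is flat at a plateau P up to a breakpoint
  DOY and then declines linearly (slope s <= 0);
* yields generated as ``frontier(doy) * (1 - W) + covariate effects + noise``
  where W is a below-frontier shortfall fraction (zero-inflated Beta), so the
  configured frontier is the ~0.99 upper envelope of the scatter;
* heavier record frequency at 35-45 degN;
* year and state random effects (carried inside the shortfall so the frontier
  stays a hard envelope) and tillage/irrigation/seeding-rate effects whose
  sign can flip with planting window.

Two presets ship: ``contest_like`` (plateau 21 Mg/ha, breakpoint 152 DOY,
mean ~14.8 Mg/ha) and ``literature_like`` (plateau 18, breakpoint 123, lower
mean and wider spread).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .io import Dataset, NORMALIZED_COLUMNS
from .published import LATITUDE_GROUPS, VE_ER_MD_LT_CLASSES

DOY_CLAMP = (40, 200)

#: plausible states per latitude group (labels only; no geocoding implied)
_STATES_BY_GROUP = {
    "25-30": ("TX", "FL", "LA"),
    "30-35": ("GA", "MS", "AL", "SC"),
    "35-40": ("KS", "MO", "KY", "VA", "IL"),
    "40-45": ("IA", "NE", "IN", "OH", "SD"),
    "45-50": ("MN", "ND", "WI", "MI"),
}


@dataclass(frozen=True)
class SigmoidParams:
    """Four-parameter logistic for expected planting DOY vs latitude."""

    lower: float = 58.0      # southern asymptote, DOY
    upper: float = 122.0     # northern asymptote, DOY
    steepness: float = 0.45  # per degree N
    midpoint: float = 31.0   # degrees N

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("sigmoid lower asymptote must be below upper")


@dataclass(frozen=True)
class FrontierParams:
    """Linear-plateau upper boundary of yield vs planting DOY."""

    plateau: float = 21.0      # Mg ha^-1
    breakpoint: float = 152.0  # DOY
    slope: float = -0.055      # Mg ha^-1 day^-1, <= 0

    def __post_init__(self):
        if self.plateau <= 0:
            raise ValueError("plateau must be positive")
        if self.slope > 0:
            raise ValueError("frontier slope must be <= 0")


@dataclass(frozen=True)
class ShortfallParams:
    """Zero-inflated Beta distribution of the below-frontier deficit W.

    With probability ``p_zero`` a field sits exactly on the frontier
    (before year/state perturbation and additive noise); otherwise
    W ~ Beta(mean*conc, (1-mean)*conc).
    """

    p_zero: float = 0.07
    mean: float = 0.3165
    conc: float = 21.0

    def __post_init__(self):
        if not 0 <= self.p_zero < 1:
            raise ValueError("p_zero must be in [0, 1)")
        if not 0 < self.mean < 1 or self.conc <= 0:
            raise ValueError("invalid Beta shortfall shape")


@dataclass(frozen=True)
class CovariateEffects:
    """Additive management effects (Mg ha^-1) by planting window class.

    ``seeding_rate_slope`` is per 1000 seeds ha^-1 deviation from 85k.
    Windows are the global VE/ER/MD/LT DOY classes; dates past the LT class
    reuse the LT effects.
    """

    seeding_rate_slope: Mapping[str, float] = field(default_factory=lambda: {
        "VE": -0.015, "ER": -0.006, "MD": 0.0, "LT": 0.006})
    tillage: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: {
        "VE": {"CT": 0.25, "NT": -0.15, "RT": -0.10},
        "ER": {"CT": 0.0, "NT": 0.0, "RT": 0.0},
        "MD": {"CT": 0.0, "NT": 0.0, "RT": 0.0},
        "LT": {"CT": -0.20, "NT": 0.15, "RT": 0.15}})
    irrigated: Mapping[str, float] = field(default_factory=lambda: {
        "VE": -0.25, "ER": -0.10, "MD": 0.05, "LT": 0.25})

    def bound(self) -> float:
        """Upper bound on the total positive effect at any record."""
        b = max((abs(v) for v in self.seeding_rate_slope.values()), default=0.0) * 45.0
        b += max((abs(v) for d in self.tillage.values() for v in d.values()), default=0.0)
        b += max((abs(v) for v in self.irrigated.values()), default=0.0)
        return b


@dataclass(frozen=True)
class SyntheticConfig:
    """Complete generator parameterisation; fixed seed => identical output."""

    n: int = 16171
    latitude_weights: tuple[float, ...] = (0.05, 0.15, 0.30, 0.35, 0.15)
    sigmoid_params: SigmoidParams = field(default_factory=SigmoidParams)
    doy_sd: float = 7.0
    late_frac: float = 0.10    # fraction of fields replanted / weather-delayed
    late_scale: float = 30.0   # mean extra delay (days) for those fields
    frontier_params: FrontierParams = field(default_factory=FrontierParams)
    shortfall: ShortfallParams = field(default_factory=ShortfallParams)
    noise_sd: float = 0.08
    year_effect_sd: float = 0.020   # shortfall units (fraction of frontier)
    state_effect_sd: float = 0.020  # shortfall units
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    missing_rate: float = 0.02
    dataset_tag: str = "contest"
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        w = np.asarray(self.latitude_weights, dtype=float)
        if len(w) != len(LATITUDE_GROUPS) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("latitude_weights must be 5 non-negative probabilities summing to 1")
        if self.doy_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def contest_like(**overrides) -> SyntheticConfig:
    """Preset emulating the contest-winner database (mean ~14.8 Mg/ha)."""
    return replace(SyntheticConfig(), **overrides)


def literature_like(**overrides) -> SyntheticConfig:
    """Preset emulating the literature compilation: lower plateau (18 Mg/ha),
    earlier breakpoint (123 DOY), lower mean and wider spread."""
    base = SyntheticConfig(
        n=819,
        frontier_params=FrontierParams(plateau=18.0, breakpoint=123.0, slope=-0.055),
        shortfall=ShortfallParams(p_zero=0.06, mean=0.41, conc=8.0),
        noise_sd=0.10,
        dataset_tag="literature",
    )
    return replace(base, **overrides)


PRESETS = {"contest_like": contest_like, "literature_like": literature_like}


def sigmoid_mean_doy(latitude, params: SigmoidParams = SigmoidParams()):
    """Expected planting DOY at a latitude (four-parameter logistic)."""
    lat = np.asarray(latitude, dtype=float)
    a, d, b, c = params.lower, params.upper, params.steepness, params.midpoint
    out = a + (d - a) / (1.0 + np.exp(-b * (lat - c)))
    return out if out.ndim else float(out)


def true_frontier(doy, params: FrontierParams = FrontierParams()):
    """Boundary yield at a planting DOY: plateau then linear decline."""
    x = np.asarray(doy, dtype=float)
    out = params.plateau + params.slope * np.maximum(0.0, x - params.breakpoint)
    return out if out.ndim else float(out)


def window_class(doy) -> np.ndarray:
    """Map DOY to the global VE/ER/MD/LT classes (dates past LT fold into LT,
    dates before VE into VE); used for generator effect assignment."""
    x = np.asarray(doy)
    out = np.full(x.shape, "LT", dtype=object)
    for name in ("MD", "ER", "VE"):
        lo, hi = VE_ER_MD_LT_CLASSES[name]
        out[x <= hi] = name
    return out


def _group_bounds(gi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = 25.0 + 5.0 * gi
    return lo, lo + 5.0


def gen_dataset(config: SyntheticConfig) -> Dataset:
    """Draw ``config.n`` field records; reproducible for a fixed seed."""
    cfg = config  # validation happened in __post_init__
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    gi = rng.choice(len(LATITUDE_GROUPS), size=n, p=np.asarray(cfg.latitude_weights, float))
    lo, hi = _group_bounds(gi)
    lat = rng.uniform(lo, hi)

    mean_doy = sigmoid_mean_doy(lat, cfg.sigmoid_params)
    # right-skewed scatter: Gaussian field-to-field spread plus an
    # exponential delay tail (replanting / wet-spring postponements)
    scatter = rng.normal(0.0, cfg.doy_sd, n)
    if cfg.late_frac > 0:
        late = rng.random(n) < cfg.late_frac
        scatter = scatter + np.where(late, rng.exponential(cfg.late_scale, n), 0.0)
    doy = np.rint(np.clip(mean_doy + scatter, *DOY_CLAMP)).astype(int)

    years = np.arange(2011, 2017)
    year = rng.choice(years, size=n)
    # effects are demeaned so the marginal mean does not drift seed-to-seed
    year_eff = rng.normal(0.0, cfg.year_effect_sd, len(years))
    year_eff -= year_eff.mean()
    states = sorted({s for g in LATITUDE_GROUPS for s in _STATES_BY_GROUP[g]})
    raw = rng.normal(0.0, cfg.state_effect_sd, len(states))
    state_eff = dict(zip(states, raw - raw.mean()))
    state = np.array([
        _STATES_BY_GROUP[LATITUDE_GROUPS[g]][k]
        for g, k in zip(gi, rng.integers(0, 3, n))
    ], dtype=object)
    county = np.array([f"{s}-{c:03d}" for s, c in zip(state, rng.integers(1, 60, n))],
                      dtype=object)

    # shortfall fraction: zero-inflated Beta, perturbed by year/state effects,
    # clipped at 0 so the frontier remains a hard envelope
    sf = cfg.shortfall
    w0 = np.where(
        rng.random(n) < sf.p_zero, 0.0,
        rng.beta(sf.mean * sf.conc, (1.0 - sf.mean) * sf.conc, n))
    w = np.clip(w0 + year_eff[year - 2011] + np.array([state_eff[s] for s in state]),
                0.0, 0.95)

    tillage = rng.choice(np.array(["CT", "NT", "RT"], dtype=object), size=n,
                         p=[0.45, 0.35, 0.20])
    irrigated = rng.random(n) < 0.25
    seeding = np.clip(rng.normal(85_000, 15_000, n), 40_000, 130_000)
    row_spacing = np.where(rng.random(n) < 0.8, 76.0, 51.0)
    n_rate = np.clip(rng.normal(220, 40, n), 50, 400)
    p_rate = np.clip(rng.normal(90, 25, n), 10, 250)
    k_rate = np.clip(rng.normal(90, 30, n), 10, 300)

    wc = window_class(doy)
    eff = cfg.covariate_effects
    c = np.array([eff.seeding_rate_slope[w_] for w_ in wc]) * (seeding - 85_000) / 1000.0
    c += np.array([eff.tillage[w_][t] for w_, t in zip(wc, tillage)])
    c += np.where(irrigated, np.array([eff.irrigated[w_] for w_ in wc]), 0.0)

    y = true_frontier(doy, cfg.frontier_params) * (1.0 - w)
    y = y + c + (rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else 0.0)
    y = np.maximum(1e-3, y)

    df = pd.DataFrame({
        "year": pd.array(year, dtype="Int64"),
        "state": state,
        "county": county,
        "latitude": lat,
        "planting_doy": doy,
        "yield_mgha": y,
        "irrigated": pd.array(irrigated, dtype="boolean"),
        "tillage": tillage,
        "row_spacing_cm": row_spacing,
        "seeding_rate": seeding,
        "n_kgha": n_rate,
        "p_kgha": p_rate,
        "k_kgha": k_rate,
        "dataset": cfg.dataset_tag,
    }, columns=list(NORMALIZED_COLUMNS))

    if cfg.missing_rate > 0:
        for col in ("irrigated", "tillage", "row_spacing_cm",
                    "n_kgha", "p_kgha", "k_kgha"):
            mask = rng.random(n) < cfg.missing_rate
            df.loc[mask, col] = pd.NA if col in ("irrigated", "tillage") else np.nan

    return Dataset(df=df, provenance=f"synthetic:{cfg.dataset_tag}:seed={cfg.seed}")


def config_to_dict(cfg: SyntheticConfig) -> dict:
    return asdict(cfg)


def config_from_dict(d: Mapping) -> SyntheticConfig:
    d = dict(d)
    for key, cls in (("sigmoid_params", SigmoidParams), ("frontier_params", FrontierParams),
                     ("shortfall", ShortfallParams), ("covariate_effects", CovariateEffects)):
        if key in d and isinstance(d[key], Mapping):
            d[key] = cls(**d[key])
    if "latitude_weights" in d:
        d["latitude_weights"] = tuple(d["latitude_weights"])
    return SyntheticConfig(**d)
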