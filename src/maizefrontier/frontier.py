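"""Quantile linear-plateau (bi-linear) yield-frontier analysis.

The boundary of yield vs planting DOY is modelled as
``f(x) = P + s * max(0, x - beta)`` with plateau P, breakpoint beta and
slope s <= 0, fitted at a high conditional quantile (tau = 0.99 by default)
by minimising total pinball loss.  The breakpoint is profiled over an
integer-day grid; for each candidate breakpoint the remaining two-parameter
quantile regression is solved exactly:

* the inner problem in P for a fixed slope is a plain order-statistic
  quantile of the slope-adjusted responses;
* the profiled loss is convex and piecewise linear in the slope, so small
  problems are solved by enumerating every pairwise candidate slope (the
  vertex set of the underlying linear programme) and large problems by a
  bracketing grid-shrink on the 1-D profiled loss.

For large datasets, points far below the boundary are pruned (per-10-day-bin
0.95 yield quantile) and carried as an exact affine term in the loss; the
reduction is valid whenever every pruned point stays below the fitted
boundary, which is verified after the fit (a violation triggers an unpruned
refit).  Bootstrap confidence intervals use case resampling with percentile
2.5/97.5 endpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Dataset

#: loss tie tolerance for breakpoint selection (ties -> smallest breakpoint)
TIE_TOL = 1e-9
#: problems with at most this many candidate slope pairs are solved exactly
EXACT_PAIR_LIMIT = 120_000
#: pruning engages above this sample size (when prune="auto")
PRUNE_MIN_N = 600
PRUNE_BIN_DAYS = 10
PRUNE_QUANTILE = 0.95
PRUNE_MIN_BIN = 50


def pinball_loss(u, tau: float):
    """Quantile (pinball) loss ``rho_tau(u) = u * (tau - 1[u < 0])``."""
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    u = np.asarray(u, dtype=float)
    out = np.where(u >= 0, tau * u, (tau - 1.0) * u)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ConditionalFit:
    """Plateau/slope fit at a fixed breakpoint."""

    plateau: float
    slope: float
    loss: float
    degenerate: bool = False


@dataclass(frozen=True)
class FrontierFit:
    """Fitted quantile linear-plateau boundary."""

    plateau: float
    breakpoint: float
    slope: float
    tau: float
    loss: float
    n: int
    frac_above: float
    degenerate: bool = False

    def predict(self, doy):
        x = np.asarray(doy, dtype=float)
        out = self.plateau + self.slope * np.maximum(0.0, x - self.breakpoint)
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {"plateau": self.plateau, "breakpoint": self.breakpoint,
                "slope": self.slope, "tau": self.tau, "loss": self.loss,
                "n": self.n, "frac_above": self.frac_above,
                "degenerate": self.degenerate}


@dataclass
class BootstrapResult:
    """Case-resampling bootstrap of a frontier fit."""

    fit: FrontierFit
    ci_plateau: tuple[float, float]
    ci_breakpoint: tuple[float, float]
    ci_slope: tuple[float, float]
    B: int
    seed: int
    replicates: pd.DataFrame = field(repr=False, default=None)
    n_degenerate: int = 0

    def to_dict(self) -> dict:
        d = self.fit.to_dict()
        d.update({"ci_plateau": list(self.ci_plateau),
                  "ci_breakpoint": list(self.ci_breakpoint),
                  "ci_slope": list(self.ci_slope),
                  "B": self.B, "seed": self.seed,
                  "n_degenerate": self.n_degenerate})
        return d


# ---------------------------------------------------------------------------
# conditional (fixed-breakpoint) solver


def _quantile_index(n_kept: int, m_pruned: int, tau: float) -> int:
    """Order-statistic index (1-based, within kept values) of the tau-quantile
    of the full sample when ``m_pruned`` values are known to lie below it."""
    k = int(np.ceil((n_kept + m_pruned) * tau - 1e-9)) - m_pruned
    return min(max(k, 1), n_kept)


def _eval_slopes(slopes, z, y, tau, m=0, sz=0.0, sy=0.0):
    """Loss (with optimal plateau) for each candidate slope; vectorised."""
    s = np.atleast_1d(np.asarray(slopes, dtype=float))
    v = y[None, :] - s[:, None] * z[None, :]
    k = _quantile_index(y.size, m, tau)
    p = np.partition(v, k - 1, axis=1)[:, k - 1]
    u = v - p[:, None]
    loss = np.where(u >= 0, tau * u, (tau - 1.0) * u).sum(axis=1)
    if m:
        loss = loss + (1.0 - tau) * (m * p + s * sz - sy)
    return p, loss


def _conditional(z, y, tau, m=0, sz=0.0, sy=0.0, slope_tol=1e-12,
                 allow_exact=True) -> ConditionalFit:
    n = y.size
    beyond = z > 0
    nz = int(beyond.sum())
    if nz < 2:
        p, loss = _eval_slopes(0.0, z, y, tau, m, sz, sy)
        return ConditionalFit(float(p[0]), 0.0, float(loss[0]), degenerate=True)

    n_pairs = nz * n
    if allow_exact and m == 0 and n_pairs <= EXACT_PAIR_LIMIT and n <= 400:
        yb, zb = y[beyond], z[beyond]
        dz = zb[:, None] - z[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            cand = (yb[:, None] - y[None, :]) / dz
        cand = cand[np.isfinite(cand) & (cand <= 0)]
        cand = np.unique(np.concatenate([cand.ravel(), [0.0]]))
        best = (np.inf, 0.0, 0.0)
        for lo in range(0, cand.size, 1024):
            chunk = cand[lo:lo + 1024]
            p, loss = _eval_slopes(chunk, z, y, tau, m, sz, sy)
            i = int(np.argmin(loss))
            if loss[i] < best[0]:
                best = (float(loss[i]), float(chunk[i]), float(p[i]))
        return ConditionalFit(best[2], best[1], best[0])

    # convex 1-D grid-shrink on the profiled loss (slope direction);
    # slope-magnitude bracket assumes day-resolution planting dates
    yrange = float(y.max() - y.min())
    s_lo = -(yrange + 1.0) / min(1.0, max(float(z[beyond].min()), 1e-3))
    lo, hi = s_lo, 0.0
    best_s, best_p, best_loss = 0.0, np.nan, np.inf
    width = hi - lo
    rounds = max(4, int(np.ceil(np.log(max(width, slope_tol) / slope_tol) / np.log(8.0))))
    for _ in range(rounds):
        grid = np.linspace(lo, hi, 17)
        p, loss = _eval_slopes(grid, z, y, tau, m, sz, sy)
        i = int(np.argmin(loss))
        if loss[i] < best_loss:
            best_loss, best_s, best_p = float(loss[i]), float(grid[i]), float(p[i])
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, 16)]
    p0, loss0 = _eval_slopes(0.0, z, y, tau, m, sz, sy)
    if loss0[0] <= best_loss:
        best_loss, best_s, best_p = float(loss0[0]), 0.0, float(p0[0])
    return ConditionalFit(best_p, best_s, best_loss)


def fit_conditional(x, y, beta: float, tau: float) -> ConditionalFit:
    """Exact (P, s) quantile fit of ``P + s*max(0, x - beta)`` with s <= 0.

    With fewer than 2 points beyond the breakpoint the slope is
    unidentified: returns s = 0 flagged degenerate, with P the tau-quantile.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    return _conditional(np.maximum(0.0, x - beta), y, tau)


# ---------------------------------------------------------------------------
# breakpoint profiling


def _beta_grid(x, grid_step, beta_bounds=None):
    lo = int(np.ceil(x.min())) + 2
    hi = int(np.floor(x.max())) - 2
    if beta_bounds is not None:
        lo = max(lo, int(np.ceil(beta_bounds[0])))
        hi = min(hi, int(np.floor(beta_bounds[1])))
    if hi < lo:
        lo = hi = int(round((x.min() + x.max()) / 2))
    return np.arange(lo, hi + 1, grid_step)


def _prune(x, y):
    """Keep points at/above their 10-day bin's 0.95 yield quantile."""
    bins = np.floor(x / PRUNE_BIN_DAYS).astype(int)
    keep = np.ones(x.size, dtype=bool)
    for b in np.unique(bins):
        mask = bins == b
        if mask.sum() >= PRUNE_MIN_BIN:
            thr = np.quantile(y[mask], PRUNE_QUANTILE)
            keep[mask] = y[mask] >= thr
    return keep


def fit_frontier(x, y, tau: float = 0.99, grid_step: int = 1,
                 prune: bool | str = "auto", beta_bounds=None,
                 coarse_step: int | None = None,
                 slope_tol: float = 1e-12, allow_exact: bool = True) -> FrontierFit:
    """Fit the quantile linear-plateau boundary, profiling the breakpoint
    over an integer-day grid from min(x)+2 to max(x)-2.

    Ties in profiled loss (within 1e-9) resolve to the smallest breakpoint.
    ``beta_bounds`` optionally clips the profiling grid and ``coarse_step``
    profiles a coarse grid first and refines around its optimum (both used
    by the bootstrap); ``prune`` may be True, False or "auto" (n > 600).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 points")
    if x.max() - x.min() < 10:
        raise ValueError("DOY span must be at least 10 days")
    betas = _beta_grid(x, grid_step, beta_bounds)

    do_prune = prune is True or (prune == "auto" and n > PRUNE_MIN_N)
    if do_prune:
        keep = _prune(x, y)
        xk, yk = x[keep], y[keep]
        xp = np.sort(x[~keep])
        m = xp.size
        sy = float(y[~keep].sum())
        suffix = np.concatenate([np.cumsum(xp[::-1])[::-1], [0.0]])
    else:
        xk, yk = x, y
        m, sy = 0, 0.0
        xp = suffix = None

    def profile(grid):
        best_ = None
        best_loss = np.inf
        for beta in grid:
            if m:
                idx = int(np.searchsorted(xp, beta, side="right"))
                sz = float(suffix[idx] - (m - idx) * beta)
            else:
                sz = 0.0
            cf = _conditional(np.maximum(0.0, xk - beta), yk, tau, m, sz, sy,
                              slope_tol, allow_exact)
            if cf.loss < best_loss - TIE_TOL:
                best_loss = cf.loss
                best_ = (float(beta), cf)
        return best_

    if coarse_step and coarse_step > grid_step and len(betas) > 2 * coarse_step:
        b0, _ = profile(betas[::coarse_step])
        fine = betas[(betas >= b0 - coarse_step) & (betas <= b0 + coarse_step)]
        beta, cf = profile(fine)
    else:
        beta, cf = profile(betas)

    if do_prune:
        yhat_pruned = cf.plateau + cf.slope * np.maximum(0.0, x[~keep] - beta)
        if np.any(y[~keep] > yhat_pruned + 1e-9):
            return fit_frontier(x, y, tau, grid_step, prune=False,
                                beta_bounds=beta_bounds, coarse_step=coarse_step,
                                slope_tol=slope_tol, allow_exact=allow_exact)
    yhat = cf.plateau + cf.slope * np.maximum(0.0, x - beta)
    frac_above = float(np.mean(y > yhat + 1e-12))
    return FrontierFit(plateau=cf.plateau, breakpoint=beta, slope=cf.slope,
                       tau=tau, loss=cf.loss, n=n, frac_above=frac_above,
                       degenerate=cf.degenerate)


def frontier_oracle(x, y, tau: float, grid_step: int = 1) -> FrontierFit:
    """Brute-force reference fit (n <= 200): for every grid breakpoint,
    enumerate every line through two data points (in plateau coordinates)
    plus every flat line through one point, and take the global pinball-loss
    minimum with the same tie rules as :func:`fit_frontier`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > 200:
        raise ValueError("oracle refuses n > 200 (combinatorial guard)")
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    betas = _beta_grid(x, grid_step)
    best = None
    best_loss = np.inf
    for beta in betas:
        z = np.maximum(0.0, x - beta)
        dz = z[:, None] - z[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            s_pair = (y[:, None] - y[None, :]) / dz
            p_pair = y[:, None] - s_pair * z[:, None]
        ok = np.isfinite(s_pair) & (s_pair <= 0)
        ps = np.concatenate([p_pair[ok].ravel(), y])
        ss = np.concatenate([s_pair[ok].ravel(), np.zeros(n)])
        resid = y[None, :] - (ps[:, None] + ss[:, None] * z[None, :])
        loss = np.where(resid >= 0, tau * resid, (tau - 1.0) * resid).sum(axis=1)
        i = int(np.argmin(loss))
        if loss[i] < best_loss - TIE_TOL:
            best_loss = float(loss[i])
            best = (float(beta), float(ps[i]), float(ss[i]))
    beta, p, s = best
    yhat = p + s * np.maximum(0.0, x - beta)
    return FrontierFit(plateau=p, breakpoint=beta, slope=s, tau=tau,
                       loss=best_loss, n=n,
                       frac_above=float(np.mean(y > yhat + 1e-12)))


# ---------------------------------------------------------------------------
# bootstrap and dataset comparison


def bootstrap_frontier(x, y, tau: float = 0.99, B: int = 500, seed: int = 0,
                       grid_step: int = 1, beta_window: float = 30.0,
                       prune: bool | str = "auto") -> BootstrapResult:
    """Case-resampling bootstrap (B >= 200) with percentile 95% intervals.

    Replicate fits profile the breakpoint only within ``beta_window`` days
    of the full-data estimate (the profiled loss is flat far from the
    optimum, and the restriction keeps B large affordable).  Degenerate
    replicates (unidentified slope) are retained and counted; more than 20%
    attaches a warning.
    """
    if B < 200:
        raise ValueError("need B >= 200 bootstrap replicates")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fit0 = fit_frontier(x, y, tau, grid_step, prune)
    bounds = (fit0.breakpoint - beta_window, fit0.breakpoint + beta_window)
    rng = np.random.default_rng(seed)
    rows = np.empty((B, 3))
    n_deg = 0
    for b in range(B):
        idx = rng.integers(0, x.size, x.size)
        fb = fit_frontier(x[idx], y[idx], tau, grid_step, prune,
                          beta_bounds=bounds, coarse_step=3 * grid_step,
                          slope_tol=1e-6, allow_exact=False)
        rows[b] = (fb.plateau, fb.breakpoint, fb.slope)
        n_deg += fb.degenerate
    if n_deg > 0.2 * B:
        warnings.warn(f"{n_deg}/{B} bootstrap replicates had an unidentified "
                      "slope; intervals may be unreliable")
    reps = pd.DataFrame(rows, columns=["plateau", "breakpoint", "slope"])
    ci = {c: tuple(np.percentile(reps[c], [2.5, 97.5])) for c in reps.columns}
    return BootstrapResult(fit=fit0, ci_plateau=ci["plateau"],
                           ci_breakpoint=ci["breakpoint"], ci_slope=ci["slope"],
                           B=B, seed=seed, replicates=reps, n_degenerate=n_deg)


def equalize_combine(large: Dataset, small: Dataset, seed: int = 0
                     ) -> tuple[Dataset, Dataset]:
    """Equalise dataset sizes by one seeded with-replacement draw of
    ``small.n`` records from the larger dataset, and return it together with
    the union (combined) dataset of n = 2 * small.n records."""
    if large.n < small.n:
        warnings.warn("datasets passed in reversed size order; swapping")
        large, small = small, large
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, large.n, small.n)
    resampled = Dataset(df=large.df.iloc[idx].reset_index(drop=True),
                        provenance=f"{large.provenance}:resampled(n={small.n},seed={seed})")
    combined = Dataset(
        df=pd.concat([resampled.df, small.df], ignore_index=True),
        provenance="combined")
    return resampled, combined


def equalized_frontier_replicates(large: Dataset, small: Dataset, tau: float = 0.99,
                                  R: int = 100, seed: int = 0,
                                  grid_step: int = 1) -> pd.DataFrame:
    """Robustness mode: repeat the equalisation draw R times and fit the
    combined frontier each time; returns per-replicate parameters."""
    rows = []
    rng = np.random.default_rng(seed)
    for _ in range(R):
        _, combined = equalize_combine(large, small, seed=int(rng.integers(2**31)))
        fit = fit_frontier(combined.df["planting_doy"].to_numpy(),
                           combined.df["yield_mgha"].to_numpy(), tau, grid_step)
        rows.append((fit.plateau, fit.breakpoint, fit.slope))
    return pd.DataFrame(rows, columns=["plateau", "breakpoint", "slope"])


def compare_frontiers(a: BootstrapResult, b: BootstrapResult) -> dict:
    """Per-parameter verdicts: "different" iff the two 95% CIs do not
    overlap.  ``overlap`` is the shared interval length (negative = gap)."""
    if a.fit.tau != b.fit.tau:
        raise ValueError("cannot compare fits at different tau")
    out = {}
    for name, ia, ib in (("plateau", a.ci_plateau, b.ci_plateau),
                         ("breakpoint", a.ci_breakpoint, b.ci_breakpoint),
                         ("slope", a.ci_slope, b.ci_slope)):
        overlap = min(ia[1], ib[1]) - max(ia[0], ib[0])
        out[name] = {"different": bool(overlap < 0), "overlap": float(overlap),
                     "ci_a": list(ia), "ci_b": list(ib)}
    return out
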