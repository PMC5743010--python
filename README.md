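# maizefrontier

Planting-date / yield synthesis analysis for high-yielding maize (*Zea mays*
L.) production systems.

When should maize be planted to keep the *attainable* yield on its plateau?
National yield-contest records and three decades of field literature show
yields flat across a wide planting window and then declining once planting
is delayed past a latitude-dependent date.  `maizefrontier` is a tested
re-implementation of that synthesis workflow for agronomists and
biostatisticians:

* **Ingestion** of tabular field records (CSV) with unit consolidation to
  Mg ha⁻¹ at 155 g kg⁻¹ grain moisture and calendar-date → day-of-year
  (DOY) conversion;
* **Stratification** into latitude groups (25–50 °N in 5° bands), yield
  environments (MY 5–10, HY 10–15, VHY > 15 Mg ha⁻¹) and planting-date
  windows, plus most-frequent-window estimation;
* **Variance components**: marginal one-way method-of-moments
  decomposition of yield over environment and management factors;
* **Trends**: the four-parameter logistic planting-date–latitude fit
  `doy = A + (D−A)/(1+exp(−B(lat−C)))`, Tukey-HSD window comparisons with
  compact letters, and management interaction profiles;
* **Frontier analysis** (the core): the 0.99-quantile linear-plateau
  boundary `f(doy) = P + s·max(0, doy − β)` with `s ≤ 0`, fitted by exact
  pinball-loss minimisation with the breakpoint profiled on an integer-day
  grid, case-resampling bootstrap 95% CIs, dataset-size equalization, a
  combined model, and CI-overlap parameter comparisons;
* **Synthetic data**: the contest database is not publicly deposited, so a
  first-class generator emulates it — sigmoidal planting-date/latitude
  structure, a configurable linear-plateau yield frontier with
  zero-inflated-Beta shortfall below it, year/state effects and
  window-dependent management effects.  Presets: `contest_like`
  (P = 21 Mg ha⁻¹, β = 152 DOY, mean ≈ 14.8) and `literature_like`
  (P = 18, β = 123, wider spread).

See `docs/methods.md` for models, estimators and calibration detail.

## Worked example

```python
import numpy as np
from maizefrontier import (contest_like, literature_like, gen_dataset,
                           fit_frontier, bootstrap_frontier, compare_frontiers,
                           fit_sigmoid)

contest = gen_dataset(contest_like(seed=2))        # n = 16171 records
lit     = gen_dataset(literature_like(seed=102))   # n = 819 records

x, y = contest.df["planting_doy"].to_numpy(), contest.df["yield_mgha"].to_numpy()
print(f"mean yield {y.mean():.2f} Mg/ha")

fit = fit_frontier(x, y, tau=0.99)
print(f"plateau {fit.plateau:.2f} Mg/ha, breakpoint {fit.breakpoint:.0f} DOY, "
      f"slope {fit.slope:.4f} Mg/ha/day")

sig = fit_sigmoid(contest.df["latitude"].to_numpy(), x)
print(f"sigmoid R2 {sig.r2:.2f}")

bc = bootstrap_frontier(x, y, B=200, seed=1)
bl = bootstrap_frontier(lit.df["planting_doy"].to_numpy(),
                        lit.df["yield_mgha"].to_numpy(), B=200, seed=1)
v = compare_frontiers(bl, bc)
print("breakpoints differ:", v["breakpoint"]["different"],
      "| slopes differ:", v["slope"]["different"])
```

prints

```
mean yield 14.81 Mg/ha
plateau 21.17 Mg/ha, breakpoint 152 DOY, slope -0.0540 Mg/ha/day
sigmoid R2 0.48
breakpoints differ: True | slopes differ: False
```

i.e. the generated contest-like data average 14.8 Mg ha⁻¹; the fitted
0.99-quantile boundary stays at ≈ 21 Mg ha⁻¹ until day 152 and then loses
≈ 0.06 Mg ha⁻¹ per day of delay; planting date rises sigmoidally with
latitude (R² ≈ 0.5); and against the lower-yielding literature-like data
the boundary breakpoints are statistically different while the post-plateau
decline rates are not — later planting costs about the same per day, but
high-yield systems keep their plateau roughly a month longer.

A command-line interface mirrors the library:

```bash
maizefrontier simulate --preset contest_like --n 16171 --seed 7 --out data.csv
maizefrontier frontier data.csv --tau 0.99 --boot 500 --seed 7
maizefrontier run --seed 7 --out results/run1     # full pipeline
```

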