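"""End-to-end orchestration: simulate/load -> stratify -> variance components
-> trends -> frontier analysis -> report bundle.

Every stochastic stage receives an explicit seed derived from the run seed,
and the bundle includes a machine-readable manifest (versions, seeds,
timings) so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from . import published, stratify, synth, trend, varcomp
from . import frontier as fr

log = logging.getLogger("maizefrontier")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full synthesis run.

    Either CSV input paths or synthetic presets per source dataset; seeds
    for simulation, equalization and each bootstrap; the quantile level and
    bootstrap size of the frontier stage.
    """

    contest_path: str | None = None
    literature_path: str | None = None
    contest_preset: str = "contest_like"
    literature_preset: str = "literature_like"
    contest_n: int = 16171
    literature_n: int = 819
    tau: float = 0.99
    grid_step: int = 1
    bootstrap_B: int = 500
    coverage: float = 0.5
    window_scheme: str = "published"  # published | estimated
    anchor_quantile: float | None = None
    seed: int = 0
    equalize: bool = True
    out_dir: str = "maizefrontier_run"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def paper_replica(seed: int = 0, out_dir: str = "maizefrontier_run", **over) -> RunConfig:
    """Both presets at source sizes, plus equalization and a combined fit."""
    return RunConfig(seed=seed, out_dir=out_dir, **over)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(name, exc) from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out, time.perf_counter() - t0
        return wrapped
    return deco


@_stage("load")
def _load(cfg: RunConfig):
    seeds = {"contest": cfg.seed, "literature": cfg.seed + 1}
    if cfg.contest_path:
        contest = mio.load_dataset(cfg.contest_path, {"provenance": "contest"})
    else:
        contest = synth.gen_dataset(synth.PRESETS[cfg.contest_preset](
            n=cfg.contest_n, seed=seeds["contest"]))
    if cfg.literature_path:
        lit = mio.load_dataset(cfg.literature_path, {"provenance": "literature"})
    else:
        lit = synth.gen_dataset(synth.PRESETS[cfg.literature_preset](
            n=cfg.literature_n, seed=seeds["literature"]))
    return contest, lit, seeds


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthesis; returns the report bundle as a dict and writes
    CSV/JSON artefacts plus a manifest under ``config.out_dir``."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    seeds_used: dict[str, int] = {}
    bundle: dict = {}

    (contest, lit, seeds), timings["load"] = _load(cfg)
    seeds_used.update(seeds)
    contest.to_csv(out / "contest_normalized.csv")
    lit.to_csv(out / "literature_normalized.csv")

    @_stage("stratify")
    def s_strat():
        summaries = {
            name: stratify.stratum_summary(contest, name)
            for name in ("latitude_group", "yield_env", "window_fixed")
        }
        wt = (dict(published.MOST_FREQUENT_WINDOWS)
              if cfg.window_scheme == "published"
              else stratify.window_table(contest, cfg.coverage))
        return summaries, wt

    (summaries, wtable), timings["stratify"] = s_strat()
    for name, tab in summaries.items():
        tab.to_csv(out / f"summary_{name}.csv", index=False)
    bundle["window_table"] = {k: list(v) for k, v in wtable.items()}
    (out / "window_table.json").write_text(json.dumps(bundle["window_table"], indent=2))

    @_stage("varcomp")
    def s_var():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return varcomp.build_variance_table(contest)

    vtab, timings["varcomp"] = s_var()
    vtab.to_frame().to_csv(out / "variance_table.csv", index=False)
    bundle["variance_table"] = vtab.to_frame().to_dict(orient="records")

    @_stage("trend")
    def s_trend():
        sig = trend.fit_sigmoid(contest.df["latitude"].to_numpy(),
                                contest.df["planting_doy"].to_numpy())
        effects = {}
        for g in published.LATITUDE_GROUPS:
            if g not in wtable:
                continue
            try:
                cmp_ = trend.window_effect(contest, wtable, g)
            except (ValueError, KeyError):
                continue
            effects[g] = cmp_.table.to_dict(orient="records")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mgmt = trend.management_profiles(contest)
        return sig, effects, mgmt

    (sig, effects, mgmt), timings["trend"] = s_trend()
    bundle["sigmoid_fit"] = asdict(sig)
    (out / "sigmoid_fit.json").write_text(json.dumps(bundle["sigmoid_fit"], indent=2))
    bundle["window_effects"] = effects
    (out / "window_effects.json").write_text(json.dumps(effects, indent=2))
    for name in ("tillage", "irrigation", "seeding"):
        tab = getattr(mgmt, name)
        if tab is not None:
            tab.to_csv(out / f"management_{name}.csv", index=False)

    @_stage("frontier")
    def s_front():
        seeds_used["bootstrap_contest"] = cfg.seed + 10
        seeds_used["bootstrap_literature"] = cfg.seed + 11
        args = dict(tau=cfg.tau, B=cfg.bootstrap_B, grid_step=cfg.grid_step)
        xc = contest.df["planting_doy"].to_numpy()
        yc = contest.df["yield_mgha"].to_numpy()
        xl = lit.df["planting_doy"].to_numpy()
        yl = lit.df["yield_mgha"].to_numpy()
        boots = {
            "contest": fr.bootstrap_frontier(xc, yc, seed=seeds_used["bootstrap_contest"], **args),
            "literature": fr.bootstrap_frontier(xl, yl, seed=seeds_used["bootstrap_literature"], **args),
        }
        comparisons = {}
        if cfg.equalize:
            seeds_used["equalize"] = cfg.seed + 12
            seeds_used["bootstrap_combined"] = cfg.seed + 13
            large, small = (contest, lit) if contest.n >= lit.n else (lit, contest)
            _, combined = fr.equalize_combine(large, small, seed=seeds_used["equalize"])
            boots["combined"] = fr.bootstrap_frontier(
                combined.df["planting_doy"].to_numpy(),
                combined.df["yield_mgha"].to_numpy(),
                seed=seeds_used["bootstrap_combined"], **args)
        pairs = [("literature", "contest")]
        if "combined" in boots:
            pairs += [("literature", "combined"), ("combined", "contest")]
        for a, b in pairs:
            comparisons[f"{a}_vs_{b}"] = fr.compare_frontiers(boots[a], boots[b])
        return boots, comparisons

    (boots, comparisons), timings["frontier"] = s_front()
    bundle["frontiers"] = {k: b.to_dict() for k, b in boots.items()}
    bundle["comparisons"] = comparisons
    (out / "frontiers.json").write_text(json.dumps(bundle["frontiers"], indent=2))
    (out / "comparisons.json").write_text(json.dumps(comparisons, indent=2))
    for k, b in boots.items():
        b.replicates.to_csv(out / f"bootstrap_{k}.csv", index=False)

    manifest = {
        "config": asdict(cfg),
        "seeds": seeds_used,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "n": {"contest": contest.n, "literature": lit.n},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle
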