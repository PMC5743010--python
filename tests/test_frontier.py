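import numpy as np
import pytest

from maizefrontier.frontier import (pinball_loss, fit_conditional, fit_frontier,
                                    frontier_oracle, bootstrap_frontier,
                                    equalize_combine, equalized_frontier_replicates,
                                    compare_frontiers, BootstrapResult, FrontierFit)
from maizefrontier.synth import (contest_like, literature_like, gen_dataset,
                                 FrontierParams, true_frontier)
from .conftest import make_dataset


def frontier_points(n, plateau, breakpoint, slope, seed=0, noise=0.0, deficit=2.0):
    """Scatter at/below a known linear-plateau envelope."""
    rng = np.random.default_rng(seed)
    x = rng.integers(60, 200, n).astype(float)
    f = plateau + slope * np.maximum(0.0, x - breakpoint)
    y = f - (rng.exponential(deficit, n) if deficit else 0.0)
    if noise:
        y = y + rng.normal(0, noise, n)
    return x, y


class TestPinballLoss:
    @pytest.mark.parametrize("u, tau, expected", [
        (1.0, 0.99, 0.99), (-1.0, 0.99, 0.01), (0.0, 0.5, 0.0),
        (2.0, 0.8, 1.6), (-2.0, 0.8, 0.4),
    ])
    def test_values(self, u, tau, expected):
        assert pinball_loss(u, tau) == pytest.approx(expected)

    def test_tau_domain(self):
        with pytest.raises(ValueError):
            pinball_loss(1.0, 1.0)


class TestFitConditional:
    def test_zero_loss_generative_curve(self):
        x = np.arange(80, 125, 4, dtype=float)
        y = 18.0 - 0.1 * np.maximum(0.0, x - 100)
        for tau in (0.5, 0.9, 0.99):
            cf = fit_conditional(x, y, 100.0, tau)
            assert cf.loss == pytest.approx(0.0, abs=1e-10)
            assert cf.plateau == pytest.approx(18.0, abs=1e-9)
            assert cf.slope == pytest.approx(-0.1, abs=1e-9)

    def test_matches_pair_enumeration_oracle(self):
        """The solver attains the minimum over every basis candidate: lines
        through two points and flat lines through one point."""
        rng = np.random.default_rng(2)
        for trial in range(6):
            n = 12
            beta = 100.0
            x = rng.uniform(70, 160, n)
            y = rng.uniform(8, 20, n)
            tau = rng.choice([0.5, 0.9, 0.99])
            cf = fit_conditional(x, y, beta, tau)
            z = np.maximum(0.0, x - beta)
            best = np.inf
            for i in range(n):
                for j in range(n):
                    if z[i] == z[j]:
                        continue
                    s = (y[i] - y[j]) / (z[i] - z[j])
                    if s > 0:
                        continue
                    p = y[i] - s * z[i]
                    best = min(best, pinball_loss(y - p - s * z, tau).sum())
            for i in range(n):
                best = min(best, pinball_loss(y - y[i], tau).sum())
            assert cf.loss == pytest.approx(best, abs=1e-9)

    def test_all_points_before_breakpoint_degenerate(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(5, 20, 40)
        x = rng.uniform(60, 99, 40)
        tau = 0.9
        cf = fit_conditional(x, y, 120.0, tau)
        assert cf.degenerate
        assert cf.slope == 0.0
        k = int(np.ceil(len(y) * tau))
        assert cf.plateau == pytest.approx(np.sort(y)[k - 1])


class TestFitFrontier:
    def test_exact_recovery_of_zero_loss_fixture(self):
        x, y = frontier_points(200, 19.0, 140, -0.06, seed=4, deficit=1.5)
        # put a spine of points exactly on the envelope
        x[:30] = np.linspace(65, 195, 30).round()
        y[:30] = 19.0 - 0.06 * np.maximum(0.0, x[:30] - 140)
        fit = fit_frontier(x, y, tau=0.99)
        assert fit.plateau == pytest.approx(19.0, abs=0.02)
        assert fit.breakpoint == pytest.approx(140, abs=2)
        assert fit.slope == pytest.approx(-0.06, abs=0.005)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            n = int(rng.integers(20, 60))
            x, y = frontier_points(n, rng.uniform(15, 22), rng.uniform(100, 160),
                                   -rng.uniform(0.02, 0.15), seed=trial,
                                   noise=0.2)
            tau = float(rng.choice([0.5, 0.9, 0.99]))
            f1 = fit_frontier(x, y, tau)
            f2 = frontier_oracle(x, y, tau)
            assert abs(f1.loss - f2.loss) <= 1e-9

    def test_oracle_refuses_large_n(self):
        x, y = frontier_points(300, 20, 140, -0.05)
        with pytest.raises(ValueError):
            frontier_oracle(x, y, 0.99)

    def test_frac_above_bounded(self):
        for preset, seed in [(contest_like, 0), (literature_like, 1)]:
            ds = gen_dataset(preset(n=4000, seed=seed))
            fit = fit_frontier(ds.df["planting_doy"].to_numpy(),
                               ds.df["yield_mgha"].to_numpy(), 0.99)
            assert fit.frac_above <= 2 * 0.01 + 3 / 4000

    def test_monotone_in_tau_on_dense_support(self):
        ds = gen_dataset(contest_like(n=6000, seed=1))
        x = ds.df["planting_doy"].to_numpy()
        y = ds.df["yield_mgha"].to_numpy()
        grid = np.arange(np.quantile(x, 0.01), np.quantile(x, 0.99))
        prev = None
        for tau in (0.5, 0.8, 0.9, 0.95, 0.99):
            cur = fit_frontier(x, y, tau).predict(grid)
            if prev is not None:
                assert np.all(cur >= prev - 1e-9)
            prev = cur

    def test_pruned_equals_unpruned(self):
        """The below-frontier pruning is an exact reduction."""
        ds = gen_dataset(literature_like(n=2000, seed=6))
        x = ds.df["planting_doy"].to_numpy()
        y = ds.df["yield_mgha"].to_numpy()
        fp = fit_frontier(x, y, 0.99, prune=True)
        fu = fit_frontier(x, y, 0.99, prune=False)
        assert fp.breakpoint == fu.breakpoint
        assert fp.plateau == pytest.approx(fu.plateau, abs=1e-6)
        assert fp.loss == pytest.approx(fu.loss, abs=1e-5)

    def test_short_span_rejected(self):
        with pytest.raises(ValueError):
            fit_frontier(np.full(20, 100.0) + np.arange(20) * 0.1,
                         np.ones(20) * 10, 0.99)


class TestBootstrap:
    def test_deterministic_given_seed(self):
        ds = gen_dataset(literature_like(n=400, seed=7))
        x = ds.df["planting_doy"].to_numpy()
        y = ds.df["yield_mgha"].to_numpy()
        b1 = bootstrap_frontier(x, y, B=200, seed=42)
        b2 = bootstrap_frontier(x, y, B=200, seed=42)
        assert b1.ci_plateau == b2.ci_plateau
        assert b1.ci_breakpoint == b2.ci_breakpoint
        assert b1.ci_slope == b2.ci_slope

    def test_zero_noise_envelope_gives_degenerate_cis(self):
        # every point exactly on the envelope: no sampling variability
        rng = np.random.default_rng(8)
        x = rng.integers(60, 200, 600).astype(float)
        y = true_frontier(x, FrontierParams(plateau=18, breakpoint=130, slope=-0.05))
        b = bootstrap_frontier(x, y, B=200, seed=0)
        assert b.ci_plateau[1] - b.ci_plateau[0] == pytest.approx(0, abs=1e-6)
        assert b.ci_slope[1] - b.ci_slope[0] == pytest.approx(0, abs=1e-6)
        assert b.ci_breakpoint[1] - b.ci_breakpoint[0] <= 1.0

    def test_ci_width_shrinks_with_n(self):
        widths = {}
        for n in (500, 8000):
            ds = gen_dataset(contest_like(n=n, seed=9))
            b = bootstrap_frontier(ds.df["planting_doy"].to_numpy(),
                                   ds.df["yield_mgha"].to_numpy(), B=200, seed=1)
            widths[n] = (b.ci_plateau[1] - b.ci_plateau[0],
                         b.ci_slope[1] - b.ci_slope[0])
        assert widths[8000][0] < widths[500][0]
        assert widths[8000][1] < widths[500][1]

    def test_cis_contain_point_estimate(self):
        ds = gen_dataset(literature_like(n=500, seed=10))
        b = bootstrap_frontier(ds.df["planting_doy"].to_numpy(),
                               ds.df["yield_mgha"].to_numpy(), B=200, seed=2)
        assert b.ci_plateau[0] <= b.fit.plateau <= b.ci_plateau[1]
        assert b.ci_breakpoint[0] <= b.fit.breakpoint <= b.ci_breakpoint[1]
        assert b.ci_slope[0] <= b.fit.slope <= b.ci_slope[1]

    def test_small_B_rejected(self):
        x, y = frontier_points(100, 18, 120, -0.05)
        with pytest.raises(ValueError):
            bootstrap_frontier(x, y, B=50)


class TestEqualizeCombine:
    def test_sizes(self):
        large = gen_dataset(contest_like(n=1600, seed=11))
        small = gen_dataset(literature_like(n=300, seed=11))
        resampled, combined = equalize_combine(large, small, seed=5)
        assert resampled.n == 300
        assert combined.n == 600

    def test_resample_is_multiset_subset(self):
        large = gen_dataset(contest_like(n=1200, seed=12))
        small = gen_dataset(literature_like(n=200, seed=12))
        resampled, _ = equalize_combine(large, small, seed=6)
        keys = set(map(tuple, large.df[["latitude", "yield_mgha"]].to_numpy()))
        for row in resampled.df[["latitude", "yield_mgha"]].to_numpy():
            assert tuple(row) in keys

    def test_identical_datasets_double(self):
        ds = gen_dataset(literature_like(n=250, seed=13))
        _, combined = equalize_combine(ds, ds, seed=0)
        assert combined.n == 2 * ds.n

    def test_seeded_reproducibility_and_swap_warning(self):
        large = gen_dataset(contest_like(n=800, seed=14))
        small = gen_dataset(literature_like(n=200, seed=14))
        r1, _ = equalize_combine(large, small, seed=9)
        r2, _ = equalize_combine(large, small, seed=9)
        assert r1.df.equals(r2.df)
        with pytest.warns(UserWarning, match="swap"):
            r3, c3 = equalize_combine(small, large, seed=9)
        assert r3.n == small.n and c3.n == 2 * small.n

    def test_replicate_mode_returns_fits(self):
        large = gen_dataset(contest_like(n=900, seed=15))
        small = gen_dataset(literature_like(n=250, seed=15))
        reps = equalized_frontier_replicates(large, small, R=3, seed=1)
        assert len(reps) == 3
        assert set(reps.columns) == {"plateau", "breakpoint", "slope"}


def _fake_boot(ci_p, ci_b, ci_s, tau=0.99):
    fit = FrontierFit(plateau=np.mean(ci_p), breakpoint=np.mean(ci_b),
                      slope=np.mean(ci_s), tau=tau, loss=0.0, n=100,
                      frac_above=0.0)
    return BootstrapResult(fit=fit, ci_plateau=ci_p, ci_breakpoint=ci_b,
                           ci_slope=ci_s, B=200, seed=0)


class TestCompareFrontiers:
    def test_disjoint_intervals_differ(self):
        a = _fake_boot((17, 18), (120, 126), (-0.08, -0.05))
        b = _fake_boot((20, 22), (148, 156), (-0.07, -0.04))
        out = compare_frontiers(a, b)
        assert out["plateau"]["different"]
        assert out["breakpoint"]["different"]
        assert not out["slope"]["different"]

    def test_nested_intervals_do_not_differ(self):
        a = _fake_boot((17, 22), (120, 156), (-0.08, -0.04))
        b = _fake_boot((18, 20), (130, 140), (-0.06, -0.05))
        out = compare_frontiers(a, b)
        assert not any(v["different"] for v in out.values())

    def test_tau_mismatch_rejected(self):
        a = _fake_boot((17, 18), (120, 126), (-0.08, -0.05), tau=0.99)
        b = _fake_boot((17, 18), (120, 126), (-0.08, -0.05), tau=0.95)
        with pytest.raises(ValueError):
            compare_frontiers(a, b)
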