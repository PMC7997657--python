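"""WHAM / PMF estimation against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from switchquant import pmf, synth
from switchquant.pmf import (
    BlockDistribution,
    Thermo,
    UmbrellaWindow,
    WhamGrid,
    bias_energy,
    estimate_pmf,
    make_grid,
    pmf_from_blocks,
    split_blocks,
    wham_solve,
)


class TestGrid:
    def test_measurement_binning(self):
        g = make_grid(3.75, 10.25, 13)
        assert g.width == pytest.approx(0.5)
        # bin centers coincide with the 13 window centers, 4..10 A
        assert np.allclose(g.centers, np.linspace(4.0, 10.0, 13))

    def test_single_bin(self):
        g = make_grid(0, 1, 1)
        assert g.centers == pytest.approx([0.5])

    def test_half_width_bins(self):
        g = make_grid(3.75, 10.25, 26)
        assert g.width == pytest.approx(0.25)
        assert g.centers[0] == pytest.approx(3.875)

    def test_rejects_empty_interval(self):
        with pytest.raises(ValueError):
            make_grid(1.0, 1.0, 4)
        with pytest.raises(ValueError):
            make_grid(0, 1, 0)


class TestBlocking:
    @pytest.mark.parametrize(
        "total_ns, expected",
        [(30.0, 5), (10.0, 1), (31.0, 5)],  # trailing partial ns dropped
    )
    def test_block_counts(self, total_ns, expected):
        dt = 0.01
        series = np.zeros(int(round(total_ns / dt)))
        blocks = split_blocks(series, dt, equilibration_ns=5.0, block_ns=5.0)
        assert len(blocks) == expected
        assert all(b.size == int(round(5.0 / dt)) for b in blocks)

    def test_too_short_series_names_shortfall(self):
        series = np.zeros(600)  # 6 ns at 0.01 ns spacing
        with pytest.raises(ValueError, match="100 post-equilibration samples"):
            split_blocks(series, 0.01, equilibration_ns=5.0, block_ns=5.0)


class TestBias:
    @pytest.mark.parametrize(
        "dx, expected", [(0.0, 0.0), (1.0, 10.0), (0.5, 2.5), (-1.0, 10.0)]
    )
    def test_half_prefactor_harmonic(self, dx, expected):
        win = UmbrellaWindow(center=5.0, spring_constant=20.0, series=[5.0], sampling_interval_ns=1.0)
        assert bias_energy(win, 5.0 + dx) == pytest.approx(expected)


def brute_force_wham(counts, bias, N_w, kT, tol=1e-12, max_iter=2_000_000):
    """Independent fixed-point iteration of the WHAM equations.

    Plain elementwise loops, run to a much tighter tolerance than the
    implementation under test.
    """
    n_win, n_bins = counts.shape
    total = counts.sum(axis=0)
    beta = 1.0 / kT
    f = [0.0] * n_win
    for _ in range(max_iter):
        p = []
        for i in range(n_bins):
            denom = sum(N_w[w] * math.exp(-beta * (bias[w][i] - f[w])) for w in range(n_win))
            p.append(total[i] / denom)
        f_new = [
            -kT * math.log(sum(p[i] * math.exp(-beta * bias[w][i]) for i in range(n_bins)))
            for w in range(n_win)
        ]
        if max(abs(a - b) for a, b in zip(f_new, f)) < tol:
            f = f_new
            break
        f = f_new
    z = sum(p)
    return np.array([pi / z for pi in p]), np.array(f) - f[0]


class TestWhamSolve:
    def test_unbiased_window_recovers_its_histogram(self, thermo):
        rng = np.random.default_rng(11)
        grid = make_grid(0.0, 5.0, 5)
        series = rng.uniform(0.2, 4.8, size=500)
        win = UmbrellaWindow(center=2.5, spring_constant=0.0, series=series, sampling_interval_ns=0.01)
        blk = wham_solve([win], grid, thermo, tolerance=1e-10)
        hist, _ = np.histogram(series, bins=grid.edges)
        assert np.allclose(blk.p, hist / hist.sum(), atol=1e-12)

    def test_matches_brute_force_fixed_point(self, thermo):
        """Self-consistent solver equals elementwise fixed-point iteration."""
        grid = make_grid(4.0, 9.0, 5)
        counts = np.array(
            [[120, 340, 80, 10, 2], [15, 200, 310, 140, 30], [1, 25, 180, 390, 160]],
            dtype=float,
        )
        windows = []
        rng = np.random.default_rng(0)
        for w, center in enumerate((5.0, 6.5, 8.0)):
            # build a series realizing exactly these per-bin counts
            xs = []
            for i in range(5):
                xs.append(rng.uniform(grid.edges[i], grid.edges[i + 1], int(counts[w, i])))
            windows.append(
                UmbrellaWindow(center=center, spring_constant=3.0,
                               series=np.concatenate(xs), sampling_interval_ns=0.01)
            )
        blk = wham_solve(windows, grid, thermo, tolerance=1e-8)

        bias = [
            [0.5 * 3.0 * (c - win.center) ** 2 for c in grid.centers] for win in windows
        ]
        p_ref, f_ref = brute_force_wham(counts, bias, counts.sum(axis=1), thermo.kT)
        assert np.allclose(blk.window_free_energies, f_ref, atol=1e-6)
        F = -thermo.kT * np.log(blk.p)
        F_ref = -thermo.kT * np.log(p_ref)
        assert np.allclose(F - F.min(), F_ref - F_ref.min(), atol=1e-6)

    def test_flat_landscape_recovered_from_biased_draws(self, thermo):
        """Two overlapping biased windows on a flat potential must
        reweight back to a uniform distribution.  Samples are drawn by
        direct Monte-Carlo from the known biased Boltzmann law on the
        grid's support so every deviation is pure estimator error."""
        grid = make_grid(2.5, 7.5, 10)
        k = 0.5
        rng = np.random.default_rng(42)
        windows = []
        for c in (4.0, 6.0):
            q = np.exp(-thermo.beta * 0.5 * k * (grid.centers - c) ** 2)
            q /= q.sum()
            draws = rng.choice(grid.centers, size=50_000, p=q)
            windows.append(
                UmbrellaWindow(center=c, spring_constant=k, series=draws,
                               sampling_interval_ns=0.01)
            )
        blk = wham_solve(windows, grid, thermo, tolerance=1e-9)
        # oracle: exp(-beta*0) normalized over 10 bins = 0.1 each;
        # 0.01 is ~3 SE for the worst (most reweighted) bin
        assert np.all(np.abs(blk.p - 0.1) < 0.01)

    def test_harmonic_landscape_matches_analytic_gaussian(self, thermo):
        """Three biased windows on a harmonic landscape: the recovered
        distribution matches the discretized analytic Gaussian, and the
        solver agrees with the brute-force fixed point."""
        kappa, x0 = 1.5, 5.0
        pot = synth.harmonic_potential(kappa, x0)
        grid = make_grid(3.0, 7.0, 8)
        k = 2.0
        rng = np.random.default_rng(7)
        windows = []
        for c in (4.0, 5.0, 6.0):
            q = np.exp(-thermo.beta * (pot.energy(grid.centers) + 0.5 * k * (grid.centers - c) ** 2))
            q /= q.sum()
            windows.append(
                UmbrellaWindow(center=c, spring_constant=k,
                               series=rng.choice(grid.centers, size=50_000, p=q),
                               sampling_interval_ns=0.01)
            )
        blk = wham_solve(windows, grid, thermo, tolerance=1e-9)
        F = -thermo.kT * np.log(blk.p)
        F = F - F.min()
        truth = pot.energy(grid.centers)
        truth = truth - truth.min()
        assert np.all(np.abs(F - truth) < 0.05)  # ~3 SE in the worst bin
        # independent oracle: brute-force fixed-point on the same histograms
        counts = np.stack([np.histogram(w.series, bins=grid.edges)[0] for w in windows]).astype(float)
        bias = [[0.5 * k * (c - w.center) ** 2 for c in grid.centers] for w in windows]
        p_ref, f_ref = brute_force_wham(counts, bias, counts.sum(axis=1), thermo.kT)
        assert np.allclose(blk.p, p_ref, atol=1e-8)
        assert np.allclose(blk.window_free_energies, f_ref, atol=1e-6)

    def test_out_of_grid_majority_fails(self, thermo):
        grid = make_grid(0.0, 1.0, 2)
        win = UmbrellaWindow(center=0.5, spring_constant=0.0,
                             series=np.concatenate([np.full(90, 5.0), np.full(10, 0.5)]),
                             sampling_interval_ns=0.01)
        with pytest.raises(ValueError, match="outside the grid"):
            wham_solve([win], grid, thermo)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        counts=st.lists(
            st.lists(st.integers(0, 500), min_size=4, max_size=4),
            min_size=2,
            max_size=3,
        ).filter(lambda c: all(sum(row) > 0 for row in c))
    )
    def test_probabilities_conserve_mass(self, counts):
        thermo = Thermo()
        grid = make_grid(0.0, 4.0, 4)
        rng = np.random.default_rng(1)
        windows = []
        for w, row in enumerate(counts):
            xs = [rng.uniform(grid.edges[i], grid.edges[i + 1], n) for i, n in enumerate(row)]
            series = np.concatenate([x for x in xs if x.size])
            windows.append(
                UmbrellaWindow(center=1.0 + w, spring_constant=1.0,
                               series=series, sampling_interval_ns=0.01)
            )
        blk = wham_solve(windows, grid, thermo, tolerance=1e-9)
        assert abs(blk.p.sum() - 1.0) < 1e-10
        assert np.all(blk.p >= 0)


class TestPmfFromBlocks:
    def _blk(self, p, idx=0):
        return BlockDistribution(block_index=idx, p=np.asarray(p, dtype=float),
                                 window_free_energies=np.zeros(1), n_iterations=1)

    def test_identical_blocks_have_zero_error(self, thermo):
        grid = make_grid(0, 3, 3)
        blocks = [self._blk([0.5, 0.3, 0.2], i) for i in range(5)]
        prof = pmf_from_blocks(blocks, grid, thermo)
        assert np.allclose(prof.sigma_F, 0.0)

    def test_uniform_probability_is_flat_zero(self, thermo):
        grid = make_grid(0, 4, 4)
        prof = pmf_from_blocks([self._blk([0.25] * 4, i) for i in range(3)], grid, thermo)
        assert np.allclose(prof.F, 0.0)

    def test_two_bin_free_energy_difference(self, thermo):
        """p = (0.8, 0.2) at 310 K gives dF = kT ln 4 ~ 0.854 kcal/mol."""
        grid = make_grid(0, 2, 2)
        prof = pmf_from_blocks([self._blk([0.8, 0.2], i) for i in range(2)], grid, thermo)
        dF = prof.F[1] - prof.F[0]
        assert dF == pytest.approx(thermo.kT * math.log(4.0), abs=1e-12)
        assert dF == pytest.approx(0.854, abs=5e-4)

    def test_single_block_flags_undefined_errors(self, thermo):
        grid = make_grid(0, 2, 2)
        prof = pmf_from_blocks([self._blk([0.6, 0.4])], grid, thermo)
        assert np.all(np.isfinite(prof.F))
        assert np.all(np.isnan(prof.sigma_F))

    def test_empty_bin_marked_undefined_and_offset_ignores_it(self, thermo):
        grid = make_grid(0, 3, 3)
        prof = pmf_from_blocks([self._blk([0.7, 0.3, 0.0], i) for i in range(2)], grid, thermo)
        assert np.isnan(prof.F[2])
        assert np.nanmin(prof.F) == 0.0


class TestEstimatePmf:
    def test_recovers_harmonic_profile(self, thermo, window_ladder):
        pot = synth.harmonic_potential(1.0, 7.0)
        grid = make_grid(3.75, 10.25, 13)
        wins = synth.simulate_umbrella(pot, window_ladder, synth.LangevinSpec(seed=3), thermo)
        prof = estimate_pmf(wins, grid, thermo)
        truth = synth.analytic_pmf(pot, grid, thermo)
        rmse = np.sqrt(np.nanmean((prof.F - truth.F) ** 2))
        assert rmse < 0.3

    def test_gauge_invariance_under_constant_offset(self, thermo, well, window_ladder):
        grid = make_grid(3.75, 10.25, 13)
        spec = synth.LangevinSpec(seed=5, n_steps=6000)
        wins_a = synth.simulate_umbrella(well, window_ladder, spec, thermo)
        wins_b = synth.simulate_umbrella(well.shifted(12.5), window_ladder, spec, thermo)
        prof_a = estimate_pmf(wins_a, grid, thermo, equilibration_ns=2, block_ns=2)
        prof_b = estimate_pmf(wins_b, grid, thermo, equilibration_ns=2, block_ns=2)
        # constant offsets leave the gradient, hence the trajectories, unchanged
        assert np.array_equal(prof_a.F, prof_b.F)

    def test_single_block_run_yields_profile_without_errors(self, thermo, well, window_ladder):
        spec = synth.LangevinSpec(seed=2, n_steps=5000)  # 10 ns
        wins = synth.simulate_umbrella(well, window_ladder, spec, thermo)
        prof = estimate_pmf(wins, grid := make_grid(3.75, 10.25, 13), thermo)
        assert prof.n_blocks == 1
        assert np.any(np.isfinite(prof.F))
        assert np.all(np.isnan(prof.sigma_F))

    def test_more_blocks_shrink_error_bars(self, thermo, well, window_ladder):
        grid = make_grid(3.75, 10.25, 13)
        short = synth.simulate_umbrella(well, window_ladder, synth.LangevinSpec(seed=9), thermo)
        long = synth.simulate_umbrella(
            well, window_ladder, synth.LangevinSpec(seed=9, n_steps=30_000), thermo
        )
        s1 = estimate_pmf(short, grid, thermo)
        s2 = estimate_pmf(long, grid, thermo)
        assert np.nanmean(s2.sigma_F) < np.nanmean(s1.sigma_F)
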