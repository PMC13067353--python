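"""WHAM, block averaging and metadynamics free-energy reconstruction."""

import math

import numpy as np
import pytest

from protonpath import (
    BiasedTimeSeries,
    GridAxis,
    HillsLog,
    RestraintSpec,
    block_averaged_wham,
    merge_walkers,
    metad_free_energy,
    wham,
)
from protonpath.constants import kT

KT310 = kT(310.0)


def quartic_double_well(x):
    """Analytic reference profile in kcal/mol: wells at x = +-1, barrier 2."""
    return 2.0 * (x**2 - 1.0) ** 2


def draw_biased(rng, windows, f, lo, hi, n, fine=4000):
    """Exact Monte-Carlo draws from exp(-(f + bias)/kT) per window."""
    xs = np.linspace(lo, hi, fine)
    out = []
    for win in windows:
        u = f(xs) + sum(r.energy(xs) for r in win)
        w = np.exp(-(u - u.min()) / KT310)
        w /= w.sum()
        x = xs[rng.choice(fine, size=n, p=w)]
        out.append(BiasedTimeSeries.from_arrays(
            time=np.arange(1, n + 1), cvs={"x": x}, restraints=win))
    return out


def brute_force_wham(hists, bias, n_counts, kT_val, n_iter=60000, tol=1e-13):
    """Independent WHAM oracle: plain-loop direct iteration of the
    self-consistent equations (no vectorization, no acceleration)."""
    K, M = bias.shape
    f = [0.0] * K
    for _ in range(n_iter):
        p = []
        for j in range(M):
            denom = 0.0
            for k in range(K):
                denom += n_counts[k] * math.exp((f[k] - bias[k][j]) / kT_val)
            num = sum(h[j] for h in hists)
            p.append(num / denom if denom > 0 else 0.0)
        fnew = []
        for k in range(K):
            z = sum(math.exp(-bias[k][j] / kT_val) * p[j] for j in range(M))
            fnew.append(-kT_val * math.log(z))
        shift = fnew[0]
        fnew = [v - shift for v in fnew]
        if max(abs(a - b) for a, b in zip(fnew, f)) < tol:
            f = fnew
            break
        f = fnew
    total = sum(p)
    return f, [v / total for v in p]


class TestWham:
    def test_single_unbiased_window_is_log_histogram(self, rng):
        x = rng.normal(0.0, 0.6, 20000)
        series = BiasedTimeSeries.from_arrays(
            time=np.arange(1, x.size + 1), cvs={"x": x})
        axis = GridAxis("x", -2.0, 2.0, 30)
        grid = wham([series], [axis], 310.0)
        hist = np.histogram(x, bins=np.linspace(-2, 2, 31))[0].astype(float)
        ref = -KT310 * np.log(hist, where=hist > 0,
                              out=np.full(30, np.nan))
        ref -= np.nanmin(ref)
        np.testing.assert_allclose(grid.free_energy[grid.mask],
                                   ref[grid.mask], atol=1e-10)

    def test_exact_sampling_recovers_quartic_double_well(self, rng):
        centers = np.linspace(-1.6, 1.6, 12)
        windows = [(RestraintSpec("x", float(c), 15.0),) for c in centers]
        series = draw_biased(rng, windows, quartic_double_well, -2.2, 2.2,
                             4000)
        axis = GridAxis("x", -2.0, 2.0, 50)
        grid = wham(series, [axis], 310.0)
        ref = quartic_double_well(axis.centers)
        err = grid.free_energy[grid.mask] - ref[grid.mask]
        err -= err.mean()
        assert float(np.sqrt(np.mean(err**2))) < 0.2

    def test_translation_of_centers_and_surface_leaves_pmf_unchanged(self, rng):
        centers = np.linspace(-1.2, 1.2, 6)
        shift = 5.0
        w0 = [(RestraintSpec("x", float(c), 12.0),) for c in centers]
        w1 = [(RestraintSpec("x", float(c + shift), 12.0),) for c in centers]
        s0 = draw_biased(rng, w0, quartic_double_well, -2.0, 2.0, 3000)
        rng2 = np.random.default_rng(rng.bit_generator.seed_seq.entropy)
        s1 = draw_biased(rng2, w1, lambda x: quartic_double_well(x - shift),
                         -2.0 + shift, 2.0 + shift, 3000)
        g0 = wham(s0, [GridAxis("x", -1.8, 1.8, 36)], 310.0)
        g1 = wham(s1, [GridAxis("x", -1.8 + shift, 1.8 + shift, 36)], 310.0)
        np.testing.assert_allclose(g0.free_energy[g0.mask & g1.mask],
                                   g1.free_energy[g0.mask & g1.mask],
                                   atol=1e-8)

    def test_matches_brute_force_fixed_point_oracle(self, rng):
        # <= 3 windows, <= 20 bins: compare against a plain-loop iteration
        centers = [-0.8, 0.0, 0.8]
        windows = [(RestraintSpec("x", c, 8.0),) for c in centers]
        series = draw_biased(rng, windows, quartic_double_well, -1.6, 1.6,
                             1500)
        axis = GridAxis("x", -1.5, 1.5, 18)
        grid = wham(series, [axis], 310.0, tol=1e-12)

        hists = [np.histogram(s.cv("x"), bins=np.linspace(-1.5, 1.5, 19))[0]
                 for s in series]
        bias = np.array([[float(windows[k][0].energy(c))
                          for c in axis.centers] for k in range(3)])
        f, p = brute_force_wham([h.tolist() for h in hists], bias,
                                [int(h.sum()) for h in hists], KT310)
        p = np.asarray(p)
        ref = -KT310 * np.log(p, where=p > 0, out=np.full(p.size, np.nan))
        ref -= np.nanmin(ref[grid.mask])
        np.testing.assert_allclose(grid.free_energy[grid.mask],
                                   ref[grid.mask], atol=1e-8)

    def test_reweighted_histograms_match_window_histograms(self, rng):
        # chi^2 consistency on exact-sampling inputs
        centers = np.linspace(-1.2, 1.2, 5)
        windows = [(RestraintSpec("x", float(c), 10.0),) for c in centers]
        series = draw_biased(rng, windows, quartic_double_well, -2.0, 2.0,
                             5000)
        axis = GridAxis("x", -1.8, 1.8, 24)
        grid = wham(series, [axis], 310.0)
        F = np.where(grid.mask, grid.free_energy, np.inf)
        p_unb = np.exp(-F / KT310)
        from scipy.stats import chisquare
        for s, win in zip(series, windows):
            hist = np.histogram(s.cv("x"), bins=np.linspace(-1.8, 1.8, 25))[0]
            pb = p_unb * np.exp(-win[0].energy(axis.centers) / KT310)
            sel = (pb > 0) & (hist > 4)
            expected = pb[sel] / pb[sel].sum() * hist[sel].sum()
            stat = chisquare(hist[sel], expected)
            assert stat.pvalue > 0.01

    def test_disconnected_windows_rejected(self, rng):
        far = [(RestraintSpec("x", -10.0, 50.0),),
               (RestraintSpec("x", 10.0, 50.0),)]
        series = draw_biased(rng, far, lambda x: 0.0 * x, -12.0, 12.0, 500)
        with pytest.raises(ValueError, match="non-overlapping"):
            wham(series, [GridAxis("x", -12.0, 12.0, 60)], 310.0)


class TestBlockAveraging:
    def test_stationary_series_matches_full_wham(self, rng):
        centers = np.linspace(-1.4, 1.4, 8)
        windows = [(RestraintSpec("x", float(c), 12.0),) for c in centers]
        series = draw_biased(rng, windows, quartic_double_well, -2.0, 2.0,
                             8000)
        axis = GridAxis("x", -1.7, 1.7, 30)
        full = wham(series, [axis], 310.0)
        avg, report = block_averaged_wham(series, [axis], 310.0,
                                          n_blocks=8, keep_last=4)
        assert report.n_blocks == 8 and report.retained == (4, 5, 6, 7)
        common = full.mask & avg.mask
        se = np.where(common, avg.se, np.nan)
        diff = np.abs(avg.free_energy[common] - full.free_energy[common])
        rms = float(np.sqrt(np.mean(diff**2)))
        assert rms < 2.0 * max(float(np.nanmean(se)), 0.05)

    def test_drifting_first_half_is_discarded(self, rng):
        # first half of every window drifts; retained average should match
        # WHAM of the equilibrated half
        centers = np.linspace(-1.4, 1.4, 8)
        windows = [(RestraintSpec("x", float(c), 12.0),) for c in centers]
        series = draw_biased(rng, windows, quartic_double_well, -2.0, 2.0,
                             8000)
        drifted = []
        for s in series:
            x = s.cv("x").copy()
            n = x.size
            x[: n // 2] += np.linspace(0.8, 0.0, n // 2)  # synthetic drift
            drifted.append(BiasedTimeSeries.from_arrays(
                time=s.data["time"], cvs={"x": x}, restraints=s.restraints))
        axis = GridAxis("x", -1.7, 1.7, 30)
        clean_half = wham(
            [BiasedTimeSeries.from_arrays(
                time=s.data["time"][s.n_samples // 2:],
                cvs={"x": s.cv("x")[s.n_samples // 2:]},
                restraints=s.restraints) for s in series],
            [axis], 310.0)
        avg, report = block_averaged_wham(drifted, [axis], 310.0,
                                          n_blocks=4, keep_last=2)
        common = clean_half.mask & avg.mask
        diff = avg.free_energy[common] - clean_half.free_energy[common]
        diff -= diff.mean()
        se = float(np.nanmean(np.where(common, avg.se, np.nan)))
        assert float(np.sqrt(np.mean(diff**2))) < 2.0 * max(se, 0.08)

    def test_empty_block_is_named(self):
        s = BiasedTimeSeries.from_arrays(
            time=np.arange(1.0, 9.0),
            cvs={"x": np.array([0.1] * 4 + [99.0] * 4)},
            restraints=(RestraintSpec("x", 0.0, 5.0),))
        with pytest.raises(ValueError, match="window 0, block 1"):
            block_averaged_wham([s, s], [GridAxis("x", -1, 1, 4)], 310.0,
                                n_blocks=2, keep_last=1)


def one_hill_log(**kw):
    defaults = dict(
        cv_names=("phi",), times=np.array([1.0]),
        centers=np.array([[0.4]]), sigmas=np.array([[0.05]]),
        heights=np.array([0.6]), bias_factor=10.0,
        walkers=np.array([0]),
    )
    defaults.update(kw)
    return HillsLog(**defaults)


class TestMetadFreeEnergy:
    def test_single_hill_gives_inverted_gaussian(self):
        log = one_hill_log()
        axis = GridAxis("phi", 0.0, 1.0, 100)
        fes = metad_free_energy(log, [axis], 310.0)
        f = fes.free_energy
        assert axis.centers[np.argmin(f)] == pytest.approx(0.4, abs=axis.width)
        expected = -(10.0 / 9.0) * 0.6 * np.exp(
            -0.5 * ((axis.centers - 0.4) / 0.05) ** 2)
        expected -= expected.min()
        np.testing.assert_allclose(f, expected, atol=1e-9)

    def test_infinite_gamma_is_standard_metadynamics_identity(self):
        log = one_hill_log(bias_factor=math.inf)
        axis = GridAxis("phi", 0.0, 1.0, 50)
        fes = metad_free_energy(log, [axis], 310.0)
        v = 0.6 * np.exp(-0.5 * ((axis.centers - 0.4) / 0.05) ** 2)
        np.testing.assert_allclose(fes.free_energy, -(v - v.max()), atol=1e-9)

    def test_merge_order_does_not_change_result(self):
        a = one_hill_log()
        b = one_hill_log(times=np.array([2.0]), centers=np.array([[0.6]]),
                         walkers=np.array([1]))
        axis = GridAxis("phi", 0.0, 1.0, 40)
        f1 = metad_free_energy(merge_walkers([a, b]), [axis], 310.0,
                               average_last=0.0)
        f2 = metad_free_energy(merge_walkers([b, a]), [axis], 310.0,
                               average_last=0.0)
        np.testing.assert_array_equal(f1.free_energy, f2.free_energy)

    def test_empty_log_rejected(self):
        log = one_hill_log(times=np.zeros(0), centers=np.zeros((0, 1)),
                           sigmas=np.zeros((0, 1)), heights=np.zeros(0),
                           walkers=np.zeros(0, dtype=int))
        with pytest.raises(ValueError, match="empty"):
            metad_free_energy(log, [GridAxis("phi", 0, 1, 10)], 310.0)


class TestMergeWalkers:
    def test_single_log_round_trips(self):
        log = one_hill_log()
        merged = merge_walkers([log])
        np.testing.assert_array_equal(merged.centers, log.centers)

    def test_two_logs_concatenate_time_ordered(self):
        a = one_hill_log(times=np.array([1.0, 3.0]),
                         centers=np.array([[0.1], [0.3]]),
                         sigmas=np.array([[0.05], [0.05]]),
                         heights=np.array([0.6, 0.5]),
                         walkers=np.array([0, 0]))
        b = one_hill_log(times=np.array([2.0]), centers=np.array([[0.2]]),
                         walkers=np.array([1]))
        merged = merge_walkers([a, b])
        assert merged.n_hills == 3
        assert np.all(np.diff(merged.times) >= 0)
        np.testing.assert_allclose(merged.centers.ravel(), [0.1, 0.2, 0.3])

    def test_shuffled_input_gives_identical_output(self):
        logs = [
            one_hill_log(times=np.array([t]), centers=np.array([[c]]),
                         walkers=np.array([w]))
            for t, c, w in [(1.0, 0.1, 0), (1.0, 0.2, 1), (2.0, 0.3, 2)]
        ]
        m1 = merge_walkers(logs)
        m2 = merge_walkers(logs[::-1])
        np.testing.assert_array_equal(m1.centers, m2.centers)
        np.testing.assert_array_equal(m1.walkers, m2.walkers)

    def test_mismatched_bias_factor_rejected(self):
        with pytest.raises(ValueError, match="bias factor"):
            merge_walkers([one_hill_log(), one_hill_log(bias_factor=5.0)])
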