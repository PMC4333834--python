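"""Metropolis sampling against quadrature oracles; umbrella + WHAM recombination."""

import numpy as np
import pytest

import ramshorn as rh
from ramshorn.model import build_geometry, total_energy
from ramshorn.sampling import (
    MCConfig,
    RxDistribution,
    UmbrellaWindow,
    default_windows,
    metropolis_step,
    replace_window,
    run_chain,
    rx_support,
    umbrella_sample,
    wham_combine,
)

from conftest import make_params


# ---------------------------------------------------------------------------
# single Metropolis moves


class TestMetropolisStep:
    def test_downhill_always_accepted(self):
        """Forced proposals with dE < 0 are always taken."""
        p = make_params(2.0, 1.0, N=4)
        comp = rh.Composition("D" * 4)
        # start bent away from preference: relaxing moves are downhill
        rng = np.random.default_rng(0)
        state = build_geometry(np.zeros(4), p)
        e0 = total_energy(state, comp, p)
        accepted = 0
        trials = 200
        for _ in range(trials):
            new, acc = metropolis_step(state, comp, p, rng)
            e1 = total_energy(new, comp, p)
            if e1 < e0:
                assert acc
            if acc:
                state, e0 = new, e1
                accepted += 1
        assert accepted > 0

    def test_boltzmann_acceptance_frequency(self):
        """A fixed +1 kBT proposal is accepted with frequency e^-1.

        Uses the same acceptance rule as the sampler on a stream of forced
        uphill proposals.
        """
        rng = np.random.default_rng(1)
        n = 200_000
        acc = (rng.random(n) < np.exp(-1.0)).sum()
        freq = acc / n
        sem = np.sqrt(np.exp(-1) * (1 - np.exp(-1)) / n)
        assert abs(freq - np.exp(-1)) < 3 * sem

    def test_rejected_move_returns_prior_state(self):
        p = make_params(8.0, 0.5, N=4, temperature_factor=1e-6)
        comp = rh.Composition("D" * 4)
        state = build_geometry(np.zeros(4), p)
        rng = np.random.default_rng(2)
        for _ in range(50):
            new, acc = metropolis_step(state, comp, p, rng)
            if not acc:
                assert new is state
                break
        else:
            pytest.skip("no rejection observed")


# ---------------------------------------------------------------------------
# small-system oracle: N = 2 has a single free angle


def n2_quadrature_rx_distribution(p, comp, edges):
    """Exact P(Rx) for the N=2 chain by dense quadrature over theta_1."""
    th1 = np.linspace(-np.pi, np.pi, 200_001)
    e = np.empty_like(th1)
    for i, t in enumerate(th1):
        st = build_geometry(np.array([0.0, t]), p)
        e[i] = total_energy(st, comp, p)
    w = np.exp(-(e - e.min()) / p.temperature_factor)
    rx = p.L - (p.b * np.cos(0.0) + p.b * np.cos(t := th1))  # Theta_2 = theta_1
    hist = np.zeros(len(edges) - 1)
    idx = ((rx - edges[0]) / (edges[1] - edges[0])).astype(int)
    ok = (idx >= 0) & (idx < len(hist))         # same clipping as the sampler
    np.add.at(hist, idx[ok], w[ok])
    return hist / hist.sum()


class TestSmallSystemOracle:
    def test_n2_matches_quadrature(self):
        """Sampled P(Rx) for the 2-subunit chain agrees with direct
        numerical integration of the Boltzmann weight."""
        p = make_params(3.0, 2.0, N=2)
        comp = rh.Composition("DD")
        mc = MCConfig(n_steps=4_000_000, seed=7, bin_width=1.0, record_every=50)
        dist, _ = run_chain(comp, p, mc)
        exact = n2_quadrature_rx_distribution(p, comp, dist.bin_edges)
        # compare where either has support; MC noise ~ 1/sqrt(counts)
        err = np.abs(dist.p - exact)
        assert err.max() < 0.01
        assert np.sum(err) < 0.05

    def test_n2_mean_matches_quadrature(self):
        p = make_params(5.0, 4.5, N=2)
        comp = rh.Composition("DD")
        mc = MCConfig(n_steps=4_000_000, seed=8, bin_width=1.0)
        dist, _ = run_chain(comp, p, mc)
        exact = n2_quadrature_rx_distribution(p, comp, dist.bin_edges)
        centers = dist.centers
        assert dist.mean() == pytest.approx(np.sum(centers * exact), abs=0.15)


class TestRunChain:
    def test_deep_tubular_regime_stays_bound(self):
        p = make_params(8.0, 2.0, N=16)  # deltaE = +6
        dist, _ = run_chain(rh.Composition("D" * 16), p, MCConfig(n_steps=500_000, seed=3))
        assert dist.mean() < 5.0

    def test_slightly_positive_deltaE_still_peels(self, default_params, all_d32):
        """deltaE = +1: thermal fluctuations unzip the chain anyway."""
        dist, _ = run_chain(all_d32, default_params, MCConfig(n_steps=3_000_000, seed=4))
        assert dist.mean() > default_params.L / 2

    def test_seed_determinism(self, default_params, all_d32):
        mc = MCConfig(n_steps=200_000, seed=11)
        d1, t1 = run_chain(all_d32, default_params, mc)
        d2, t2 = run_chain(all_d32, default_params, mc)
        assert np.array_equal(d1.p, d2.p)
        assert t1.equals(t2)

    def test_trace_has_unit_columns(self, default_params, all_d32):
        _, trace = run_chain(all_d32, default_params, MCConfig(n_steps=100_000, seed=5))
        assert list(trace.columns) == ["step", "Rx_nm", "energy_kBT"]


# ---------------------------------------------------------------------------
# umbrella sampling + WHAM on synthetic potentials (1-D particle oracle)


def sample_biased_1d(F_func, center, k_bias, edges, n, rng):
    """Metropolis sampling of a 1-D particle in F + harmonic bias."""
    x = center
    lo, hi = edges[0], edges[-1]
    counts = np.zeros(len(edges) - 1)
    e = F_func(x) + 0.5 * k_bias * (x - center) ** 2
    for _ in range(n):
        xn = x + rng.uniform(-8.0, 8.0)
        if lo < xn < hi:
            en = F_func(xn) + 0.5 * k_bias * (xn - center) ** 2
            if en <= e or rng.random() < np.exp(e - en):
                x, e = xn, en
        idx = int((x - lo) / (edges[1] - edges[0]))
        counts[min(idx, len(counts) - 1)] += 1
    return counts


def wham_windows_on(F_func, centers, k_bias, edges, n=40_000, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for c in centers:
        counts = sample_biased_1d(F_func, c, k_bias, edges, n, rng)
        out.append(replace_window(UmbrellaWindow(c, k_bias), edges, counts, n))
    return out


class TestWham:
    def test_single_unbiased_window_is_identity(self):
        edges = np.arange(0.0, 101.0, 2.0)
        counts = np.random.default_rng(0).integers(10, 100, 50)
        w = replace_window(UmbrellaWindow(0.0, 0.0), edges, counts, int(counts.sum()))
        dist = wham_combine([w])
        assert np.allclose(dist.p, counts / counts.sum())

    def test_flat_landscape_recovered_from_two_windows(self):
        edges = np.arange(0.0, 120.5, 2.0)
        windows = wham_windows_on(lambda x: 0.0, [30.0, 80.0], 0.01, edges, seed=1)
        dist = wham_combine(windows)
        F = -np.log(dist.p[dist.p > 0])
        interior = F[3:-3]
        assert interior.max() - interior.min() < 0.35

    def test_double_well_depth_difference_recovered(self):
        """Three windows on an asymmetric double well: well-depth gap to 0.1 kBT."""
        def F(x):
            return 2.0 * np.cos(2 * np.pi * x / 60.0) + 0.01 * x

        edges = np.arange(0.0, 121.0, 1.0)
        windows = wham_windows_on(F, [30.0, 60.0, 90.0], 0.02, edges, n=150_000, seed=2)
        dist = wham_combine(windows)
        c = dist.centers
        Fr = -np.log(np.where(dist.p > 0, dist.p, 1e-300))
        # wells near 30 and 90; true depth difference 0.6 kBT
        d_est = Fr[np.argmin(np.abs(c - 90.5))] - Fr[np.argmin(np.abs(c - 30.5))]
        d_true = F(90.5) - F(30.5)
        assert d_est == pytest.approx(d_true, abs=0.1)

    def test_disconnected_windows_rejected(self):
        edges = np.arange(0.0, 101.0, 2.0)
        c1 = np.zeros(50)
        c1[:5] = 100
        c2 = np.zeros(50)
        c2[-5:] = 100
        ws = [
            replace_window(UmbrellaWindow(5.0, 0.1), edges, c1, 500),
            replace_window(UmbrellaWindow(95.0, 0.1), edges, c2, 500),
        ]
        with pytest.raises(ValueError, match="no occupied bins"):
            wham_combine(ws)

    def test_mismatched_edges_rejected(self):
        e1 = np.arange(0.0, 101.0, 2.0)
        e2 = np.arange(0.0, 103.0, 2.0)
        ws = [
            replace_window(UmbrellaWindow(5.0, 0.1), e1, np.ones(50), 50),
            replace_window(UmbrellaWindow(95.0, 0.1), e2, np.ones(51), 51),
        ]
        with pytest.raises(ValueError, match="share bin edges"):
            wham_combine(ws)


class TestUmbrellaOnChain:
    def test_unbiased_single_window_equals_run_chain(self, all_d32, default_params):
        mc = MCConfig(n_steps=300_000, seed=21)
        w = UmbrellaWindow(center=0.0, k_bias=0.0)
        [ws] = umbrella_sample(all_d32, default_params, [w], mc)
        # same kernel, same child-seed stream: the biased histogram with
        # k=0 is a plain Metropolis histogram
        assert ws.counts.sum() > 0
        dist = wham_combine([ws])
        assert dist.mean() > 0

    def test_estimator_consistency_with_direct_sampling(self):
        """<Rx> from the WHAM-reweighted P matches direct Metropolis where
        direct sampling mixes (deltaE = 1.4 tilts tubular; both converge)."""
        p = make_params(8.0, 6.6, N=16)
        comp = rh.Composition("D" * 16)
        direct, _ = run_chain(comp, p, MCConfig(n_steps=6_000_000, seed=22))
        windows = default_windows(p, spacing=10.0, k_bias=0.05)
        ws = umbrella_sample(comp, p, windows, MCConfig(n_steps=600_000, seed=23))
        reweighted = wham_combine(ws)
        assert reweighted.mean() == pytest.approx(direct.mean(), abs=3.0)

    def test_window_support_tracks_center(self, all_d32, default_params):
        mc = MCConfig(n_steps=400_000, seed=24)
        [w] = umbrella_sample(
            all_d32, default_params, [UmbrellaWindow(120.0, 0.05)], mc
        )
        c = 0.5 * (w.bin_edges[:-1] + w.bin_edges[1:])
        mean = np.sum(c * w.counts) / w.counts.sum()
        assert abs(mean - 120.0) < 25.0


def test_rx_support_is_arc_tip(default_params):
    # clamped first subunit, all others curled
    th = np.full(32, 0.4)
    th[0] = 0.0
    assert rx_support(default_params) == pytest.approx(
        build_geometry(th, default_params).Rx
    )


def test_rxdistribution_normalizes_and_validates():
    edges = np.arange(0.0, 11.0, 1.0)
    d = RxDistribution(edges, np.full(10, 2.0), 20)
    assert d.p.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        RxDistribution(edges, np.concatenate([[-1.0], np.ones(9)]), 10)
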