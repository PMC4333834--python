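"""Equilibrium sampling of the chain: Metropolis MC, umbrella sampling, WHAM.

The reaction coordinate throughout is the tip excursion ``Rx = L - x_N``.
Direct Metropolis sampling yields P(Rx) in regimes where the chain mixes;
in the bistable transition zone harmonic umbrella windows on Rx are
recombined by self-consistent histogram reweighting (WHAM) to produce an
unbiased P(Rx) over the full support.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _kernels
from .model import ChainState, Composition, ModelParams, build_geometry, params_from_energies, total_energy

__all__ = [
    "MCConfig",
    "UmbrellaWindow",
    "RxDistribution",
    "metropolis_step",
    "run_chain",
    "default_windows",
    "umbrella_sample",
    "wham_combine",
    "sample_landscape_distribution",
    "transition_curve",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCConfig:
    """Metropolis run settings.

    ``max_rotation`` is the half-width of the uniform angle-increment
    proposal (the move pivots all subunits distal to the chosen bond).
    """

    n_steps: int = 2_000_000
    max_rotation: float = 1.5
    seed: int = 0
    record_every: int = 100
    burn_in: int | None = None      # None -> 10% of n_steps
    bin_width: float = 2.0          # Rx histogram resolution, nm

    def __post_init__(self) -> None:
        if self.max_rotation <= 0:
            raise ValueError("max_rotation must be positive")
        bi = self.resolved_burn_in
        if not self.n_steps > bi >= 0:
            raise ValueError("need n_steps > burn_in >= 0")

    @property
    def resolved_burn_in(self) -> int:
        return self.n_steps // 10 if self.burn_in is None else self.burn_in


@dataclass
class RxDistribution:
    """Normalized histogram of the tip coordinate."""

    bin_edges: np.ndarray
    p: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < 0):
            raise ValueError("probabilities must be non-negative")
        tot = self.p.sum()
        if tot > 0:
            self.p = self.p / tot

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mean(self) -> float:
        return float(np.sum(self.centers * self.p))

    def std(self) -> float:
        m = self.mean()
        return float(np.sqrt(np.sum((self.centers - m) ** 2 * self.p)))


@dataclass
class UmbrellaWindow:
    """One harmonic-bias window 0.5*k_bias*(Rx-center)^2 and its biased counts."""

    center: float
    k_bias: float
    bin_edges: np.ndarray | None = None
    counts: np.ndarray | None = None
    n_samples: int = 0


# ---------------------------------------------------------------------------


def rx_support(params: ModelParams) -> float:
    """Largest Rx reachable with the clamped minus end (all free bonds at thetaD)."""
    th = np.full(params.N, params.thetaD)
    th[0] = 0.0
    return build_geometry(th, params).Rx


def _initial_theta(params: ModelParams, target_rx: float | None = None) -> np.ndarray:
    """Straight chain, or a tip-peeled arc whose Rx is close to ``target_rx``."""
    th = np.zeros(params.N)
    if target_rx is None or target_rx <= 0:
        return th
    best = 0
    best_err = target_rx
    for nc in range(1, params.N):
        t = np.zeros(params.N)
        t[params.N - nc:] = params.thetaD
        err = abs(build_geometry(t, params).Rx - target_rx)
        if err < best_err:
            best, best_err = nc, err
    th[params.N - best:] = params.thetaD if best else 0.0
    return th


def metropolis_step(
    state: ChainState,
    comp: Composition,
    params: ModelParams,
    rng: np.random.Generator,
    max_rotation: float = 1.5,
) -> tuple[ChainState, bool]:
    """One pivot move on a ChainState (reference path; the production
    sampler runs the compiled kernel).

    Picks a free bond j >= 1 uniformly, increments theta_j by a uniform
    draw in [-max_rotation, +max_rotation] (all distal subunits rotate
    rigidly), and accepts with probability min(1, exp(-beta dE)).
    """
    j = int(rng.integers(1, params.N))
    dth = rng.uniform(-max_rotation, max_rotation)
    theta_new = state.theta.copy()
    theta_new[j] += dth
    trial = build_geometry(theta_new, params)
    de = total_energy(trial, comp, params) - total_energy(state, comp, params)
    tf = params.temperature_factor
    if de <= 0 or (tf > 0 and rng.random() < math.exp(-de / tf)):
        return trial, True
    return state, False


def _edges(params: ModelParams, bin_width: float) -> np.ndarray:
    # headroom above the zero-temperature arc tip: thermal fluctuations
    # overshoot it, and Rx is bounded by 2L only
    hi = min(2.0 * params.L, rx_support(params) + max(10.0, 0.05 * params.L))
    n = int(np.ceil(hi / bin_width))
    return np.linspace(0.0, n * bin_width, n + 1)


def run_chain(
    comp: Composition,
    params: ModelParams,
    mc: MCConfig,
    initial_rx: float | None = None,
) -> tuple[RxDistribution, pd.DataFrame]:
    """Direct Metropolis sampling; returns the post-burn-in Rx histogram
    and a thinned trace (step, Rx_nm, energy_kBT)."""
    if len(comp) != params.N:
        raise ValueError("composition length does not match N")
    edges = _edges(params, mc.bin_width)
    theta = _initial_theta(params, initial_rx)
    out = _kernels.chain_mc(
        theta, comp.theta0(params),
        params.b, params.l0, params.lmax, params.ks, params.kb,
        params.temperature_factor,
        mc.n_steps, mc.resolved_burn_in, mc.record_every, mc.max_rotation,
        0.0, 0.0, edges, _u32(mc.seed),
    )
    hist, t_step, t_rx, t_e, n_acc, _, _, n_meas, _ = out
    logger.info("metropolis: %d steps, acceptance %.2f%%", mc.n_steps, 100 * n_acc / mc.n_steps)
    dist = RxDistribution(edges, hist.astype(float), n_samples=int(n_meas))
    trace = pd.DataFrame({"step": t_step, "Rx_nm": t_rx, "energy_kBT": t_e})
    return dist, trace


def _u32(seed: int) -> int:
    return int(np.uint32(seed))


def default_windows(
    params: ModelParams,
    spacing: float = 10.0,
    k_bias: float = 0.05,
    rx_max: float | None = None,
) -> list[UmbrellaWindow]:
    """Evenly spaced harmonic windows covering [0, rx_max]."""
    hi = rx_support(params) if rx_max is None else rx_max
    centers = np.arange(0.0, hi + 0.5 * spacing, spacing)
    return [UmbrellaWindow(center=float(c), k_bias=k_bias) for c in centers]


def umbrella_sample(
    comp: Composition,
    params: ModelParams,
    windows: list[UmbrellaWindow],
    mc: MCConfig,
) -> list[UmbrellaWindow]:
    """Sample each window with its bias added to the physical energy.

    Every window is initialized from a peeled-arc configuration near its
    center and gets an independent child seed derived from ``mc.seed``.
    """
    if len(comp) != params.N:
        raise ValueError("composition length does not match N")
    edges = _edges(params, mc.bin_width)
    seeds = np.random.SeedSequence(mc.seed).generate_state(len(windows))
    out = []
    for w, s in zip(windows, seeds):
        theta = _initial_theta(params, w.center)
        res = _kernels.chain_mc(
            theta, comp.theta0(params),
            params.b, params.l0, params.lmax, params.ks, params.kb,
            params.temperature_factor,
            mc.n_steps, mc.resolved_burn_in, mc.record_every, mc.max_rotation,
            w.k_bias, w.center, edges, _u32(int(s)),
        )
        hist, _, _, _, n_acc, _, _, n_meas, _ = res
        if hist.sum() == 0:
            logger.warning(
                "umbrella window at %.1f nm collected no samples; rerun with "
                "smaller k_bias or a wider histogram", w.center,
            )
        out.append(replace_window(w, edges, hist, int(n_meas)))
    return out


def replace_window(w: UmbrellaWindow, edges, counts, n) -> UmbrellaWindow:
    return UmbrellaWindow(center=w.center, k_bias=w.k_bias, bin_edges=edges,
                          counts=np.asarray(counts), n_samples=n)


def wham_combine(
    windows: list[UmbrellaWindow],
    tol: float = 1e-8,
    max_iter: int = 100_000,
    temperature_factor: float = 1.0,
) -> RxDistribution:
    """Self-consistent histogram reweighting of biased windows.

    Iterates the standard coupled equations for the unbiased bin
    probabilities and per-window free-energy shifts f_k until no shift
    changes by more than ``tol`` kBT.  Windows must share bin edges and
    form one overlapping chain along Rx.
    """
    if not windows:
        raise ValueError("need at least one window")
    edges = windows[0].bin_edges
    for w in windows:
        if w.bin_edges is None or w.counts is None:
            raise ValueError("windows must be sampled first")
        if not np.array_equal(w.bin_edges, edges):
            raise ValueError("all windows must share bin edges")
    centers = 0.5 * (edges[:-1] + edges[1:])
    K = len(windows)
    n_ki = np.stack([w.counts for w in windows]).astype(float)
    N_k = n_ki.sum(axis=1)
    _check_overlap(windows, n_ki)
    beta = 1.0 / temperature_factor
    bias = np.stack([
        0.5 * w.k_bias * (centers - w.center) ** 2 for w in windows
    ])
    w_ki = np.exp(-beta * (bias - bias.min()))
    n_i = n_ki.sum(axis=0)
    f = np.zeros(K)
    for _ in range(max_iter):
        denom = (N_k[:, None] * np.exp(f)[:, None] * w_ki).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, n_i / denom, 0.0)
        z = w_ki @ p
        f_new = -np.log(np.where(z > 0, z, 1.0))
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    denom = (N_k[:, None] * np.exp(f)[:, None] * w_ki).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, n_i / denom, 0.0)
    return RxDistribution(edges, p, n_samples=int(N_k.sum()))


def _check_overlap(windows, n_ki) -> None:
    """Every adjacent pair of windows (by center) must share occupied bins."""
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((n_ki[a] > 0) & (n_ki[b] > 0)):
            raise ValueError(
                f"umbrella windows at {windows[a].center:.1f} and "
                f"{windows[b].center:.1f} nm share no occupied bins; "
                "decrease spacing or k_bias"
            )


def sample_landscape_distribution(
    comp: Composition,
    params: ModelParams,
    mc: MCConfig,
    spacing: float = 10.0,
    k_bias: float = 0.05,
    rx_max: float | None = None,
) -> RxDistribution:
    """Umbrella-sample and WHAM-recombine P(Rx) over the full support."""
    windows = default_windows(params, spacing=spacing, k_bias=k_bias, rx_max=rx_max)
    sampled = umbrella_sample(comp, params, windows, mc)
    return wham_combine(sampled, temperature_factor=params.temperature_factor)


def transition_curve(
    params_base: ModelParams,
    deltaE_grid: np.ndarray,
    comp: Composition,
    mc: MCConfig,
    method: str = "umbrella",
    Ems: float | None = None,
) -> pd.DataFrame:
    """<Rx> and SD versus the power-struggle parameter deltaE.

    The grid is realized by varying Emb at fixed Ems (default: the base
    parameters' Ems).  ``method='umbrella'`` estimates the moments from the
    WHAM-recombined P(Rx), which converges through the bistable transition
    zone at modest step budgets; ``method='metropolis'`` uses direct
    sampling.
    """
    if method not in ("umbrella", "metropolis"):
        raise ValueError("method must be 'umbrella' or 'metropolis'")
    ems = params_base.Ems if Ems is None else Ems
    rows = []
    for i, de in enumerate(np.asarray(deltaE_grid, dtype=float)):
        p = params_from_energies(ems, ems - de, params_base)
        mc_i = replace(mc, seed=mc.seed + 1000 * (i + 1))
        if method == "umbrella":
            dist = sample_landscape_distribution(comp, p, mc_i)
        else:
            dist, _ = run_chain(comp, p, mc_i)
        rows.append({"deltaE_kBT": de, "Rx_mean_nm": dist.mean(), "Rx_sd_nm": dist.std()})
    return pd.DataFrame(rows)
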