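"""Tip Langevin dynamics on the landscape, coupled to subunit dissociation.

Between dissociation events the tip diffuses on F(Rx) by overdamped
Euler-Maruyama dynamics; while the protofilament is unzippered beyond a
gate (``rx_gate``, at least one subunit's worth of peeling) exposed
subunits dissociate as a Poisson process with rate ``k_off``.  Each event
shortens the peeled arc by one subunit, remapping Rx through the
zero-temperature tip-position geometry, and the observable microtubule
length follows

    L_obs(t) = L_obs(0) - Rx(t) * l_d - b * Nd(t),

whose ensemble-mean slope is the shrinkage velocity v-.  "Ram's horn"
statistics (mean excursion lifetime Tu, events per second Nu) are read off
the Rx(t) trace with a 10 nm excursion threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _kernels
from .landscape import Landscape, tilt

__all__ = [
    "LangevinConfig",
    "DissociationConfig",
    "ShrinkageTrajectory",
    "HornStats",
    "langevin_trajectory",
    "simulate_shrinkage",
    "shrinkage_velocity",
    "horn_statistics",
    "force_response",
    "first_passage_ensemble",
]


@dataclass(frozen=True)
class LangevinConfig:
    dt: float = 1e-7            # s
    t_total: float = 0.1        # s
    seed: int = 0
    D: float = 5.457e6          # nm^2/s (Stokes-Einstein, a = 40 nm, 298 K)
    record_every: int = 100

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_total <= 0 or self.D <= 0:
            raise ValueError("dt, t_total and D must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total / self.dt))


@dataclass(frozen=True)
class DissociationConfig:
    k_off: float = 75.0         # 1/s per exposed tip subunit
    rx_gate: float = 8.0        # nm; no dissociation while Rx <= gate (tubular)

    def __post_init__(self) -> None:
        if self.k_off < 0 or self.rx_gate < 0:
            raise ValueError("k_off and rx_gate must be non-negative")


@dataclass
class ShrinkageTrajectory:
    """Time series of tip position, dissociation count and observable length."""

    t: np.ndarray
    Rx: np.ndarray
    Nd: np.ndarray
    Lobs: np.ndarray
    dt_record: float
    params: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "Rx_nm": self.Rx,
                             "Nd": self.Nd, "Lobs_nm": self.Lobs})


@dataclass(frozen=True)
class HornStats:
    """Lifetime and frequency of unzippered (Rx > threshold) excursions.

    With no excursions Nu = 0 and Tu is reported missing (None), not 0.
    """

    Tu: float | None
    Nu: float
    threshold: float


def _prepare(landscape: Landscape, cfg: LangevinConfig, bin_width: float = 2.0):
    """Dense gradient table + drift-step sanity check."""
    lo, hi = landscape.support
    dx = 0.25
    x = np.arange(lo, hi + dx / 2, dx)
    F = landscape(x)
    grad = np.gradient(F, x)
    max_drift = np.max(np.abs(grad)) * cfg.D * cfg.dt
    if max_drift > bin_width:
        raise ValueError(
            f"drift per step {max_drift:.2f} nm exceeds {bin_width} nm; "
            f"reduce dt below {bin_width / (np.max(np.abs(grad)) * cfg.D):.2e} s"
        )
    return x, grad, lo, hi


def _geometry_tables(b: float, rc: float, L: float):
    """Monotone (Lc, Rx0) tables of the zero-temperature tip relation."""
    lc = np.linspace(0.0, L, 2048)
    rx0 = lc - rc * np.sin(lc / rc)
    rx0 = np.maximum.accumulate(rx0) + 1e-9 * lc   # strictly increasing
    return lc, rx0


def langevin_trajectory(
    landscape: Landscape,
    cfg: LangevinConfig,
    rx_init: float | None = None,
) -> ShrinkageTrajectory:
    """Pure tip diffusion on the landscape (no dissociation), reflecting at
    both support ends; deterministic per seed."""
    x, grad, lo, hi = _prepare(landscape, cfg)
    rx0 = lo if rx_init is None else rx_init
    lc_tab, rx0_tab = _geometry_tables(8.0, 20.0, hi * 2 + 16.0)
    t, rx, nd, lobs = _kernels.langevin(
        grad, x[0], x[1] - x[0], lo, hi,
        cfg.D, cfg.dt, cfg.n_steps, cfg.record_every,
        rx0, int(np.uint32(cfg.seed)),
        0.0, 0.0, 8.0, 1.0, np.inf, lc_tab, rx0_tab,
    )
    lobs = hi - rx             # nominal observable length; no dissociation
    return ShrinkageTrajectory(t, rx, nd, lobs, cfg.dt * cfg.record_every,
                               {"seed": cfg.seed, "D": cfg.D, "dt": cfg.dt})


def simulate_shrinkage(
    landscape: Landscape,
    lcfg: LangevinConfig,
    dcfg: DissociationConfig,
    l_d: float = 1.0,
    L0: float | None = None,
    b: float = 8.0,
    rc: float = 20.0,
    rx_init: float | None = None,
) -> ShrinkageTrajectory:
    """Langevin tip motion with gated Poisson dissociation.

    ``L0`` defaults to 50 full subunit lengths above the landscape support
    so that runs of a few seconds do not exhaust the filament; the run ends
    cleanly if L_obs reaches zero.
    """
    if L0 is None:
        L0 = landscape.support[1] + 50 * b
    if L0 <= 0:
        raise ValueError("L0 must be positive")
    x, grad, lo, hi = _prepare(landscape, lcfg)
    lc_tab, rx0_tab = _geometry_tables(b, rc, max(L0, 2 * hi) + b)
    t, rx, nd, lobs = _kernels.langevin(
        grad, x[0], x[1] - x[0], lo, hi,
        lcfg.D, lcfg.dt, lcfg.n_steps, lcfg.record_every,
        lo if rx_init is None else rx_init, int(np.uint32(lcfg.seed)),
        dcfg.k_off, dcfg.rx_gate, b, l_d, L0, lc_tab, rx0_tab,
    )
    return ShrinkageTrajectory(
        t, rx, nd, lobs, lcfg.dt * lcfg.record_every,
        {"seed": lcfg.seed, "D": lcfg.D, "dt": lcfg.dt, "k_off": dcfg.k_off,
         "rx_gate": dcfg.rx_gate, "l_d": l_d, "L0": L0, "b": b},
    )


def shrinkage_velocity(
    trajectories: list[ShrinkageTrajectory],
    transient_fraction: float = 0.1,
) -> tuple[float, float]:
    """v- = -d<L_obs>/dt by least squares over the post-transient window.

    Returns (v-, SEM) in nm/s; SEM across per-trajectory slopes (0 for a
    single trajectory).
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    n = min(len(tr.t) for tr in trajectories)
    i0 = int(n * transient_fraction)
    if n - i0 < 2:
        raise ValueError("trajectories shorter than the transient window")
    slopes = []
    for tr in trajectories:
        c = np.polyfit(tr.t[i0:n], tr.Lobs[i0:n], 1)
        slopes.append(-c[0])
    slopes = np.asarray(slopes)
    sem = slopes.std(ddof=1) / np.sqrt(len(slopes)) if len(slopes) > 1 else 0.0
    return float(slopes.mean()), float(sem)


def horn_statistics(
    traj: ShrinkageTrajectory,
    threshold: float = 10.0,
    debounce: int = 10,
) -> HornStats:
    """Excursion statistics of Rx above the ram's-horn threshold.

    An event is a maximal contiguous interval with Rx > threshold;
    excursions and gaps shorter than ``debounce`` recorded samples are
    merged to avoid counting integrator chatter.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    above = traj.Rx > threshold
    if not above.any():
        return HornStats(Tu=None, Nu=0.0, threshold=threshold)
    # merge short gaps, then drop short excursions
    runs = _runs(above)
    runs = [r for r in _merge_gaps(runs, len(above), debounce) if r[1] - r[0] >= debounce]
    total_t = traj.t[-1] - traj.t[0] + traj.dt_record
    if not runs:
        return HornStats(Tu=None, Nu=0.0, threshold=threshold)
    durations = [(b - a) * traj.dt_record for a, b in runs]
    return HornStats(Tu=float(np.mean(durations)),
                     Nu=float(len(runs) / total_t), threshold=threshold)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _merge_gaps(runs, n, debounce):
    if not runs:
        return runs
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] < debounce:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [tuple(r) for r in merged]


def force_response(
    landscape: Landscape,
    f_grid,
    lcfg: LangevinConfig,
    dcfg: DissociationConfig,
    n_traj: int = 8,
    l_d: float = 1.0,
) -> pd.DataFrame:
    """Shrinkage velocity versus pulling force on the tilted landscape.

    Reports per-force v- with SEM and whether the sequence is monotone
    decreasing.
    """
    rows = []
    for i, f in enumerate(np.asarray(f_grid, dtype=float)):
        if f < 0:
            raise ValueError("forces must be >= 0")
        land_f = tilt(landscape, f)
        trajs = [
            simulate_shrinkage(
                land_f, replace(lcfg, seed=lcfg.seed + 7919 * i + k), dcfg, l_d=l_d
            )
            for k in range(n_traj)
        ]
        v, sem = shrinkage_velocity(trajs)
        rows.append({"f_pN": f, "v_minus_nm_s": v, "sem_nm_s": sem})
    df = pd.DataFrame(rows)
    df.attrs["monotone_decreasing"] = bool(np.all(np.diff(df["v_minus_nm_s"]) <= 0))
    return df


def first_passage_ensemble(
    landscape: Landscape,
    cfg: LangevinConfig,
    A: float,
    B: float,
    n_runs: int = 1000,
    max_time: float = 1.0,
) -> np.ndarray:
    """First-passage times A -> B from direct Langevin runs (NaN if not
    reached within ``max_time``); the simulation cross-check for the
    quadrature mean first-passage time."""
    x, grad, lo, hi = _prepare(landscape, cfg)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(n_runs)
    out = np.empty(n_runs)
    max_steps = int(max_time / cfg.dt)
    for k, s in enumerate(seeds):
        out[k] = _kernels.first_passage(
            grad, x[0], x[1] - x[0], lo, B, cfg.D, cfg.dt, A,
            int(np.uint32(s)), max_steps,
        )
    return out
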