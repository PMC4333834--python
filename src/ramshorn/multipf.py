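"""Three-protofilament model: planar chains on planes at 120 degrees.

Three PFs spring from an equilateral triangular cross-section of side l0
(so the straight tube stores no lateral energy).  Each PF bends only in
the plane spanned by the tube axis x and its own radial direction; lateral
bonds connect same-index subunits of cyclically adjacent PFs through the
full 3-D distance.  Freezing one or two PFs straight interpolates between
the tube and the single-PF-against-rigid-wall model: the effective lateral
energy per bendable PF is the total bond capacity shared among the p
bendable PFs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .model import Composition, ModelParams, params_from_energies
from .sampling import MCConfig, RxDistribution

__all__ = [
    "MultiPFState",
    "EffectiveEnergy",
    "build_3pf",
    "run_3pf_mc",
    "effective_lateral_energy",
    "destabilization_threshold",
]


@dataclass
class MultiPFState:
    """Angles and derived 3-D geometry of the three chains.

    ``theta[a]`` follows the single-PF convention (clamp + relative
    angles); ``bendable`` marks which PFs may move.  In-plane coordinates
    (x, y) have y as the outward radial excursion; the straight tube sits
    at radius R = l0/sqrt(3) from the centroid.
    """

    theta: np.ndarray           # (3, N)
    bendable: np.ndarray        # (3,) bool
    params: ModelParams

    @property
    def R(self) -> float:
        return self.params.l0 / np.sqrt(3.0)

    def plane_angles(self) -> np.ndarray:
        return np.deg2rad(np.array([90.0, 210.0, 330.0]))

    def inplane_nodes(self, a: int) -> np.ndarray:
        """(N+1, 2) in-plane node coordinates of PF a."""
        p = self.params
        big = np.cumsum(self.theta[a])
        nodes = np.zeros((p.N + 1, 2))
        nodes[1:, 0] = np.cumsum(p.b * np.cos(big))
        nodes[1:, 1] = np.cumsum(p.b * np.sin(big))
        return nodes

    def nodes3d(self, a: int) -> np.ndarray:
        """(N+1, 3) coordinates: x along the tube axis, (y, z) in the
        cross-section, PF planes at 120 degrees."""
        phi = self.plane_angles()[a]
        ip = self.inplane_nodes(a)
        r = self.R + ip[:, 1]
        out = np.empty((len(ip), 3))
        out[:, 0] = ip[:, 0]
        out[:, 1] = r * np.cos(phi)
        out[:, 2] = r * np.sin(phi)
        return out

    def lateral_distances(self) -> np.ndarray:
        """(3, N) distances l_{i,alpha} between node i of PF alpha and PF
        alpha+1 (cyclic)."""
        p = self.params
        nd = [self.nodes3d(a) for a in range(3)]
        out = np.empty((3, p.N))
        for a in range(3):
            d = nd[a][1:] - nd[(a + 1) % 3][1:]
            out[a] = np.linalg.norm(d, axis=1)
        return out

    def rx(self, a: int) -> float:
        return self.params.L - self.inplane_nodes(a)[-1, 0]


def build_3pf(params: ModelParams, bendable=(True, True, True)) -> MultiPFState:
    """Three straight PFs whose same-index subunits sit at mutual distance
    l0 (equilateral cross-section), zero lateral energy."""
    theta = np.zeros((3, params.N))
    return MultiPFState(theta=theta, bendable=np.asarray(bendable, dtype=bool),
                        params=params)


@dataclass(frozen=True)
class EffectiveEnergy:
    """Lateral bond capacity per bendable PF, kBT."""

    p: int
    Eeff: float


def effective_lateral_energy(p: int, per_bond: float) -> EffectiveEnergy:
    """Total lateral capacity shared among the p bendable PFs.

    One bendable PF engages its two bonds alone (2*per_bond); two share
    three bonds (3/2*per_bond each); three share three (per_bond each).
    """
    if p not in (1, 2, 3):
        raise ValueError("p must be 1, 2 or 3")
    factor = {1: 2.0, 2: 1.5, 3: 1.0}[p]
    return EffectiveEnergy(p=p, Eeff=factor * per_bond)


def run_3pf_mc(
    state: MultiPFState,
    comp: Composition,
    params: ModelParams,
    mc: MCConfig,
    bendable_mask=None,
) -> dict:
    """Metropolis sampling of the bendable PFs; per-PF Rx statistics.

    Returns a dict with per-PF RxDistribution, means and SDs (bendable PFs
    only carry meaning; frozen PFs stay at Rx = 0 exactly).
    """
    bendable = state.bendable if bendable_mask is None else np.asarray(bendable_mask, bool)
    if not bendable.any():
        raise ValueError("need at least one bendable protofilament")
    if len(comp) != params.N:
        raise ValueError("composition length does not match N")
    hi = params.L + 2 * params.b
    nb = int(np.ceil(hi / mc.bin_width))
    edges = np.linspace(0.0, nb * mc.bin_width, nb + 1)
    hist, s1, s2, n, n_acc, theta_f, _, _ = _kernels.mc3(
        state.theta, comp.theta0(params), bendable.astype(np.uint8),
        params.b, params.l0, params.lmax, params.ks, params.kb,
        params.temperature_factor,
        mc.n_steps, mc.resolved_burn_in, max(mc.record_every // 10, 1),
        mc.max_rotation, edges, int(np.uint32(mc.seed)),
    )
    out = {
        "bendable": bendable,
        "acceptance": n_acc / mc.n_steps,
        "final_theta": theta_f,
        "per_pf": [],
    }
    for a in range(3):
        mean = s1[a] / n
        var = max(s2[a] / n - mean**2, 0.0)
        out["per_pf"].append({
            "pf": a,
            "dist": RxDistribution(edges, hist[a].astype(float), n_samples=int(n)),
            "Rx_mean_nm": float(mean),
            "Rx_sd_nm": float(np.sqrt(var)),
        })
    means = [r["Rx_mean_nm"] for r, bb in zip(out["per_pf"], bendable) if bb]
    out["Rx_mean_bendable_nm"] = float(np.mean(means))
    return out


def _mean_rx_two_starts(
    p_emb: ModelParams, comp: Composition, mc: MCConfig, bendable: np.ndarray
) -> float:
    """<Rx> over bendable PFs, averaged over a straight start and a fully
    peeled start to symmetrize residual hysteresis at modest step budgets."""
    means = []
    for kind, seed_off in (("straight", 0), ("peeled", 1)):
        st = build_3pf(p_emb, bendable)
        if kind == "peeled":
            for a in range(3):
                if bendable[a]:
                    st.theta[a, 1:] = p_emb.thetaD
        res = run_3pf_mc(st, comp, p_emb, replace(mc, seed=mc.seed + seed_off))
        means.append(res["Rx_mean_bendable_nm"])
    return float(np.mean(means))


def destabilization_threshold(
    p: int,
    params_base: ModelParams,
    mc: MCConfig,
    per_bond: float = 4.0,
    emb_lo: float = 0.5,
    emb_hi: float = 12.0,
    resolution: float = 0.25,
) -> float:
    """Smallest per-subunit bending energy Emb making <Rx> >= L/2, kBT.

    Bisection over Emb at fixed per-bond lateral energy, with p bendable
    PFs (the rest frozen straight), bracketed to +/- ``resolution``.
    """
    effective_lateral_energy(p, per_bond)  # validates p
    comp = Composition("D" * params_base.N)
    bendable = np.array([i < p for i in range(3)])
    half_L = params_base.L / 2.0

    def unstable(emb: float, i: int) -> bool:
        prm = params_from_energies(per_bond, emb, params_base)
        m = _mean_rx_two_starts(prm, comp, replace(mc, seed=mc.seed + 100 * i), bendable)
        return m >= half_L

    if unstable(emb_lo, 0):
        raise ValueError(f"already unstable at Emb = {emb_lo} kBT; lower emb_lo")
    if not unstable(emb_hi, 1):
        raise ValueError(f"still stable at Emb = {emb_hi} kBT; raise emb_hi")
    lo, hi = emb_lo, emb_hi
    i = 2
    while hi - lo > 2 * resolution:
        mid = 0.5 * (lo + hi)
        if unstable(mid, i):
            hi = mid
        else:
            lo = mid
        i += 1
    return 0.5 * (lo + hi)
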