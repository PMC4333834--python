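"""Mechanical model of a single protofilament against a rigid neighbor.

A protofilament (PF) is a chain of ``N`` rigid subunits of length ``b``
confined to a plane.  Each subunit is laterally bonded to a fixed site on a
rigid neighboring PF by a breakable Hookean spring (rest length ``l0``,
broken beyond ``lmax``), and longitudinal bonds carry a bending energy
``kb * (1 - cos(theta - theta0))`` with a nucleotide-dependent preferred
angle: GDP (D) subunits prefer an outward kink ``thetaD`` while GTP (T)
subunits prefer to stay straight.

Two derived energy scales summarize the "power struggle" of the model:

* ``Ems = ks/2 * (lmax - l0)**2`` -- maximum energy stored in one lateral
  bond before it breaks;
* ``Emb = kb * (1 - cos(thetaD))`` -- bending strain per subunit stored in
  a straightened GDP lattice.

Their difference ``deltaE = Ems - Emb`` controls whether the PF stays
tubular or peels off into a "ram's horn".

Units: energies in kBT (at the reference temperature), lengths in nm,
angles in rad.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelParams",
    "Composition",
    "ChainState",
    "lateral_energy",
    "bending_energy",
    "total_energy",
    "build_geometry",
    "params_from_energies",
    "cap_composition",
    "write_xyz",
]


@dataclass(frozen=True)
class ModelParams:
    """Mechanical and thermal constants of the chain and its lateral bonds.

    ``temperature_factor`` is a dimensionless rescaling of temperature:
    1 is the reference temperature at which energies are expressed in kBT;
    values -> 0 approach the zero-temperature (quenched) limit.
    """

    b: float = 8.0
    N: int = 32
    l0: float = 6.5
    lmax: float = 7.8
    ks: float = 2.0 * 8.0 / 1.3**2
    kb: float = 7.0 / (1.0 - np.cos(0.4))
    thetaD: float = 0.4
    thetaT: float = 0.0
    temperature_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError("subunit length b must be positive")
        if self.N < 2:
            raise ValueError("need at least 2 subunits")
        if not (self.lmax > self.l0 > 0):
            raise ValueError("require lmax > l0 > 0")
        if self.ks < 0 or self.kb < 0:
            raise ValueError("stiffnesses must be non-negative")
        if self.temperature_factor < 0:
            raise ValueError("temperature_factor must be >= 0")

    @property
    def Ems(self) -> float:
        """Maximum lateral-bond energy, ks/2 (lmax-l0)^2, kBT."""
        return 0.5 * self.ks * (self.lmax - self.l0) ** 2

    @property
    def Emb(self) -> float:
        """Bending strain per straightened GDP subunit, kb (1-cos thetaD), kBT."""
        return self.kb * (1.0 - np.cos(self.thetaD))

    @property
    def deltaE(self) -> float:
        """Power-struggle parameter Ems - Emb, kBT (derived, never stored)."""
        return self.Ems - self.Emb

    @property
    def L(self) -> float:
        """Contour length N*b, nm."""
        return self.N * self.b

    @property
    def rc(self) -> float:
        """Intrinsic radius of curvature b/thetaD of the GDP chain, nm."""
        if self.thetaD == 0:
            raise ValueError("rc undefined for thetaD = 0")
        return self.b / self.thetaD


def params_from_energies(Ems: float, Emb: float, base: ModelParams) -> ModelParams:
    """Back-compute (ks, kb) from the energy scales (Ems, Emb).

    Round-trips with the ``ModelParams.Ems`` / ``.Emb`` accessors.
    """
    if Ems < 0 or Emb < 0:
        raise ValueError("Ems and Emb must be non-negative")
    gap = base.lmax - base.l0
    if gap == 0 and Ems > 0:
        raise ValueError("lmax == l0: cannot realize a nonzero Ems")
    strain = 1.0 - np.cos(base.thetaD)
    if strain == 0 and Emb > 0:
        raise ValueError("thetaD == 0: cannot realize a nonzero Emb")
    ks = 0.0 if Ems == 0 else 2.0 * Ems / gap**2
    kb = 0.0 if Emb == 0 else Emb / strain
    return replace(base, ks=ks, kb=kb)


@dataclass(frozen=True)
class Composition:
    """Per-subunit nucleotide labels, tip (plus end) last.

    ``nucleotide[i]`` labels subunit ``i+1``; the preferred angle of the
    bond proximal to subunit ``i+1`` (the clamp bond for i = 0) follows
    that subunit's label.
    """

    nucleotide: str

    def __post_init__(self) -> None:
        if not set(self.nucleotide) <= {"T", "D"}:
            raise ValueError("nucleotide labels must be 'T' or 'D'")
        if len(self.nucleotide) < 2:
            raise ValueError("composition needs at least 2 subunits")

    def __len__(self) -> int:
        return len(self.nucleotide)

    def theta0(self, params: ModelParams) -> np.ndarray:
        """Preferred bond angles theta_i^o, one per bond (length N)."""
        return np.array(
            [params.thetaT if c == "T" else params.thetaD for c in self.nucleotide]
        )


def cap_composition(m: int, n_bulk: int) -> Composition:
    """A GDP bulk of ``n_bulk`` subunits capped by ``m`` GTP subunits at the tip."""
    if m < 0 or n_bulk < 1:
        raise ValueError("need m >= 0 and n_bulk >= 1")
    return Composition("D" * n_bulk + "T" * m)


@dataclass(frozen=True)
class ChainState:
    """Conformation of the chain: angles, node coordinates, bond lengths.

    ``theta[0]`` is the clamp angle of subunit 1 relative to the +x wall
    direction; ``theta[i]`` (i >= 1) is the relative angle between
    subunits i and i+1.  ``nodes`` holds the N+1 subunit endpoints,
    ``li`` the N lateral distances, ``Rx = L - x_N`` the tip coordinate,
    and ``Lc = Nc*b`` the contiguously peeled length from the tip.
    """

    theta: np.ndarray
    nodes: np.ndarray
    li: np.ndarray
    Rx: float
    Lc: float
    Nc: int
    params: ModelParams = field(repr=False)


def build_geometry(theta: np.ndarray, params: ModelParams) -> ChainState:
    """Construct node coordinates and lateral distances from bond angles.

    Pure function of (theta, params): node k sits at node k-1 plus
    ``b*(cos Theta_k, sin Theta_k)`` with Theta_k the cumulative angle.
    The rigid neighbor's attachment sites are at (i*b, -l0), so a straight
    chain has li = l0 everywhere and peeling (positive theta) stretches
    the bonds.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (params.N,):
        raise ValueError(f"theta must have {params.N} entries (clamp + N-1 relative)")
    big_theta = np.cumsum(theta)
    nodes = np.zeros((params.N + 1, 2))
    nodes[1:, 0] = np.cumsum(params.b * np.cos(big_theta))
    nodes[1:, 1] = np.cumsum(params.b * np.sin(big_theta))
    sites_x = params.b * np.arange(1, params.N + 1)
    li = np.hypot(nodes[1:, 0] - sites_x, nodes[1:, 1] + params.l0)
    Rx = params.L - nodes[-1, 0]
    if not (-1e-9 <= Rx <= 2 * params.L):
        raise ValueError(f"tip coordinate Rx={Rx:.3f} outside sanity bound [0, 2L]")
    broken = li >= params.lmax
    Nc = 0
    for flag in broken[::-1]:
        if not flag:
            break
        Nc += 1
    return ChainState(
        theta=theta, nodes=nodes, li=li, Rx=max(Rx, 0.0),
        Lc=Nc * params.b, Nc=Nc, params=params,
    )


def lateral_energy(li: float, params: ModelParams) -> float:
    """Breakable-spring energy of one lateral bond, kBT.

    Harmonic below ``lmax``, constant plateau ``Ems`` beyond (the bond is
    "broken" but re-forms freely if the distance shrinks again: the energy
    is history-free).
    """
    if li < 0:
        raise ValueError("lateral distance must be non-negative")
    if li < params.lmax:
        return 0.5 * params.ks * (li - params.l0) ** 2
    return params.Ems


def bending_energy(theta_i: float, theta0_i: float, params: ModelParams) -> float:
    """Longitudinal-bond bending energy kb (1 - cos(theta - theta0)), kBT."""
    return params.kb * (1.0 - np.cos(theta_i - theta0_i))


def total_energy(state: ChainState, comp: Composition, params: ModelParams) -> float:
    """Total energy: sum of all lateral and bending terms (additive)."""
    if len(comp) != params.N:
        raise ValueError("composition length does not match N")
    theta0 = comp.theta0(params)
    e = sum(bending_energy(t, t0, params) for t, t0 in zip(state.theta, theta0))
    e += sum(lateral_energy(l, params) for l in state.li)
    return float(e)


def write_xyz(state: ChainState, path: str, comment: str = "") -> None:
    """Dump node coordinates as simple XYZ text (x y z in nm, z = 0)."""
    with open(path, "w") as fh:
        fh.write(f"{len(state.nodes)}\n{comment}\n")
        for x, y in state.nodes:
            fh.write(f"C {x:.6f} {y:.6f} 0.000000\n")
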