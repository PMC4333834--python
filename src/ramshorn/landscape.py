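"""Free-energy landscape F(Rx) and first-passage kinetics of the peeling tip.

F(Rx) = -kBT ln P(Rx) is the potential of mean force felt by the tip of an
unzippering protofilament.  The mean first-passage time between two tip
positions on the landscape,

    tau = (1/D) int_A^B exp[-F(x)] { int_x^B exp[F(u)] du } dx,

with reflecting boundary at A and absorbing at B, turns the landscape into
unzippering timescales; v_AB = 125 nm / tau_AB and v_AC = 250 nm / tau_AC
are the local peeling velocities toward the one-circle (B) and two-circle
(C) ram's-horn states.  The tip's diffusion coefficient comes from
Stokes-Einstein with the size of the curled blob.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .sampling import RxDistribution

__all__ = [
    "Landscape",
    "KineticsResult",
    "free_energy_from_distribution",
    "tilt",
    "diffusion_coefficient",
    "mean_first_passage_time",
    "unzippering_velocities",
    "find_minima",
    "KBT_PN_NM",
]

KB_J = 1.380649e-23
#: kBT at the 298 K reference temperature, in pN nm (converts pulling forces)
KBT_PN_NM = KB_J * 298.0 * 1e21


@dataclass
class Landscape:
    """Tabulated free energy over an Rx grid, with spline interpolation.

    F is defined up to an additive constant; every consumer in this module
    is invariant to that constant.  Evaluation outside [grid_min, grid_max]
    raises instead of extrapolating.
    """

    grid: np.ndarray
    F: np.ndarray
    tilt_force: float = 0.0     # pN, 0 if untilted
    _spline: CubicSpline = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.F.shape:
            raise ValueError("grid and F must be 1-D arrays of equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("F must be finite everywhere on the grid")
        self._spline = CubicSpline(self.grid, self.F)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.grid[0]), float(self.grid[-1])

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi = self.support
        if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
            raise ValueError(f"evaluation outside landscape support [{lo}, {hi}]")
        return self._spline(np.clip(x, lo, hi))

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(self.grid.tobytes())
        h.update(self.F.tobytes())
        return h.hexdigest()[:16]


def free_energy_from_distribution(dist: RxDistribution) -> Landscape:
    """F = -ln P on non-empty bins; interior empty bins filled by
    interpolation (with a warning); minimum shifted to zero."""
    p = dist.p
    if p.sum() == 0:
        raise ValueError("distribution is empty everywhere")
    centers = dist.centers
    occ = p > 0
    idx = np.flatnonzero(occ)
    first, last = idx[0], idx[-1]
    centers = centers[first:last + 1]
    p = p[first:last + 1]
    occ = p > 0
    with np.errstate(divide="ignore"):
        F = -np.log(p)
    if not occ.all():
        warnings.warn(
            f"{(~occ).sum()} empty interior bins filled by interpolation",
            stacklevel=2,
        )
        F[~occ] = np.interp(centers[~occ], centers[occ], F[occ])
    F -= F.min()
    return Landscape(centers, F)


def tilt(landscape: Landscape, f: float) -> Landscape:
    """Tilt by a pulling force: F(Rx, f) = F(Rx, 0) + f*Rx, f in pN.

    The conversion to kBT/nm uses the 298 K reference temperature
    (1 kBT/nm ~= 4.114 pN).  Exact pointwise identity on the grid.
    """
    slope = f / KBT_PN_NM
    return Landscape(landscape.grid, landscape.F + slope * landscape.grid,
                     tilt_force=landscape.tilt_force + f)


def diffusion_coefficient(a: float, eta: float = 1e-3, temperature: float = 298.0) -> float:
    """Stokes-Einstein D = kBT / (6 pi eta a) in nm^2/s.

    ``a`` is the effective radius of the peeling blob in nm (40 nm, the
    size of one curled circle, gives a conservative lower bound), ``eta``
    the solvent viscosity in Pa s.
    """
    if a <= 0 or eta <= 0:
        raise ValueError("a and eta must be positive")
    return KB_J * temperature / (6.0 * np.pi * eta * a * 1e-9) * 1e18


def mean_first_passage_time(
    landscape: Landscape,
    D: float,
    A: float,
    B: float,
    n_grid: int = 4001,
) -> float:
    """Mean first-passage time from A (reflecting) to B (absorbing), s.

    Evaluates the double integral on a dense uniform grid of the spline,
    in the Fubini-swapped order tau = (1/D) int_A^B e^{F(u)}
    [int_A^u e^{-F} dx] du, which needs one cumulative pass.  Invariant to
    an additive constant in F.
    """
    lo, hi = landscape.support
    if not (lo - 1e-9 <= A < B <= hi + 1e-9):
        raise ValueError(f"need support[0] <= A < B <= support[1]; got A={A}, B={B}")
    x = np.linspace(A, B, n_grid)
    F = landscape(x)
    F = F - F.mean()            # guard against exp overflow
    inner = cumulative_trapezoid(np.exp(-F), x, initial=0.0)
    tau = np.trapezoid(np.exp(F) * inner, x) / D
    return float(tau)


@dataclass(frozen=True)
class KineticsResult:
    """Unzippering timescales and velocities between the landmark states
    A (Rx=0), B (one circle, 125 nm) and C (two circles, 250 nm)."""

    tau_AB: float
    tau_AC: float
    v_AB: float
    v_AC: float
    D: float

    def to_dict(self) -> dict:
        return {
            "tau_AB_s": self.tau_AB, "tau_AC_s": self.tau_AC,
            "v_AB_nm_s": self.v_AB, "v_AC_nm_s": self.v_AC,
            "D_nm2_s": self.D,
        }


def unzippering_velocities(
    landscape: Landscape,
    D: float,
    A: float = 0.0,
    B: float = 125.0,
    C: float = 250.0,
) -> KineticsResult:
    """tau_AB, tau_AC by first passage from A, and v = distance / tau."""
    lo, hi = landscape.support
    if hi < C:
        raise ValueError(f"landscape support ends at {hi:.1f} nm < C = {C} nm")
    A = max(A, lo)
    tab = mean_first_passage_time(landscape, D, A, B)
    tac = mean_first_passage_time(landscape, D, A, C)
    return KineticsResult(tau_AB=tab, tau_AC=tac,
                          v_AB=(B - A) / tab, v_AC=(C - A) / tac, D=D)


def find_minima(
    landscape: Landscape,
    prominence: float = 1.0,
    smooth_sigma: float = 4.0,
) -> list[tuple[float, float]]:
    """Local minima of the (Gaussian-smoothed) landscape, sorted by Rx.

    ``prominence`` (kBT) is the required depth relative to the lower
    flanking barrier; ``smooth_sigma`` (nm) suppresses histogram noise
    before detection.  The end bins count as candidate minima so the
    tubular (Rx=0) and fully peeled states are reported when prominent.
    """
    if prominence <= 0:
        raise ValueError("prominence must be positive")
    lo, hi = landscape.support
    dx = 0.5
    x = np.arange(lo, hi + dx / 2, dx)
    F = landscape(x)
    if smooth_sigma > 0:
        F = gaussian_filter1d(F, smooth_sigma / dx, mode="nearest")
    # pad with high walls so boundary minima are detectable by find_peaks
    pad = F.max() - F.min() + 2 * prominence
    peaks, _ = find_peaks(np.concatenate([[-F[0] - pad], -F, [-F[-1] - pad]]),
                          prominence=prominence)
    out = [(float(x[p - 1]), float(landscape(x[p - 1]))) for p in peaks]
    return sorted(out)


def kinetics_report(
    landscape: Landscape,
    D: float,
    prominence: float = 1.0,
    A: float = 0.0,
    B: float = 125.0,
    C: float = 250.0,
) -> dict:
    """JSON-ready summary: D, timescales, velocities, minima, checksum."""
    kin = unzippering_velocities(landscape, D, A=A, B=B, C=C)
    return {
        **kin.to_dict(),
        "minima": [{"Rx_nm": x, "F_kBT": f} for x, f in find_minima(landscape, prominence)],
        "landscape_checksum": landscape.checksum(),
        "tilt_force_pN": landscape.tilt_force,
    }
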