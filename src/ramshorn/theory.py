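"""Closed-form references: zero-temperature geometry and the semi-analytic
multi-peak approximation of P(Rx).

A peeled segment of arc length Lc relaxes onto a circle of the intrinsic
radius rc = b/thetaD, putting the tip at

    Rx0(Lc) = Lc - rc * sin(Lc / rc),

a non-decreasing map whose flat spots at multiples of 2*pi*rc (whole
circles) concentrate probability and seed the minima of the sampled free
energy.  At zero temperature the chain has only two states: fully bound
(Rx = 0) when deltaE > 0 and fully peeled when deltaE < 0.  Approximating
the tip distribution of a free curved segment of Nc subunits as a Gaussian
around Rx0(Nc*b) with Boltzmann weight exp(-deltaE*Nc) reproduces the
multi-peak structure of P(Rx) semi-analytically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sampling import RxDistribution

__all__ = [
    "GeometryParams",
    "SemiAnalyticConfig",
    "ZeroTemperatureState",
    "rx_of_lc",
    "zero_temperature_state",
    "semi_analytic_P",
]


@dataclass(frozen=True)
class GeometryParams:
    """Intrinsic radius rc = b/thetaD and contour length L, both nm."""

    rc: float = 20.0
    L: float = 256.0

    def __post_init__(self) -> None:
        if self.rc <= 0 or self.L <= 0:
            raise ValueError("rc and L must be positive")


def rx_of_lc(Lc, geom: GeometryParams):
    """Zero-temperature tip position Rx0 = Lc - rc sin(Lc/rc) of a peeled
    arc of length Lc (scalar or array)."""
    Lc = np.asarray(Lc, dtype=float)
    if np.any(Lc < -1e-9) or np.any(Lc > geom.L + 1e-9):
        raise ValueError("need 0 <= Lc <= L")
    out = Lc - geom.rc * np.sin(Lc / geom.rc)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ZeroTemperatureState:
    """Tip position of the quenched chain; degenerate at deltaE = 0."""

    Rx: float | None
    degenerate: bool


def zero_temperature_state(deltaE: float, geom: GeometryParams) -> ZeroTemperatureState:
    """Two-state prediction without thermal fluctuations: fully bound for
    deltaE > 0, fully peeled for deltaE < 0, degenerate at exactly 0."""
    if deltaE == 0:
        return ZeroTemperatureState(Rx=None, degenerate=True)
    if deltaE > 0:
        return ZeroTemperatureState(Rx=0.0, degenerate=False)
    return ZeroTemperatureState(Rx=rx_of_lc(geom.L, geom), degenerate=False)


@dataclass(frozen=True)
class SemiAnalyticConfig:
    """Gaussian-mixture approximation settings.

    ``sigma0`` sets the thermal width of the peeled-segment tip
    distribution, sigma(Nc) = sigma0 * sqrt(Nc) nm (widths grow with
    peeled length; only peak positions are quantitative).
    """

    deltaE: float = 1.2
    sigma0: float = 2.0

    def sigma(self, Nc: int) -> float:
        if Nc < 1:
            raise ValueError("Nc must be >= 1")
        return self.sigma0 * np.sqrt(Nc)


def semi_analytic_P(
    cfg: SemiAnalyticConfig,
    geom: GeometryParams,
    N: int,
    b: float = 8.0,
    bin_width: float = 2.0,
) -> RxDistribution:
    """P(Rx) as a Boltzmann-weighted mixture of Gaussians, one per peeled
    subunit count: weight exp(-deltaE*Nc), center Rx0(Nc*b)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    from scipy.special import erf

    edges = np.arange(0.0, geom.L + bin_width, bin_width)
    p = np.zeros(len(edges) - 1)
    w0 = np.exp(-cfg.deltaE)   # per-subunit Boltzmann factor
    for nc in range(1, N + 1):
        mu = rx_of_lc(min(nc * b, geom.L), geom)
        s = cfg.sigma(nc)
        z = (edges - mu) / (np.sqrt(2.0) * s)
        p += w0**nc * 0.5 * (erf(z[1:]) - erf(z[:-1]))   # exact bin mass
    if p.sum() == 0:
        raise ValueError("mixture underflowed; deltaE too large")
    return RxDistribution(edges, p, n_samples=0)
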