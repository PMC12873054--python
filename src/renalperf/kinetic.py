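"""Forward tracer-kinetic models for DCE-MRI enhancement curves.

All models map an arterial input function (AIF) sampled on a uniform time
grid, together with a small set of physiological parameters, to a tissue
enhancement curve.  Modeling operates directly on absolute signal
enhancement S(t) - S0, assuming signal-concentration linearity; no
conversion to gadolinium concentration is performed.

Time is handled internally in minutes so that all rate constants
(``ktrans``, ``kep``, ``fp``, ``ps``) are in 1/min and all volume
fractions (``vp``, ``ve``) are dimensionless.  Reported units elsewhere in
the package are mL/100 mL/min for Ktrans-like rates and mL/100 mL for
volume fractions (a factor of 100).

Models
------
- Patlak: ``Ct(t) = Ktrans * int_0^t Cp(tau) dtau + vp * Cp(t)``; valid
  when backflux from the interstitium is negligible over the imaging
  window.
- Extended Tofts: adds a first-order efflux rate ``kep``;
  ``Ct = vp*Cp + Ktrans * (Cp (*) exp(-kep t))``.
- Two-compartment uptake (2CUM): plasma flow ``fp`` and
  permeability-surface product ``ps`` with no backflux; residue
  ``R(t) = fp * [(1-E) exp(-t/Tp) + E]``, ``E = ps/(ps+fp)``,
  ``Tp = vp/(fp+ps)``.
- Two-compartment exchange (2CXM): full bidirectional exchange with a
  biexponential residue; the degenerate equal-root case uses the
  confluent ``t*exp`` limit.

All quadrature (running integrals and convolutions) uses the trapezoidal
rule on the uniform acquisition grid, so that nested models agree exactly
in their shared limits (e.g. extended Tofts with ``kep = 0`` reproduces
Patlak to machine precision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "TimeGrid",
    "ArterialInputFunction",
    "TissueCurve",
    "PatlakParams",
    "ExtendedToftsParams",
    "UptakeParams",
    "ExchangeParams",
    "cumulative_integral",
    "patlak_forward",
    "extended_tofts_forward",
    "uptake_forward",
    "exchange_forward",
]

SECONDS_PER_MINUTE = 60.0

#: factor between internal units (1/min, dimensionless) and reported units
#: (mL/100 mL/min, mL/100 mL)
REPORTED_SCALE = 100.0


@dataclass(frozen=True)
class TimeGrid:
    """Uniform acquisition time grid.

    Parameters
    ----------
    n_frames : int
        Number of dynamic frames (>= 2).
    dt : float
        Temporal resolution in seconds per frame (> 0).
    t0 : float
        Acquisition time of the first frame in seconds (default 0).
    """

    n_frames: int
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")

    @property
    def times_s(self) -> np.ndarray:
        """Frame times in seconds."""
        return self.t0 + self.dt * np.arange(self.n_frames)

    @property
    def times_min(self) -> np.ndarray:
        """Frame times in minutes."""
        return self.times_s / SECONDS_PER_MINUTE

    @property
    def dt_min(self) -> float:
        return self.dt / SECONDS_PER_MINUTE


def _check_samples(grid: TimeGrid, values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.shape[0] != grid.n_frames:
        raise ValueError(
            f"{name} must be a 1-D array of length {grid.n_frames}, "
            f"got shape {values.shape}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name} contains non-finite values")
    return values


@dataclass(frozen=True)
class ArterialInputFunction:
    """Plasma enhancement curve sampled in a feeding artery (here: aorta)."""

    grid: TimeGrid
    cp: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "cp", _check_samples(self.grid, self.cp, "cp"))


@dataclass(frozen=True)
class TissueCurve:
    """Tissue enhancement curve S(t) - S0 for one voxel or ROI."""

    grid: TimeGrid
    ct: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ct", _check_samples(self.grid, self.ct, "ct"))


@dataclass(frozen=True)
class PatlakParams:
    """Patlak parameters, internal units: ktrans in 1/min, vp dimensionless."""

    ktrans: float
    vp: float

    def __post_init__(self) -> None:
        if self.ktrans < 0:
            raise ValueError(f"ktrans must be >= 0, got {self.ktrans}")
        if not 0 <= self.vp <= 1:
            raise ValueError(f"vp must be in [0, 1], got {self.vp}")


@dataclass(frozen=True)
class ExtendedToftsParams:
    ktrans: float
    kep: float
    vp: float

    def __post_init__(self) -> None:
        if self.ktrans < 0:
            raise ValueError(f"ktrans must be >= 0, got {self.ktrans}")
        if self.kep < 0:
            raise ValueError(f"kep must be >= 0, got {self.kep}")
        if not 0 <= self.vp <= 1:
            raise ValueError(f"vp must be in [0, 1], got {self.vp}")


@dataclass(frozen=True)
class UptakeParams:
    fp: float
    ps: float
    vp: float

    def __post_init__(self) -> None:
        if not self.fp > 0:
            raise ValueError(f"fp must be > 0, got {self.fp}")
        if self.ps < 0:
            raise ValueError(f"ps must be >= 0, got {self.ps}")
        if not 0 < self.vp <= 1:
            raise ValueError(f"vp must be in (0, 1], got {self.vp}")


@dataclass(frozen=True)
class ExchangeParams:
    fp: float
    ps: float
    vp: float
    ve: float

    def __post_init__(self) -> None:
        if not self.fp > 0:
            raise ValueError(f"fp must be > 0, got {self.fp}")
        if self.ps < 0:
            raise ValueError(f"ps must be >= 0, got {self.ps}")
        if not 0 < self.vp <= 1:
            raise ValueError(f"vp must be in (0, 1], got {self.vp}")
        if not 0 < self.ve <= 1:
            raise ValueError(f"ve must be in (0, 1], got {self.ve}")
        if self.vp + self.ve > 1 + 1e-12:
            raise ValueError(
                f"vp + ve must be <= 1, got {self.vp} + {self.ve}"
            )


def cumulative_integral(aif: ArterialInputFunction) -> np.ndarray:
    """Running trapezoidal integral of the AIF, in (signal unit) * min.

    The first element is 0 by definition.
    """
    return cumulative_trapezoid(aif.cp, dx=aif.grid.dt_min, initial=0.0)


def patlak_forward(p: PatlakParams, aif: ArterialInputFunction) -> TissueCurve:
    """Patlak model: Ct = ktrans * int Cp + vp * Cp."""
    ct = p.ktrans * cumulative_integral(aif) + p.vp * aif.cp
    return TissueCurve(aif.grid, ct)


def _trapz_convolve(f: np.ndarray, kernel: np.ndarray, dt_min: float) -> np.ndarray:
    """Trapezoidal discrete convolution (f (*) kernel)(t_n) on a uniform grid.

    Uses the same quadrature as :func:`cumulative_integral` so that
    kernel == 1 reproduces the running trapezoidal integral exactly.
    """
    n = f.shape[0]
    full = np.convolve(f, kernel)[:n]
    out = dt_min * (full - 0.5 * f[0] * kernel - 0.5 * kernel[0] * f)
    out[0] = 0.0
    return out


def extended_tofts_forward(
    p: ExtendedToftsParams, aif: ArterialInputFunction
) -> TissueCurve:
    """Extended Tofts model: Ct = vp*Cp + ktrans * (Cp (*) exp(-kep t))."""
    t_rel = aif.grid.times_min - aif.grid.times_min[0]
    kernel = np.exp(-p.kep * t_rel)
    leak = _trapz_convolve(aif.cp, kernel, aif.grid.dt_min)
    return TissueCurve(aif.grid, p.vp * aif.cp + p.ktrans * leak)


def uptake_forward(p: UptakeParams, aif: ArterialInputFunction) -> TissueCurve:
    """Two-compartment uptake model (no backflux from the interstitium)."""
    e = p.ps / (p.ps + p.fp)
    tp = p.vp / (p.fp + p.ps)
    t_rel = aif.grid.times_min - aif.grid.times_min[0]
    residue = p.fp * ((1.0 - e) * np.exp(-t_rel / tp) + e)
    ct = _trapz_convolve(aif.cp, residue, aif.grid.dt_min)
    return TissueCurve(aif.grid, ct)


def exchange_residue(p: ExchangeParams, t_min: np.ndarray) -> np.ndarray:
    """Impulse response of the two-compartment exchange model, R(0) = fp.

    Derived from the mass balance of a plasma compartment (vp) exchanging
    with an interstitial compartment (ve) at rate ps, fed at plasma flow
    fp.  R(t) = fp * [A exp(-alpha t) + B exp(-beta t)] where -alpha and
    -beta are the roots of

        s^2 + s*((fp+ps)/vp + ps/ve) + fp*ps/(vp*ve) = 0

    and A = (sigma - alpha)/(beta - alpha), B = (sigma - beta)/(alpha - beta)
    with sigma = ps/vp + ps/ve.  The total area under R equals vp + ve
    (total distribution volume).  Equal roots use the confluent
    (1 + (sigma - alpha) t) exp(-alpha t) limit.
    """
    s = (p.fp + p.ps) / p.vp + p.ps / p.ve
    q = p.fp * p.ps / (p.vp * p.ve)
    disc = s * s - 4.0 * q
    sqrt_disc = math.sqrt(max(disc, 0.0))
    alpha = 0.5 * (s + sqrt_disc)
    beta = 0.5 * (s - sqrt_disc)
    sigma = p.ps / p.vp + p.ps / p.ve
    if sqrt_disc <= 1e-12 * alpha:
        # confluent limit for (near-)equal roots
        return p.fp * (1.0 + (sigma - alpha) * t_min) * np.exp(-alpha * t_min)
    a_amp = (sigma - alpha) / (beta - alpha)
    b_amp = (sigma - beta) / (alpha - beta)
    return p.fp * (a_amp * np.exp(-alpha * t_min) + b_amp * np.exp(-beta * t_min))


def exchange_forward(p: ExchangeParams, aif: ArterialInputFunction) -> TissueCurve:
    """Two-compartment exchange model: Ct = R_2CXM (*) Cp."""
    t_rel = aif.grid.times_min - aif.grid.times_min[0]
    residue = exchange_residue(p, t_rel)
    ct = _trapz_convolve(aif.cp, residue, aif.grid.dt_min)
    return TissueCurve(aif.grid, ct)
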