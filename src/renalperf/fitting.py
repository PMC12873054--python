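"""Per-curve kinetic parameter estimation and AIC-based model selection.

The Patlak model is linear in its parameters and is fitted by ordinary
least squares on the two regressors [running AIF integral, AIF].  The
three alternative models (extended Tofts, two-compartment uptake,
two-compartment exchange) are fitted by bounded nonlinear least squares
with seeded Latin-hypercube multi-start.  Models are compared with the
Akaike information criterion

    AIC = n * ln(RSS / n) + 2 * (k + 1)

where the +1 counts the estimated noise variance as a free parameter.  A
small-sample corrected variant (AICc) is available but off by default so
a single canonical score governs selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .kinetic import (
    ArterialInputFunction,
    ExchangeParams,
    ExtendedToftsParams,
    PatlakParams,
    TissueCurve,
    UptakeParams,
    cumulative_integral,
    extended_tofts_forward,
    exchange_forward,
    patlak_forward,
    uptake_forward,
)

__all__ = [
    "KineticFit",
    "FitWindow",
    "SingularDesignError",
    "FitConvergenceError",
    "MODEL_N_PARAMS",
    "aic",
    "detect_bolus_arrival",
    "default_window",
    "fit_patlak",
    "fit_nonlinear",
    "select_model",
]

MODEL_N_PARAMS = {
    "patlak": 2,
    "extended_tofts": 3,
    "uptake": 3,
    "exchange": 4,
}

#: upper bound for all rate constants, 1/min (generous physiological range)
RATE_BOUND = 10.0


class SingularDesignError(ValueError):
    """Raised when the AIF carries no signal inside the fit window."""


class FitConvergenceError(RuntimeError):
    """Raised when no multi-start succeeds; carries the best attempt."""

    def __init__(self, message: str, best: "KineticFit | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class FitWindow:
    """Frame range used for fitting; both ends inclusive."""

    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_frame < self.end_frame:
            raise ValueError(
                f"need 0 <= start_frame < end_frame, got "
                f"[{self.start_frame}, {self.end_frame}]"
            )

    def slice(self) -> slice:
        return slice(self.start_frame, self.end_frame + 1)


@dataclass(frozen=True)
class KineticFit:
    """Result of fitting one kinetic model to one curve."""

    model_name: str
    params: object
    rss: float
    n_obs: int
    n_params: int
    aic: float
    flags: tuple[str, ...] = ()
    delta_aic: Mapping[str, float] | None = None


def aic(rss: float, n_obs: int, n_params: int, corrected: bool = False) -> float:
    """Akaike information criterion with the noise variance counted.

    ``rss == 0`` returns ``-inf`` as a sentinel (a perfect fit dominates
    every finite score); callers flag this condition.
    """
    if n_obs <= n_params + 1:
        raise ValueError(
            f"AIC needs n_obs > n_params + 1 (got n_obs={n_obs}, "
            f"n_params={n_params})"
        )
    if rss < 0:
        raise ValueError(f"rss must be >= 0, got {rss}")
    if rss == 0:
        return -math.inf
    k = n_params + 1
    score = n_obs * math.log(rss / n_obs) + 2 * k
    if corrected:
        if n_obs <= k + 1:
            raise ValueError("AICc needs n_obs > n_params + 2")
        score += 2 * k * (k + 1) / (n_obs - k - 1)
    return score


def detect_bolus_arrival(
    cp: np.ndarray, n_baseline: int = 3, z: float = 5.0
) -> int | None:
    """First frame where the curve exceeds baseline mean + z * baseline SD.

    Returns ``None`` when no frame exceeds the threshold (e.g. a flat or
    all-zero curve).
    """
    cp = np.asarray(cp, dtype=float)
    if not 1 <= n_baseline < cp.shape[0]:
        raise ValueError(f"n_baseline must be in [1, {cp.shape[0] - 1}]")
    base = cp[:n_baseline]
    thresh = base.mean() + z * base.std()
    eps = 1e-12 * max(1.0, float(np.abs(cp).max()))
    above = np.nonzero(cp > thresh + eps)[0]
    return int(above[0]) if above.size else None


def default_window(aif: ArterialInputFunction, n_baseline: int = 3) -> FitWindow:
    """Fit window from detected bolus arrival to the last frame."""
    arrival = detect_bolus_arrival(aif.cp, n_baseline=n_baseline)
    start = 0 if arrival is None else arrival
    return FitWindow(start, aif.grid.n_frames - 1)


def _window_arrays(curve, aif, window):
    if curve.grid != aif.grid:
        raise ValueError("curve and AIF must share the same time grid")
    if window is None:
        window = default_window(aif)
    if window.end_frame >= aif.grid.n_frames:
        raise ValueError("window extends past the last frame")
    sl = window.slice()
    return window, aif.cp[sl], cumulative_integral(aif)[sl], curve.ct[sl]


def fit_patlak(
    curve: TissueCurve,
    aif: ArterialInputFunction,
    window: FitWindow | None = None,
) -> KineticFit:
    """Linear Patlak fit by OLS of Ct on [running AIF integral, AIF].

    Negative estimates are clipped to zero (physical parameters are
    non-negative) and flagged; the reported RSS is that of the unclipped
    OLS solution.
    """
    window, cp, cum, y = _window_arrays(curve, aif, window)
    n_obs = y.shape[0]
    if n_obs < 3:
        raise ValueError(f"Patlak fit needs >= 3 frames, got {n_obs}")
    if not np.any(cp != 0):
        raise SingularDesignError("AIF is identically zero inside the fit window")
    design = np.column_stack([cum, cp])
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((y - design @ beta) ** 2))
    flags: list[str] = []
    ktrans, vp = float(beta[0]), float(beta[1])
    if ktrans < 0:
        ktrans = 0.0
        flags.append("ktrans_clipped")
    if vp < 0:
        vp = 0.0
        flags.append("vp_clipped")
    vp = min(vp, 1.0)
    score = aic(rss, n_obs, 2)
    if not math.isfinite(score):
        flags.append("perfect_fit")
    return KineticFit(
        model_name="patlak",
        params=PatlakParams(ktrans=ktrans, vp=vp),
        rss=rss,
        n_obs=n_obs,
        n_params=2,
        aic=score,
        flags=tuple(flags),
    )


# Internal optimizer parameterizations.  The exchange model is fitted in
# (fp, ps, vp, fe) with ve = fe * (1 - vp) so the simplex constraint
# vp + ve <= 1 becomes a box constraint.
_SPECS = {
    "extended_tofts": {
        "names": ("ktrans", "kep", "vp"),
        "lo": np.array([0.0, 0.0, 0.0]),
        "hi": np.array([RATE_BOUND, RATE_BOUND, 1.0]),
        "is_rate": np.array([True, True, False]),
    },
    "uptake": {
        "names": ("fp", "ps", "vp"),
        "lo": np.array([1e-6, 0.0, 1e-6]),
        "hi": np.array([RATE_BOUND, RATE_BOUND, 1.0]),
        "is_rate": np.array([True, True, False]),
    },
    "exchange": {
        "names": ("fp", "ps", "vp", "fe"),
        "lo": np.array([1e-6, 0.0, 1e-6, 1e-6]),
        "hi": np.array([RATE_BOUND, RATE_BOUND, 1.0, 1.0]),
        "is_rate": np.array([True, True, False, False]),
    },
}


def _make_params(model_name: str, x: np.ndarray):
    if model_name == "extended_tofts":
        return ExtendedToftsParams(ktrans=x[0], kep=x[1], vp=min(x[2], 1.0))
    if model_name == "uptake":
        return UptakeParams(fp=max(x[0], 1e-12), ps=max(x[1], 0.0), vp=min(max(x[2], 1e-12), 1.0))
    if model_name == "exchange":
        vp = min(max(x[2], 1e-12), 1.0)
        ve = max(x[3] * (1.0 - vp), 1e-12)
        return ExchangeParams(fp=max(x[0], 1e-12), ps=max(x[1], 0.0), vp=vp, ve=ve)
    raise ValueError(f"unknown model {model_name!r}")


_FORWARD = {
    "patlak": patlak_forward,
    "extended_tofts": extended_tofts_forward,
    "uptake": uptake_forward,
    "exchange": exchange_forward,
}


def _lhs_starts(spec, n_starts: int, seed: int) -> np.ndarray:
    """Latin-hypercube start points; rate axes are sampled log-uniformly."""
    dim = spec["lo"].shape[0]
    sampler = qmc.LatinHypercube(d=dim, seed=seed)
    u = sampler.random(n_starts)
    starts = np.empty_like(u)
    for j in range(dim):
        lo, hi = spec["lo"][j], spec["hi"][j]
        if spec["is_rate"][j]:
            lo_eff = max(lo, 1e-3)
            starts[:, j] = lo_eff * (hi / lo_eff) ** u[:, j]
        else:
            lo_eff = max(lo, 1e-3)
            starts[:, j] = lo_eff + u[:, j] * (hi - lo_eff)
    return starts


def fit_nonlinear(
    curve: TissueCurve,
    aif: ArterialInputFunction,
    model_name: str,
    window: FitWindow | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> KineticFit:
    """Bounded nonlinear least-squares fit with seeded multi-start.

    Start points come from a Latin-hypercube sample of the bound box
    (rates on a log scale).  Deterministic for a given seed and inputs.
    """
    if model_name not in _SPECS:
        raise ValueError(
            f"model_name must be one of {sorted(_SPECS)}, got {model_name!r}"
        )
    window, _, _, y = _window_arrays(curve, aif, window)
    sl = window.slice()
    n_obs = y.shape[0]
    spec = _SPECS[model_name]
    forward = _FORWARD[model_name]

    def residuals(x):
        params = _make_params(model_name, x)
        return forward(params, aif).ct[sl] - y

    best = None
    best_rss = math.inf
    any_success = False
    for x0 in _lhs_starts(spec, n_starts, seed):
        res = least_squares(
            residuals,
            x0,
            bounds=(spec["lo"], spec["hi"]),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=400,
        )
        rss = float(np.sum(res.fun**2))
        if rss < best_rss:
            best_rss = rss
            best = res
        any_success = any_success or res.success
    params = _make_params(model_name, best.x)
    n_params = MODEL_N_PARAMS[model_name]
    flags: list[str] = []
    score = aic(best_rss, n_obs, n_params)
    if not math.isfinite(score):
        flags.append("perfect_fit")
    fit = KineticFit(
        model_name=model_name,
        params=params,
        rss=best_rss,
        n_obs=n_obs,
        n_params=n_params,
        aic=score,
        flags=tuple(flags),
    )
    if not any_success:
        raise FitConvergenceError(
            f"no start converged for model {model_name!r}", best=fit
        )
    return fit


def select_model(
    curve: TissueCurve,
    aif: ArterialInputFunction,
    window: FitWindow | None = None,
    seed: int = 0,
    n_starts: int = 8,
) -> KineticFit:
    """Fit all four models and return the minimum-AIC fit.

    AIC ties are broken toward the model with fewest parameters.  The
    returned fit carries a ``delta_aic`` table (AIC of each other model
    minus the winner's AIC).  Per-model fit errors are tolerated as long
    as at least one model fits.
    """
    fits: dict[str, KineticFit] = {}
    errors: dict[str, Exception] = {}
    try:
        fits["patlak"] = fit_patlak(curve, aif, window)
    except Exception as exc:  # noqa: BLE001 - per-model isolation is the contract
        errors["patlak"] = exc
    for name in ("extended_tofts", "uptake", "exchange"):
        try:
            fits[name] = fit_nonlinear(
                curve, aif, name, window=window, n_starts=n_starts, seed=seed
            )
        except FitConvergenceError as exc:
            if exc.best is not None:
                fits[name] = exc.best
            else:
                errors[name] = exc
        except Exception as exc:  # noqa: BLE001
            errors[name] = exc
    if not fits:
        raise FitConvergenceError(f"all models failed: {errors}")
    best_name = min(fits, key=lambda k: (fits[k].aic, fits[k].n_params))
    best = fits[best_name]
    delta: dict[str, float] = {}
    for name, f in fits.items():
        if name == best_name:
            continue
        d = f.aic - best.aic
        delta[name] = 0.0 if math.isnan(d) else d
    return replace(best, delta_aic=delta)
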