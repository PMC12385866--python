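"""Sigmoid (tanh) length--probability model of axon specification.

The probability that a neurite of final length ``L`` (μm) has differentiated
into an axon is modeled as

    P(L) = 1/2 * [1 + tanh((L - Lc) / sigma)]

where ``Lc`` is the *critical length* (the length at which P = 50%) and
``sigma`` is the dispersion (width of the transition), both in μm.  From a
fitted curve two summary lengths are derived:

* the critical length ``Lc`` itself, and
* the *definitive length* ``Lt``, the length at which P reaches a
  near-certainty level ``p`` (default 0.9995), obtained in closed form as
  ``Lt = Lc + sigma * atanh(2 p - 1)``.

Fitting is unweighted nonlinear least squares of the sigmoid against binary
axon/non-axon outcomes (0/1), the convention used when the curve is fitted
with ``scipy.optimize.curve_fit``.  A Bernoulli maximum-likelihood objective
is available as an option but is never the default.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DEFAULT_P_DEFINITIVE",
    "FitError",
    "SigmoidFit",
    "RmseLandscape",
    "sigmoid_probability",
    "fit_sigmoid",
    "definitive_length",
    "rmse_landscape",
    "confidence_band",
]

#: Probability level defining the definitive length.  It is the unique round
#: level for which (Lc, sigma) = (43.3, 13.7) μm gives Lt = 95.4 μm after
#: 0.1 μm rounding.
DEFAULT_P_DEFINITIVE = 0.9995

#: Default grids for the RMSE landscape (μm).
DEFAULT_LC_GRID = (10.0, 120.0, 0.5)
DEFAULT_SIGMA_GRID = (1.0, 50.0, 0.5)


class FitError(RuntimeError):
    """Raised when the sigmoid cannot be fitted to the supplied data."""


def sigmoid_probability(L, Lc: float, sigma: float):
    """Axon-specification probability at length ``L``.

    Parameters
    ----------
    L : float or array-like
        Neurite length(s), μm.
    Lc : float
        Critical length (50% probability), μm.
    sigma : float
        Dispersion of the transition, μm; must be positive.

    Returns
    -------
    float or ndarray
        ``0.5 * (1 + tanh((L - Lc) / sigma))``, strictly increasing in L.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    L = np.asarray(L, dtype=float)
    out = 0.5 * (1.0 + np.tanh((L - Lc) / sigma))
    return float(out) if out.ndim == 0 else out


@dataclass
class SigmoidFit:
    """Result of fitting the tanh length-probability model.

    Lengths are in μm.  ``covariance`` is the 2x2 parameter covariance
    (order: Lc, sigma).  ``rmse`` is sqrt(mean squared residual) against the
    fitted observations; ``r_squared`` is computed on the raw binary
    observations and may legitimately be negative for a poor fit (flagged
    via :attr:`r_squared_warning`, reported as-is).
    """

    Lc: float
    sigma: float
    covariance: np.ndarray = field(
        default_factory=lambda: np.zeros((2, 2), dtype=float)
    )
    r_squared: float = float("nan")
    rmse: float = float("nan")
    n: int = 0
    converged: bool = True
    p_definitive: float = DEFAULT_P_DEFINITIVE

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(2, 2)
        if self.converged and not self.sigma > 0:
            raise ValueError("converged fit requires sigma > 0")

    @property
    def Lt(self) -> float:
        """Definitive length at ``p_definitive``, full precision (μm)."""
        return self.Lc + self.sigma * math.atanh(2.0 * self.p_definitive - 1.0)

    @property
    def r_squared_warning(self) -> bool:
        """True when R² is negative (fit worse than the mean predictor)."""
        return bool(np.isfinite(self.r_squared) and self.r_squared < 0)

    def predict(self, L):
        return sigmoid_probability(L, self.Lc, self.sigma)

    def summary(self) -> dict:
        """Flat summary with lengths rounded to 0.1 μm (reporting convention)."""
        return {
            "Lc_um": round(self.Lc, 1),
            "sigma_um": round(self.sigma, 1),
            "Lt_um": round(self.Lt, 1),
            "p_definitive": self.p_definitive,
            "r_squared": round(float(self.r_squared), 4),
            "r_squared_warning": self.r_squared_warning,
            "rmse": round(float(self.rmse), 6),
            "n": int(self.n),
            "converged": bool(self.converged),
            "covariance": self.covariance.tolist(),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def _tanh_model(L, Lc, sigma):
    return 0.5 * (1.0 + np.tanh((L - Lc) / sigma))


def _sandwich_covariance(
    L: np.ndarray, residuals: np.ndarray, Lc: float, sigma: float
) -> np.ndarray:
    """Heteroscedasticity-robust covariance of the least-squares estimate.

    Binary outcomes have Bernoulli variance p(1-p) that changes along the
    curve, so the homoscedastic covariance from a plain least-squares fit
    misstates the parameter uncertainty; the HC sandwich
    (J'J)^-1 J' diag(r_i^2) J (J'J)^-1 is consistent under that
    heteroscedasticity and tracks a parametric bootstrap.
    """
    z = np.clip((L - Lc) / sigma, -300.0, 300.0)
    sech2 = 1.0 / np.cosh(z) ** 2
    J = np.column_stack([-sech2 / (2.0 * sigma), -z * sech2 / (2.0 * sigma)])
    bread = np.linalg.pinv(J.T @ J)
    meat = J.T @ (J * residuals[:, None] ** 2)
    return bread @ meat @ bread


def _neg_log_likelihood(params, L, y):
    p = np.clip(_tanh_model(L, *params), 1e-12, 1.0 - 1e-12)
    return -np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p))


def fit_sigmoid(
    lengths,
    labels,
    init: tuple[float, float] | None = None,
    p_definitive: float = DEFAULT_P_DEFINITIVE,
    objective: str = "least_squares",
) -> SigmoidFit:
    """Fit the tanh sigmoid to (length, binary label) observations.

    Parameters
    ----------
    lengths, labels : array-like
        Neurite lengths (μm) and axon outcomes (1 = axon).  Fractional
        "labels" (e.g. per-bin rates) are accepted; the default objective is
        unweighted least squares either way.
    init : (Lc0, sigma0), optional
        Starting point.  Defaults to (median length, half the IQR); on
        failure a 5x5 coarse grid of restarts is tried before giving up.
    objective : {"least_squares", "likelihood"}
        Bernoulli maximum likelihood is available as an option; least
        squares is the default and the reporting convention.

    Raises
    ------
    FitError
        For fewer than 4 observations, single-class data, or
        non-convergence after the restart grid.
    """
    L = np.asarray(lengths, dtype=float)
    y = np.asarray(labels, dtype=float)
    if L.shape != y.shape or L.ndim != 1:
        raise ValueError("lengths and labels must be 1-D arrays of equal size")
    if L.size < 4:
        raise FitError(f"need at least 4 observations, got {L.size}")
    if np.ptp(y) == 0:
        raise FitError(
            "single-class data: all labels equal "
            f"{y[0]:g}; both outcomes are required to locate the transition"
        )
    if objective not in ("least_squares", "likelihood"):
        raise ValueError(f"unknown objective {objective!r}")

    q25, q50, q75 = np.quantile(L, [0.25, 0.5, 0.75])
    default_init = (q50, max((q75 - q25) / 2.0, 1.0))
    starts = [tuple(init)] if init is not None else [default_init]
    # coarse restart grid: length quantiles x a decade of dispersions
    grid_Lc = np.quantile(L, [0.1, 0.3, 0.5, 0.7, 0.9])
    grid_sigma = (2.0, 5.0, 10.0, 20.0, 40.0)
    starts += [(lc, s) for lc in grid_Lc for s in grid_sigma]

    best = None  # (sse, popt, pcov)
    for k, p0 in enumerate(starts):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    _tanh_model, L, y, p0=p0, maxfev=20000
                )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        Lc_hat, sigma_hat = float(popt[0]), float(popt[1])
        if not (np.isfinite(Lc_hat) and np.isfinite(sigma_hat) and sigma_hat > 0):
            continue
        sse = float(np.sum((_tanh_model(L, *popt) - y) ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, (Lc_hat, sigma_hat))
        if k == 0:
            break  # primary start succeeded; restarts are for failure only
    if best is None:
        raise FitError(
            "tanh fit failed to converge from the default start and a "
            f"{len(starts) - 1}-point restart grid (n={L.size})"
        )
    sse, (Lc_hat, sigma_hat) = best

    if objective == "likelihood":
        res = optimize.minimize(
            _neg_log_likelihood,
            x0=(Lc_hat, sigma_hat),
            args=(L, y),
            method="Nelder-Mead",
        )
        if res.success and res.x[1] > 0:
            Lc_hat, sigma_hat = float(res.x[0]), float(res.x[1])
            sse = float(np.sum((_tanh_model(L, Lc_hat, sigma_hat) - y) ** 2))

    residuals = _tanh_model(L, Lc_hat, sigma_hat) - y
    rmse = float(np.sqrt(np.mean(residuals**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else float("nan")
    return SigmoidFit(
        Lc=Lc_hat,
        sigma=sigma_hat,
        covariance=_sandwich_covariance(L, residuals, Lc_hat, sigma_hat),
        r_squared=r2,
        rmse=rmse,
        n=int(L.size),
        converged=True,
        p_definitive=p_definitive,
    )


def definitive_length(fit: SigmoidFit, p: float | None = None) -> float:
    """Definitive length ``Lt = Lc + sigma*atanh(2p - 1)``, rounded to 0.1 μm.

    ``p`` defaults to the fit's ``p_definitive`` (0.9995 unless overridden).
    """
    if not fit.converged:
        raise FitError("cannot derive Lt from an unconverged fit")
    if p is None:
        p = fit.p_definitive
    if not (0.5 <= p < 1.0):
        raise ValueError(f"p must lie in [0.5, 1), got {p}")
    return round(fit.Lc + fit.sigma * math.atanh(2.0 * p - 1.0), 1)


@dataclass
class RmseLandscape:
    """RMSE of the sigmoid over an (Lc, sigma) grid, with its argmin."""

    Lc_grid: np.ndarray
    sigma_grid: np.ndarray
    rmse: np.ndarray  # shape (len(Lc_grid), len(sigma_grid))
    argmin: tuple[float, float]

    @property
    def min_rmse(self) -> float:
        return float(self.rmse.min())

    def to_csv(self, path) -> None:
        """Matrix CSV: first row = sigma grid, first column = Lc grid."""
        df = pd.DataFrame(
            self.rmse,
            index=pd.Index(self.Lc_grid, name="Lc_um"),
            columns=pd.Index(self.sigma_grid, name="sigma_um"),
        )
        df.to_csv(path)


def _as_grid(spec) -> np.ndarray:
    if isinstance(spec, tuple) and len(spec) == 3:
        lo, hi, step = spec
        return np.arange(lo, hi + step / 2.0, step)
    return np.asarray(spec, dtype=float)


def rmse_landscape(
    lengths,
    labels,
    Lc_grid=DEFAULT_LC_GRID,
    sigma_grid=DEFAULT_SIGMA_GRID,
) -> RmseLandscape:
    """Exhaustive RMSE of the sigmoid over an (Lc, sigma) grid.

    Grids may be given as explicit arrays or (lo, hi, step) tuples.  The
    argmin is the grid point minimizing sqrt(mean((P(L) - y)^2)); for a
    fine grid it brackets the least-squares optimum.
    """
    L = np.asarray(lengths, dtype=float)
    y = np.asarray(labels, dtype=float)
    Lc_grid = _as_grid(Lc_grid)
    sigma_grid = _as_grid(sigma_grid)
    if Lc_grid.size == 0 or sigma_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(sigma_grid <= 0):
        raise ValueError("sigma grid must be strictly positive")

    rmse = np.empty((Lc_grid.size, sigma_grid.size), dtype=float)
    # loop over Lc rows to bound memory at len(sigma_grid) * n floats
    for i, lc in enumerate(Lc_grid):
        P = 0.5 * (1.0 + np.tanh((L[None, :] - lc) / sigma_grid[:, None]))
        rmse[i] = np.sqrt(np.mean((P - y[None, :]) ** 2, axis=1))
    i, j = np.unravel_index(np.argmin(rmse), rmse.shape)
    return RmseLandscape(
        Lc_grid=Lc_grid,
        sigma_grid=sigma_grid,
        rmse=rmse,
        argmin=(float(Lc_grid[i]), float(sigma_grid[j])),
    )


def confidence_band(
    fit: SigmoidFit, L_values, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise delta-method confidence band for the fitted curve.

    The parameter covariance is propagated through the sigmoid to first
    order; the band is symmetric about the central curve before clipping
    to [0, 1].  A zero covariance collapses the band onto the curve.
    """
    if not fit.converged:
        raise FitError("confidence band requires a converged fit")
    cov = fit.covariance
    if not np.all(np.isfinite(cov)):
        raise ValueError("covariance contains non-finite entries")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must lie in (0, 1), got {level}")
    L = np.asarray(L_values, dtype=float)
    z = np.clip((L - fit.Lc) / fit.sigma, -300.0, 300.0)
    sech2 = 1.0 / np.cosh(z) ** 2
    # gradient of P wrt (Lc, sigma)
    g = np.vstack(
        [-sech2 / (2.0 * fit.sigma), -(L - fit.Lc) * sech2 / (2.0 * fit.sigma**2)]
    )
    var = np.einsum("im,ij,jm->m", g, cov, g)
    var = np.clip(var, 0.0, None)
    half_width = stats.norm.ppf(0.5 + level / 2.0) * np.sqrt(var)
    center = fit.predict(L)
    lower = np.clip(center - half_width, 0.0, 1.0)
    upper = np.clip(center + half_width, 0.0, 1.0)
    return lower, upper
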