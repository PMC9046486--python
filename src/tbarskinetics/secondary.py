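"""Secondary models: temperature dependence of the first-order rate constant.

Two temperature laws are supported:

* Arrhenius: ``k(T) = k0 * exp(-Ea / (R T))``, fitted as the straight line
  ``ln k = ln k0 - Ea/(R T)`` (ln k vs 1/T).
* Log-logistic (softplus): ``k(T) = m' * ln(1 + exp(c (T - Tc)))``, fitted by
  nonlinear least squares (Levenberg-Marquardt) with multistart
  initialization.  Temperatures are kelvin throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .dataio import DataError
from .primary import InsufficientDataError

__all__ = [
    "GAS_CONSTANT",
    "ArrheniusFit",
    "LogLogisticFit",
    "ArrheniusModel",
    "LogLogisticModel",
    "FitFailureError",
    "arrhenius_rate",
    "fit_arrhenius",
    "log_logistic_rate",
    "fit_log_logistic",
]

#: Universal gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314


class FitFailureError(RuntimeError):
    """Nonlinear fit failed from every starting point."""

    def __init__(self, message: str, best_params=None):
        super().__init__(message)
        self.best_params = best_params


@dataclass(frozen=True)
class ArrheniusFit:
    """Arrhenius parameters for one sample group.

    ``ea`` is the activation energy (J/mol) — the temperature sensitivity of
    the oxidation rate; ``k0`` (day^-1) is the pre-exponential factor.
    """

    sample_label: str
    ea: float
    k0: float
    r2: float
    n_temperatures: int


@dataclass(frozen=True)
class LogLogisticFit:
    """Log-logistic (softplus) parameters for one sample group.

    ``c`` (K^-1) controls the steepness, ``tc`` (K) locates the bend;
    ``m_prime`` is usually pinned at 1.
    """

    sample_label: str
    c: float
    tc: float
    m_prime: float
    r2: float
    n_temperatures: int
    sse: float


def _softplus(x):
    return np.logaddexp(0.0, x)


def arrhenius_rate(fit: ArrheniusFit, temperature) -> float | np.ndarray:
    """Rate constant k(T) = k0 exp(-Ea/(R T)) at a kelvin temperature."""
    T = np.asarray(temperature, dtype=float)
    k = fit.k0 * np.exp(-fit.ea / (GAS_CONSTANT * T))
    return float(k) if np.isscalar(temperature) else k


def log_logistic_rate(fit: LogLogisticFit, temperature) -> float | np.ndarray:
    """Rate constant k(T) = m' ln(1 + exp(c (T - Tc))) (numerically stable)."""
    T = np.asarray(temperature, dtype=float)
    k = fit.m_prime * _softplus(fit.c * (T - fit.tc))
    return float(k) if np.isscalar(temperature) else k


class ArrheniusModel(RegressorMixin, BaseEstimator):
    """Arrhenius temperature model fitted by OLS of ln k on 1/T.

    Attributes
    ----------
    ea_ : float
        Activation energy, J/mol (``-slope * R``).
    k0_ : float
        Pre-exponential factor, day^-1 (``exp(intercept)``).
    r2_ : float
        R-squared of the straight-line fit of ln k vs 1/T.
    """

    def fit(self, X, y):
        """Fit to kelvin temperatures ``X`` and rate constants ``y`` (day^-1)."""
        T = np.asarray(X, dtype=float).reshape(-1)
        k = np.asarray(y, dtype=float).reshape(-1)
        if T.size != k.size:
            raise DataError("temperatures and rates differ in length")
        if np.unique(T).size < 2:
            raise InsufficientDataError("Arrhenius fit needs >= 2 distinct temperatures")
        if np.any(k <= 0):
            raise DataError("rate constants must be strictly positive")
        x = 1.0 / T
        lnk = np.log(k)
        slope, intercept = np.polyfit(x, lnk, 1)
        resid = lnk - (slope * x + intercept)
        sst = float(np.sum((lnk - lnk.mean()) ** 2))
        self.ea_ = float(-slope * GAS_CONSTANT)
        self.k0_ = float(np.exp(intercept))
        self.r2_ = 1.0 if sst == 0 else float(1.0 - np.sum(resid**2) / sst)
        self.n_temperatures_ = int(np.unique(T).size)
        return self

    def predict(self, X):
        check_is_fitted(self, "ea_")
        T = np.asarray(X, dtype=float).reshape(-1)
        return self.k0_ * np.exp(-self.ea_ / (GAS_CONSTANT * T))


class LogLogisticModel(RegressorMixin, BaseEstimator):
    """Softplus temperature model fitted by multistart Levenberg-Marquardt.

    Parameters
    ----------
    m_prime_free : bool, default=False
        Free the multiplier m'; by default it is pinned at 1.
    c_starts, tc_offsets : starting grids for the multistart search.  Tc
        starts are placed at T_min + offset for negative offsets, the data
        midpoint, and T_max + offset for positive ones.
    """

    _C_STARTS = (0.02, 0.05, 0.1, 0.2, 0.5)

    def __init__(self, m_prime_free: bool = False):
        self.m_prime_free = m_prime_free

    def fit(self, X, y):
        """Fit to kelvin temperatures ``X`` and rate constants ``y`` (day^-1)."""
        T = np.asarray(X, dtype=float).reshape(-1)
        k = np.asarray(y, dtype=float).reshape(-1)
        if T.size != k.size:
            raise DataError("temperatures and rates differ in length")
        n_free = 3 if self.m_prime_free else 2
        if np.unique(T).size < n_free + 1:
            raise InsufficientDataError(
                f"log-logistic fit with {n_free} free parameters needs "
                f">= {n_free + 1} distinct temperatures"
            )
        if np.any(k < 0):
            raise DataError("rate constants must be non-negative")

        tc_starts = (T.min() - 10.0, float(np.median(T)), T.max() + 15.0)

        def residuals(params):
            if self.m_prime_free:
                c, tc, m = params
            else:
                (c, tc), m = params, 1.0
            return k - m * _softplus(c * (T - tc))

        best = None
        for c0 in self._C_STARTS:
            for tc0 in tc_starts:
                x0 = [c0, tc0, 1.0] if self.m_prime_free else [c0, tc0]
                try:
                    res = least_squares(
                        residuals, x0, method="lm", xtol=1e-12, ftol=1e-10, gtol=1e-12
                    )
                except Exception:
                    continue
                sse = float(np.sum(res.fun**2))
                if np.isfinite(sse) and (best is None or sse < best[0]):
                    best = (sse, res)
        if best is None:
            raise FitFailureError("log-logistic fit failed from every start")
        sse, res = best
        if self.m_prime_free:
            c, tc, m = res.x
        else:
            (c, tc), m = res.x, 1.0
        sst = float(np.sum((k - k.mean()) ** 2))
        self.c_ = float(c)
        self.tc_ = float(tc)
        self.m_prime_ = float(m)
        self.sse_ = sse
        self.r2_ = 1.0 if sst == 0 else float(1.0 - sse / sst)
        self.n_temperatures_ = int(np.unique(T).size)
        return self

    def predict(self, X):
        check_is_fitted(self, "c_")
        T = np.asarray(X, dtype=float).reshape(-1)
        return self.m_prime_ * _softplus(self.c_ * (T - self.tc_))


def _unpack_rates(rates: Mapping[float, float]):
    T = np.array(sorted(rates), dtype=float)
    k = np.array([rates[t] for t in sorted(rates)], dtype=float)
    return T, k


def fit_arrhenius(rates: Mapping[float, float], sample_label: str) -> ArrheniusFit:
    """Fit the Arrhenius law to a kelvin -> rate-constant map."""
    T, k = _unpack_rates(rates)
    est = ArrheniusModel().fit(T, k)
    return ArrheniusFit(
        sample_label=sample_label,
        ea=est.ea_,
        k0=est.k0_,
        r2=est.r2_,
        n_temperatures=est.n_temperatures_,
    )


def fit_log_logistic(
    rates: Mapping[float, float], sample_label: str, m_prime_free: bool = False
) -> LogLogisticFit:
    """Fit the log-logistic (softplus) law to a kelvin -> rate-constant map."""
    T, k = _unpack_rates(rates)
    est = LogLogisticModel(m_prime_free=m_prime_free).fit(T, k)
    return LogLogisticFit(
        sample_label=sample_label,
        c=est.c_,
        tc=est.tc_,
        m_prime=est.m_prime_,
        r2=est.r2_,
        n_temperatures=est.n_temperatures_,
        sse=est.sse_,
    )
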