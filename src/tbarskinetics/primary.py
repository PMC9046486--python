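"""Primary kinetics: percent normalization and first-order rate estimation.

TBARS grows (approximately) exponentially during storage at constant
temperature, TBARS(t) = TBARS0 * exp(k t) with TBARS0 = 100 % of the initial
value.  The rate constant k (day^-1) is estimated per replicate series by
ordinary least squares of ln(percent) on time — either with a free intercept
(default) or forced through (0, ln 100).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .dataio import DataError, TBARSSeries

__all__ = [
    "RateEstimate",
    "RateSummary",
    "FirstOrderKinetics",
    "normalize_percent",
    "fit_first_order",
    "summarize_replicates",
]


class InsufficientDataError(DataError):
    """Fewer observations than the fit requires."""


@dataclass(frozen=True)
class RateEstimate:
    """First-order rate constant for one replicate series, with diagnostics."""

    sample_label: str
    temperature: float
    replicate_id: int
    k: float
    ln_intercept: float
    r2: float
    rmse_ln: float
    n_points: int


@dataclass(frozen=True)
class RateSummary:
    """Replicate mean +/- SD of k for one (sample, temperature) cell."""

    sample_label: str
    temperature: float
    k_mean: float
    k_sd: float
    n_replicates: int
    single_replicate: bool = False


def normalize_percent(series: TBARSSeries) -> TBARSSeries:
    """Express TBARS as percent of the day-0 value (percent[0] == 100 exactly)."""
    if series.raw_values is None:
        raise DataError("normalize_percent requires raw_values")
    raw = np.asarray(series.raw_values, dtype=float)
    if np.any(raw <= 0):
        raise DataError("raw TBARS values must be strictly positive")
    percent = 100.0 * raw / raw[0]
    percent[0] = 100.0
    return dataclasses.replace(series, percent_values=percent)


class FirstOrderKinetics(RegressorMixin, BaseEstimator):
    """Log-linear least-squares estimator of the first-order rate constant.

    Parameters
    ----------
    fix_intercept : bool, default=False
        If True, the regression of ln(percent) on time is forced through
        (0, ln 100), i.e. the model intercept is pinned at the initial 100 %.
        With a free intercept, k is the OLS slope.

    Attributes
    ----------
    k_ : float
        Estimated rate constant (day^-1).
    ln_intercept_ : float
        Fitted intercept on the ln scale (ln 100 when fixed).
    r2_ : float
        Squared Pearson correlation between ln(percent) and time.
    rmse_ln_ : float
        Root-mean-square residual on the ln scale.
    """

    def __init__(self, fix_intercept: bool = False):
        self.fix_intercept = fix_intercept

    def fit(self, X, y):
        """Fit to times ``X`` (days, shape (n,) or (n,1)) and percent values ``y``."""
        t = np.asarray(X, dtype=float).reshape(-1)
        p = np.asarray(y, dtype=float).reshape(-1)
        if t.size != p.size:
            raise DataError("times and percent values differ in length")
        if t.size < 3:
            raise InsufficientDataError("first-order fit needs >= 3 time points")
        if np.any(p <= 0):
            raise DataError("percent values must be strictly positive")
        ln_p = np.log(p)
        ln100 = np.log(100.0)
        if self.fix_intercept:
            # slope of the regression through (0, ln 100)
            slope = float(np.sum(t * (ln_p - ln100)) / np.sum(t * t))
            intercept = ln100
        else:
            # centered closed form: exactly zero slope for a constant series
            tc = t - t.mean()
            yc = ln_p - ln_p.mean()
            slope = float(tc @ yc) / float(tc @ tc)
            intercept = float(ln_p.mean() - slope * t.mean())
        resid = ln_p - (slope * t + intercept)
        sst = float(np.sum((ln_p - ln_p.mean()) ** 2))
        sse = float(np.sum(resid**2))
        if sst > 0:
            self.r2_ = float(np.corrcoef(t, ln_p)[0, 1] ** 2)
        else:
            self.r2_ = 1.0 if sse == 0.0 else 0.0
        self.k_ = float(slope)
        self.ln_intercept_ = float(intercept)
        self.rmse_ln_ = float(np.sqrt(sse / t.size))
        self.n_points_ = int(t.size)
        return self

    def predict(self, X):
        """Predicted percent values at times ``X``."""
        check_is_fitted(self, "k_")
        t = np.asarray(X, dtype=float).reshape(-1)
        return np.exp(self.ln_intercept_ + self.k_ * t)


def fit_first_order(series: TBARSSeries, fix_intercept: bool = False) -> RateEstimate:
    """Estimate k for one normalized series (see `FirstOrderKinetics`)."""
    if series.percent_values is None:
        raise DataError("series must be normalized to percent before fitting")
    est = FirstOrderKinetics(fix_intercept=fix_intercept).fit(
        series.times, series.percent_values
    )
    return RateEstimate(
        sample_label=series.sample_label,
        temperature=series.temperature,
        replicate_id=series.replicate_id,
        k=est.k_,
        ln_intercept=est.ln_intercept_,
        r2=est.r2_,
        rmse_ln=est.rmse_ln_,
        n_points=est.n_points_,
    )


def summarize_replicates(estimates: Sequence[RateEstimate]) -> RateSummary:
    """Mean and sample SD (ddof=1) of k over replicate estimates of one cell."""
    if len(estimates) == 0:
        raise DataError("no rate estimates to summarize")
    labels = {e.sample_label for e in estimates}
    temps = {e.temperature for e in estimates}
    if len(labels) > 1 or len(temps) > 1:
        raise DataError(
            f"replicates mix groups: labels={sorted(labels)}, temperatures={sorted(temps)}"
        )
    ks = np.array([e.k for e in estimates], dtype=float)
    single = ks.size == 1
    return RateSummary(
        sample_label=estimates[0].sample_label,
        temperature=estimates[0].temperature,
        k_mean=float(ks.mean()),
        k_sd=0.0 if single else float(ks.std(ddof=1)),
        n_replicates=int(ks.size),
        single_replicate=single,
    )
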