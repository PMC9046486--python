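"""Integrated time-temperature predictive models and external validation.

A predictive model composes the first-order primary law with a secondary
temperature law, giving TBARS(T, t) = 100 * exp(k(T) * t) where k(T) comes
from the Arrhenius or the log-logistic fit.  Validation mirrors the study
design: fit at four storage temperatures, hold out a fifth (12 degC) and
score predictions against the held-out observations with R^2 (1 - SSE/SST)
and RMSE on the percent scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .dataio import DataError, TBARSSeries
from .secondary import (
    ArrheniusFit,
    LogLogisticFit,
    arrhenius_rate,
    log_logistic_rate,
)

__all__ = [
    "PredictiveModel",
    "FitMetrics",
    "ValidationReport",
    "TbarsPredictor",
    "build_model",
    "predict_tbars",
    "goodness_of_fit",
    "validate_external",
]

TBARS0 = 100.0


@dataclass(frozen=True)
class FitMetrics:
    """Goodness-of-fit summary on the TBARS percent scale."""

    r2: float
    r2_adjusted: float
    rmse: float
    n: int
    p_params: int
    r2_pearson: float = float("nan")


@dataclass(frozen=True)
class PredictiveModel:
    """Integrated (T, t) -> TBARS% model for one sample group."""

    sample_label: str
    variant: Literal["arrhenius", "log_logistic"]
    arrhenius: ArrheniusFit | None = None
    loglog: LogLogisticFit | None = None
    tbars0: float = TBARS0

    def __post_init__(self) -> None:
        if self.variant == "arrhenius":
            if self.arrhenius is None or self.loglog is not None:
                raise TypeError("arrhenius variant requires exactly an ArrheniusFit")
        elif self.variant == "log_logistic":
            if self.loglog is None or self.arrhenius is not None:
                raise TypeError("log_logistic variant requires exactly a LogLogisticFit")
        else:
            raise TypeError(f"unknown variant {self.variant!r}")
        if self.tbars0 != TBARS0:
            raise ValueError("initial TBARS is pinned at 100 %")

    def rate(self, temperature):
        if self.variant == "arrhenius":
            return arrhenius_rate(self.arrhenius, temperature)
        return log_logistic_rate(self.loglog, temperature)


@dataclass(frozen=True)
class ValidationReport:
    """External-validation metrics, per held-out temperature and pooled."""

    sample_label: str
    variant: str
    per_temperature: dict[float, FitMetrics]
    pooled: FitMetrics
    sum_r2: float


def build_model(sample_label: str, variant: str, secondary_fit) -> PredictiveModel:
    """Assemble a predictive model from a secondary fit of the matching kind."""
    if variant == "arrhenius":
        if not isinstance(secondary_fit, ArrheniusFit):
            raise TypeError("arrhenius variant needs an ArrheniusFit")
        return PredictiveModel(sample_label, "arrhenius", arrhenius=secondary_fit)
    if variant == "log_logistic":
        if not isinstance(secondary_fit, LogLogisticFit):
            raise TypeError("log_logistic variant needs a LogLogisticFit")
        return PredictiveModel(sample_label, "log_logistic", loglog=secondary_fit)
    raise TypeError(f"unknown variant {variant!r}")


def predict_tbars(model: PredictiveModel, temperature, time) -> float | np.ndarray:
    """TBARS% = 100 exp(k(T) t) at a kelvin temperature and time in days."""
    t = np.asarray(time, dtype=float)
    if np.any(t < 0):
        raise DataError("storage time must be non-negative")
    out = TBARS0 * np.exp(np.asarray(model.rate(temperature)) * t)
    return float(out) if np.isscalar(time) and np.isscalar(temperature) else out


class TbarsPredictor(RegressorMixin, BaseEstimator):
    """scikit-learn wrapper: fit a secondary law per group, predict TBARS%.

    ``fit`` consumes kelvin temperatures and rate constants for one sample
    group; ``predict`` takes rows ``[temperature_K, time_days]`` and returns
    TBARS as percent of initial.
    """

    def __init__(self, variant: str = "arrhenius", sample_label: str = "Control"):
        self.variant = variant
        self.sample_label = sample_label

    def fit(self, X, y):
        from .secondary import fit_arrhenius, fit_log_logistic

        T = np.asarray(X, dtype=float).reshape(-1)
        rates = dict(zip(T, np.asarray(y, dtype=float).reshape(-1)))
        if self.variant == "arrhenius":
            sec = fit_arrhenius(rates, self.sample_label)
        elif self.variant == "log_logistic":
            sec = fit_log_logistic(rates, self.sample_label)
        else:
            raise TypeError(f"unknown variant {self.variant!r}")
        self.model_ = build_model(self.sample_label, self.variant, sec)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise DataError("predict expects rows [temperature_K, time_days]")
        return np.array(
            [predict_tbars(self.model_, T, t) for T, t in X], dtype=float
        )


def goodness_of_fit(
    observed: Sequence[float], predicted: Sequence[float], p_params: int
) -> FitMetrics:
    """R^2 = 1 - SSE/SST, adjusted R^2, and RMSE on the percent scale."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise DataError("observed and predicted must be equal-length, n >= 2")
    n = obs.size
    if n <= p_params + 1:
        raise DataError("adjusted R^2 needs n > p_params + 1")
    sse = float(np.sum((obs - pred) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise DataError("R^2 undefined: observed values have zero variance")
    r2 = 1.0 - sse / sst
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p_params - 1)
    if np.ptp(pred) > 0:
        r2_pearson = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    else:
        r2_pearson = 0.0
    return FitMetrics(
        r2=r2,
        r2_adjusted=r2_adj,
        rmse=float(np.sqrt(sse / n)),
        n=n,
        p_params=p_params,
        r2_pearson=r2_pearson,
    )


def validate_external(
    model: PredictiveModel, heldout: Sequence[TBARSSeries]
) -> ValidationReport:
    """Score the model against held-out series (e.g. the 12 degC condition)."""
    if len(heldout) == 0:
        raise DataError("no held-out series supplied")
    for s in heldout:
        if s.sample_label != model.sample_label:
            raise DataError(
                f"held-out series {s.key()} does not belong to group "
                f"{model.sample_label!r}"
            )
        if s.percent_values is None:
            raise DataError(f"held-out series {s.key()} is not normalized")
    p = 2  # (Ea, k0) or (c, Tc)
    by_temp: dict[float, list[tuple[np.ndarray, np.ndarray]]] = {}
    for s in heldout:
        pred = predict_tbars(model, s.temperature, s.times)
        by_temp.setdefault(float(s.temperature), []).append(
            (np.asarray(s.percent_values), np.asarray(pred))
        )
    per_temperature = {}
    all_obs, all_pred = [], []
    for T, pairs in sorted(by_temp.items()):
        obs = np.concatenate([o for o, _ in pairs])
        pred = np.concatenate([q for _, q in pairs])
        per_temperature[T] = goodness_of_fit(obs, pred, p)
        all_obs.append(obs)
        all_pred.append(pred)
    pooled = goodness_of_fit(np.concatenate(all_obs), np.concatenate(all_pred), p)
    sum_r2 = float(sum(m.r2 for m in per_temperature.values()))
    return ValidationReport(
        sample_label=model.sample_label,
        variant=model.variant,
        per_temperature=per_temperature,
        pooled=pooled,
        sum_r2=sum_r2,
    )
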