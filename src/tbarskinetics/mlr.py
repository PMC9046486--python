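"""Dummy-variable multiple linear regression for antioxidant-efficacy ranking.

ln(TBARS%) is regressed on storage time (days), storage temperature (degC)
and k-1 treatment indicator columns against the control reference group.
A more negative indicator coefficient means the extract slows oxidation more
strongly relative to control; two-sided t-tests flag which coefficients
differ significantly from zero.

The OLS solve is closed-form (QR through ``numpy.linalg.lstsq``; standard
errors from the inverse normal-equations matrix), so the arithmetic is fully
transparent and can be cross-checked against a general-purpose package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .dataio import CELSIUS_OFFSET, DataError, TBARSSeries

__all__ = [
    "DesignMatrix",
    "MLRResult",
    "CollinearityError",
    "DummyVariableMLR",
    "build_design_matrix",
    "fit_mlr",
    "rank_extracts",
]


class CollinearityError(np.linalg.LinAlgError):
    """The design matrix is rank deficient."""

    def __init__(self, message: str, columns: Sequence[str] = ()):  # noqa: D107
        super().__init__(message)
        self.columns = list(columns)


@dataclass
class DesignMatrix:
    """Response vector and named predictor columns for the dummy regression."""

    response: np.ndarray  # ln(percent)
    columns: pd.DataFrame  # intercept, time, temperature, dummies
    reference_label: str

    @property
    def dummy_names(self) -> list[str]:
        return [c for c in self.columns.columns if c not in ("intercept", "time", "temperature")]


@dataclass(frozen=True)
class MLRResult:
    """OLS coefficients with standard errors, t statistics and p values."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    t_stats: dict[str, float]
    p_values: dict[str, float]
    residual_se: float
    r2: float
    n: int
    dummy_names: tuple[str, ...] = ()


def build_design_matrix(
    dataset: Sequence[TBARSSeries], reference_label: str = "Control"
) -> DesignMatrix:
    """One row per (series, time point); k-1 alphabetical dummy columns.

    The reference group gets no indicator column; temperature enters in degC.
    """
    labels = sorted({s.sample_label for s in dataset})
    if reference_label not in labels:
        raise DataError(f"reference label {reference_label!r} not present in dataset")
    dummies = [lab for lab in labels if lab != reference_label]
    rows = []
    y = []
    for s in dataset:
        if s.percent_values is None:
            raise DataError(f"series {s.key()} is not normalized to percent")
        if np.any(np.asarray(s.percent_values) <= 0):
            raise DataError(f"series {s.key()} has non-positive percent values")
        for t, p in zip(s.times, s.percent_values):
            row = {"intercept": 1.0, "time": float(t),
                   "temperature": float(s.temperature) - CELSIUS_OFFSET}
            for lab in dummies:
                row[lab] = 1.0 if s.sample_label == lab else 0.0
            rows.append(row)
            y.append(np.log(p))
    cols = pd.DataFrame(rows, columns=["intercept", "time", "temperature", *dummies])
    return DesignMatrix(
        response=np.asarray(y, dtype=float), columns=cols, reference_label=reference_label
    )


def _find_collinear(X: pd.DataFrame) -> list[str]:
    # name columns whose removal restores full rank
    full_rank = np.linalg.matrix_rank(X.to_numpy())
    offenders = []
    for col in X.columns:
        rest = X.drop(columns=[col]).to_numpy()
        if np.linalg.matrix_rank(rest) == full_rank:
            offenders.append(col)
    return offenders


class DummyVariableMLR(RegressorMixin, BaseEstimator):
    """Closed-form OLS of ln(TBARS%) with treatment indicator columns.

    ``fit`` accepts a `DesignMatrix` (X) and ignores ``y``, or a plain
    predictor matrix X with a response y.  Fitted attributes mirror a
    regression summary table: ``coefficients_``, ``standard_errors_``,
    ``t_stats_``, ``p_values_``, ``residual_se_``, ``r2_``.
    """

    def fit(self, X, y=None):
        if isinstance(X, DesignMatrix):
            design, response = X.columns, X.response
            self.dummy_names_ = tuple(X.dummy_names)
        else:
            design = pd.DataFrame(np.asarray(X, dtype=float))
            design.columns = [f"x{i}" for i in range(design.shape[1])]
            response = np.asarray(y, dtype=float)
            self.dummy_names_ = ()
        n, p = design.shape
        if n <= p:
            raise DataError(f"need more rows ({n}) than predictors ({p})")
        M = design.to_numpy()
        if np.linalg.matrix_rank(M) < p:
            offenders = _find_collinear(design)
            raise CollinearityError(
                f"design matrix is rank deficient (columns: {offenders})", offenders
            )
        beta, _, _, _ = np.linalg.lstsq(M, response, rcond=None)
        resid = response - M @ beta
        dof = n - p
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(M.T @ M)
        se = np.sqrt(np.diag(cov))
        tvals = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
        sst = float(np.sum((response - response.mean()) ** 2))
        names = list(design.columns)
        self.coefficients_ = dict(zip(names, beta.astype(float)))
        self.standard_errors_ = dict(zip(names, se.astype(float)))
        self.t_stats_ = dict(zip(names, tvals.astype(float)))
        self.p_values_ = dict(zip(names, pvals.astype(float)))
        self.residual_se_ = float(np.sqrt(sigma2))
        self.r2_ = 1.0 if sst == 0 else float(1.0 - (resid @ resid) / sst)
        self.n_ = int(n)
        return self

    def predict(self, X):
        design = X.columns if isinstance(X, DesignMatrix) else pd.DataFrame(np.asarray(X))
        beta = np.array(list(self.coefficients_.values()))
        return design.to_numpy() @ beta

    def result(self) -> MLRResult:
        return MLRResult(
            coefficients=self.coefficients_,
            standard_errors=self.standard_errors_,
            t_stats=self.t_stats_,
            p_values=self.p_values_,
            residual_se=self.residual_se_,
            r2=self.r2_,
            n=self.n_,
            dummy_names=self.dummy_names_,
        )


def fit_mlr(design: DesignMatrix) -> MLRResult:
    """OLS fit of the dummy-variable regression (see `DummyVariableMLR`)."""
    return DummyVariableMLR().fit(design).result()


def rank_extracts(
    result: MLRResult, alpha: float = 0.05
) -> list[tuple[str, float, bool]]:
    """Order extracts by inhibitory strength (most negative coefficient first).

    Returns (label, coefficient, significant-at-alpha) triples for the
    indicator columns; significance is the two-sided t-test p <= alpha.
    """
    names = result.dummy_names or tuple(
        n for n in result.coefficients if n not in ("intercept", "time", "temperature")
    )
    if not names:
        raise DataError("result contains no treatment indicator coefficients")
    ranked = sorted(names, key=lambda n: result.coefficients[n])
    return [
        (n, result.coefficients[n], bool(result.p_values[n] <= alpha)) for n in ranked
    ]
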