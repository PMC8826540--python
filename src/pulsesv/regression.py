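"""Multilinear-regression baseline for stroke volume.

OLS of SV on subject covariates, with single-pass t-statistic pruning of
non-significant variables and the two cross-validation schemes used to score
the baseline: a single seeded 100/44-style train/test split ("1cv") and a
seeded 10-fold partition ("10cv").

Height enters the design in metres (the physiologically scaled coefficient
convention); gender as an indicator (M=1, F=0).  The printed-equation form
has no intercept, so the intercept is off by default and available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .agreement import AgreementStats, agreement
from .errors import ValidationError

__all__ = ["DEFAULT_VARIABLES", "SVRegression", "SVRegressionResults",
           "fit_ols", "prune_nonsignificant", "cross_validate", "CVResult"]

DEFAULT_VARIABLES = ["age", "gender", "weight_kg", "height_m",
                     "brSBP_mmHg", "brDBP_mmHg", "HR_bpm", "cfPWV_mps"]


def _design(data: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """Build the numeric design matrix from a cohort-style table."""
    X = pd.DataFrame(index=data.index)
    for v in variables:
        if v == "height_m" and v not in data.columns:
            if "height_cm" not in data.columns:
                raise ValidationError("missing variable height_m (or height_cm)")
            X[v] = data["height_cm"].astype(float) / 100.0
        elif v == "gender":
            if v not in data.columns:
                raise ValidationError("missing variable gender")
            col = data[v]
            X[v] = (col.astype(str) == "M").astype(float) if col.dtype == object \
                else col.astype(float)
        else:
            if v not in data.columns:
                raise ValidationError(f"missing variable {v!r}")
            X[v] = data[v].astype(float)
    return X


class SVRegression:
    """OLS model of a response on subject covariates (statsmodels-backed)."""

    def __init__(self, data: pd.DataFrame, response: str = "SV_ref_mL",
                 variables: Optional[Sequence[str]] = None,
                 intercept: bool = False):
        self.variables = list(variables if variables is not None
                              else DEFAULT_VARIABLES)
        self.response = response
        self.intercept = intercept
        if response not in data.columns:
            raise ValidationError(f"missing response column {response!r}")
        self.y = data[response].astype(float)
        self.X = _design(data, self.variables)
        if self.y.isna().any() or self.X.isna().any().any():
            raise ValidationError("missing values in response or design")
        n, k = self.X.shape
        if n <= k + 1:
            raise ValidationError(f"need n > {k + 1} rows, got {n}")
        self._check_rank()

    def _check_rank(self) -> None:
        X = self.X.to_numpy()
        if self.intercept:
            X = np.column_stack([np.ones(len(X)), X])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            bad = []
            for j, name in enumerate(self.variables):
                Xr = np.delete(self.X.to_numpy(), j, axis=1)
                if self.intercept:
                    Xr = np.column_stack([np.ones(len(Xr)), Xr])
                if np.linalg.matrix_rank(Xr) == rank:
                    bad.append(name)
            raise ValidationError(f"rank-deficient design; collinear columns: {bad}")

    def fit(self, prune_alpha: Optional[float] = None) -> "SVRegressionResults":
        X = sm.add_constant(self.X) if self.intercept else self.X
        res = sm.OLS(self.y, X).fit()
        out = SVRegressionResults(model=self, sm_results=res)
        if prune_alpha is not None:
            out = prune_nonsignificant(out, self._data_frame(), alpha=prune_alpha)
        return out

    def _data_frame(self) -> pd.DataFrame:
        df = self.X.copy()
        df[self.response] = self.y
        return df


@dataclass
class SVRegressionResults:
    """Fitted coefficients with their t-statistics and p-values."""

    model: Optional[SVRegression] = None
    sm_results: Optional[object] = None
    _coeffs: Optional[pd.Series] = None          # for printed-equation models
    full_model: Optional["SVRegressionResults"] = None   # pre-pruning fit
    dropped: list[str] = field(default_factory=list)

    @classmethod
    def from_coefficients(cls, coefficients: dict[str, float],
                          intercept: float = 0.0) -> "SVRegressionResults":
        """A fixed linear model (e.g. published coefficients), for prediction."""
        s = pd.Series(coefficients, dtype=float)
        if intercept:
            s = pd.concat([pd.Series({"const": intercept}), s])
        return cls(_coeffs=s)

    # -- accessors ---------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return self._coeffs if self.sm_results is None else self.sm_results.params

    @property
    def tvalues(self) -> pd.Series:
        return self.sm_results.tvalues

    @property
    def pvalues(self) -> pd.Series:
        return self.sm_results.pvalues

    @property
    def fit_n(self) -> int:
        return int(self.sm_results.nobs)

    @property
    def retained(self) -> list[str]:
        return [v for v in self.params.index if v != "const"]

    def predict(self, subject) -> np.ndarray | float:
        """Linear combination in the declared units (height in metres)."""
        scalar = isinstance(subject, (dict, pd.Series))
        df = pd.DataFrame([subject]) if scalar else pd.DataFrame(subject)
        X = _design(df, self.retained)
        yhat = X.to_numpy() @ self.params.reindex(self.retained).to_numpy()
        if "const" in self.params.index:
            yhat = yhat + self.params["const"]
        return float(yhat[0]) if scalar else yhat

    def summary(self):
        if self.sm_results is None:
            return "fixed-coefficient model:\n" + self.params.to_string()
        return self.sm_results.summary()


def fit_ols(data: pd.DataFrame, response: str = "SV_ref_mL",
            variables: Optional[Sequence[str]] = None,
            intercept: bool = False) -> SVRegressionResults:
    """Fit the OLS baseline; two-sided p-values from the coefficient t-tests."""
    return SVRegression(data, response, variables, intercept).fit()


def prune_nonsignificant(results: SVRegressionResults, data: pd.DataFrame,
                         alpha: float = 0.05) -> SVRegressionResults:
    """Single-pass pruning: drop every variable with p >= alpha, refit once."""
    if results.sm_results is None:
        raise ValidationError("cannot prune a fixed-coefficient model")
    model = results.model
    keep = [v for v in model.variables if results.pvalues[v] < alpha]
    dropped = [v for v in model.variables if v not in keep]
    if not keep:
        raise ValidationError("pruning dropped every variable")
    if not dropped:
        return results
    refit = SVRegression(data, model.response, keep, model.intercept).fit()
    refit.full_model = results
    refit.dropped = dropped
    return refit


@dataclass
class CVResult:
    """Cross-validation output: per-fold and pooled agreement metrics."""

    scheme: str
    seed: int
    fold_sizes: list[int]
    per_fold: list[AgreementStats]
    pooled: AgreementStats
    mean_metrics: dict[str, float]
    predictions: pd.Series


def cross_validate(data: pd.DataFrame, scheme: str, seed: int,
                   response: str = "SV_ref_mL",
                   variables: Optional[Sequence[str]] = None,
                   intercept: bool = False,
                   prune_alpha: Optional[float] = None) -> CVResult:
    """Score the regression baseline by one of the two CV schemes.

    ``"1cv"``: seeded shuffle, fit on the first 100/144-fraction of rows,
    evaluate on the rest.  ``"10cv"``: seeded partition into 10 folds whose
    sizes differ by at most one; every row is predicted exactly once by a
    model fitted on the other nine folds.
    """
    scheme = scheme.lower()
    if scheme not in ("1cv", "10cv"):
        raise ValidationError(f"unknown scheme {scheme!r} (use '1cv' or '10cv')")
    n = len(data)
    if n < 20:
        raise ValidationError(f"need at least 20 rows, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)

    if scheme == "1cv":
        n_train = 100 if n == 144 else int(round(n * 100.0 / 144.0))
        fold_tests = [perm[n_train:]]
        fold_trains = [perm[:n_train]]
    else:
        folds = np.array_split(perm, 10)
        fold_tests = folds
        fold_trains = [np.concatenate([f for j, f in enumerate(folds) if j != i])
                       for i in range(10)]

    preds = pd.Series(np.nan, index=data.index)
    per_fold = []
    est_all, ref_all = [], []
    for train_idx, test_idx in zip(fold_trains, fold_tests):
        train = data.iloc[train_idx]
        test = data.iloc[test_idx]
        res = SVRegression(train, response, variables, intercept).fit(
            prune_alpha=prune_alpha)
        yhat = res.predict(test)
        preds.iloc[test_idx] = yhat
        per_fold.append(agreement(yhat, test[response].to_numpy()))
        est_all.append(yhat)
        ref_all.append(test[response].to_numpy())

    pooled = agreement(np.concatenate(est_all), np.concatenate(ref_all))
    mean_metrics = {k: float(np.mean([getattr(f, k) for f in per_fold]))
                    for k in ("r", "mae", "rmse", "nrmse", "bias")}
    return CVResult(scheme=scheme, seed=seed,
                    fold_sizes=[len(t) for t in fold_tests],
                    per_fold=per_fold, pooled=pooled,
                    mean_metrics=mean_metrics, predictions=preds)
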