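"""Standardized linear models per scale with AIC scale-of-effect selection.

For each diversity response, one Gaussian linear model is fit per landscape
radius: all landscape predictors measured at that radius, plus scale-free
covariates (heterogeneity components, local habitat, detectability terms).
Explanatory variables are standardized (mean 0, sd 1, sample sd) before
fitting so coefficients are directly comparable effect sizes; responses that
are right-skewed counts use a zero-safe negative-inverse transform
``y -> -1/(y + 1)`` (monotone increasing; the strict ``-1/y`` variant is
available for strictly positive responses).  The radius whose model attains
the lowest AIC is the scale of effect; AICs are only compared across models
fit to the same location set, which listwise deletion across all scales
guarantees.  Wald 95% confidence intervals use ``beta ± 1.96 se``;
collinearity is reported through variance inflation factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr
from sklearn.base import BaseEstimator

__all__ = [
    "DegeneratePredictorError",
    "CollinearityError",
    "ComparabilityError",
    "ModelSpec",
    "FitResult",
    "standardize",
    "transform_response",
    "fit_glm",
    "select_scale",
    "select_locations",
    "ScaleSelectingLinearModel",
]

LANDSCAPE_PREDICTORS = ("FA", "FPD", "FCI", "URB", "URBHI", "AG")


class DegeneratePredictorError(ValueError):
    """A continuous predictor has zero variance."""


class CollinearityError(ValueError):
    """The design matrix is rank deficient."""

    def __init__(self, aliased: list[str]):
        self.aliased = aliased
        super().__init__(f"rank-deficient design; aliased columns: {aliased}")


class ComparabilityError(ValueError):
    """AIC compared across models fit to different location sets."""


@dataclass
class ModelSpec:
    """One response × scale model: predictors, covariates, transform."""

    response: str
    scale: float
    landscape_predictors: tuple[str, ...] = ("FA", "FPD", "FCI", "URB", "AG")
    covariates_continuous: tuple[str, ...] = ()
    covariates_categorical: tuple[str, ...] = ()
    transform: str = "identity"  # "identity" | "negative-inverse"


@dataclass
class FitResult:
    """Standardized effects, AIC, and collinearity diagnostics for one scale."""

    scale: float
    effects: pd.DataFrame  # predictor, beta, se, lo, hi
    aic: float
    n: int
    vif: dict[str, float] = field(default_factory=dict)
    location_ids: tuple = ()

    def effect(self, predictor: str) -> pd.Series:
        return self.effects.set_index("predictor").loc[predictor]


def standardize(X: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Center and scale continuous columns to mean 0, sd 1 (sample sd).

    Non-listed columns pass through untouched; a zero-variance column raises
    :class:`DegeneratePredictorError` naming it.
    """
    out = X.copy()
    cols = list(columns) if columns is not None else [
        c for c in X.columns if pd.api.types.is_numeric_dtype(X[c])
    ]
    for c in cols:
        v = out[c].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd <= 1e-10 * max(1.0, abs(v.mean())):
            raise DegeneratePredictorError(f"zero-variance predictor: {c!r}")
        out[c] = (v - v.mean()) / sd
    return out


def transform_response(y, kind: str = "identity", strict: bool = False) -> np.ndarray:
    """Identity or (zero-safe) negative-inverse response transform."""
    y = np.asarray(y, dtype=float)
    if kind == "identity":
        return y
    if kind == "negative-inverse":
        if (y < 0).any():
            raise ValueError("negative-inverse transform requires y >= 0")
        if strict:
            if (y == 0).any():
                raise ValueError("strict negative inverse requires y > 0")
            return -1.0 / y
        return -1.0 / (y + 1.0)
    raise ValueError(f"unknown response transform {kind!r}")


def _dummies(s: pd.Series) -> pd.DataFrame:
    """Fixed-effect dummies with the most frequent level as reference."""
    ref = s.value_counts().idxmax()
    levels = [l for l in s.value_counts().index if l != ref]
    return pd.DataFrame(
        {f"{s.name}[{l}]": (s == l).astype(float) for l in levels}, index=s.index
    )


def _build_design(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    cont = list(spec.landscape_predictors) + list(spec.covariates_continuous)
    design = standardize(data.loc[:, cont], cont)
    for c in spec.covariates_categorical:
        design = pd.concat([design, _dummies(data[c])], axis=1)
    return design


def _check_rank(design: pd.DataFrame) -> None:
    A = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])
    r = np.linalg.matrix_rank(A)
    if r < A.shape[1]:
        _, _, piv = qr(A, mode="economic", pivoting=True)
        aliased_idx = sorted(piv[r:])
        names = ["(intercept)"] + list(design.columns)
        raise CollinearityError([names[i] for i in aliased_idx])


def _vifs(design: pd.DataFrame, continuous: list[str]) -> dict[str, float]:
    out = {}
    X = design.to_numpy(dtype=float)
    cols = list(design.columns)
    for name in continuous:
        j = cols.index(name)
        others = np.delete(X, j, axis=1)
        aux = sm.OLS(X[:, j], sm.add_constant(others)).fit()
        r2 = min(aux.rsquared, 1 - 1e-12)
        out[name] = float(1.0 / (1.0 - r2))
    return out


def fit_glm(spec: ModelSpec, data: pd.DataFrame, ci_z: float = 1.96,
            strict_inverse: bool = False) -> FitResult:
    """Fit one standardized Gaussian linear model (OLS, identity link).

    ``data`` holds the response column plus all predictors and covariates,
    one row per location, with no missing values (listwise-delete first).
    """
    if len(data) < 8:
        raise ValueError(f"too few observations (n={len(data)}) to fit a model")
    if data.isna().any().any():
        raise ValueError("data contain missing values; listwise-delete first")
    design = _build_design(spec, data)
    n, p = design.shape
    if n <= p + 1 + 5:
        raise ValueError(f"too few observations (n={n}) for {p + 1} parameters")
    _check_rank(design)
    y = transform_response(data[spec.response], spec.transform, strict_inverse)
    res = sm.OLS(y, sm.add_constant(design.to_numpy(dtype=float))).fit()
    beta = res.params[1:]
    se = res.bse[1:]
    effects = pd.DataFrame(
        {
            "predictor": list(design.columns),
            "beta": beta,
            "se": se,
            "lo": beta - ci_z * se,
            "hi": beta + ci_z * se,
        }
    )
    continuous = list(spec.landscape_predictors) + list(spec.covariates_continuous)
    loc_ids = (
        tuple(data["location_id"]) if "location_id" in data.columns else tuple(data.index)
    )
    return FitResult(
        scale=spec.scale,
        effects=effects,
        aic=float(res.aic),
        n=n,
        vif=_vifs(design, continuous),
        location_ids=loc_ids,
    )


def select_scale(results: list[FitResult]) -> FitResult:
    """The fit with the lowest AIC; exact ties go to the smaller radius.

    All fits must share one location set, otherwise AICs are not comparable.
    """
    if len(results) < 2:
        raise ValueError("need fits at two or more scales")
    ref = set(results[0].location_ids)
    for r in results[1:]:
        if set(r.location_ids) != ref:
            raise ComparabilityError(
                "models were fit on different location sets; AIC not comparable"
            )
    return min(results, key=lambda r: (r.aic, r.scale))


def select_locations(
    locations: pd.DataFrame,
    fa_smallest: pd.Series,
    bounds: tuple[float, float, float, float],
    max_radius: float,
    min_forest: float = 0.5,
) -> pd.DataFrame:
    """Retain forest-dominated, interior locations.

    Keeps locations with forest amount at the smallest radius ≥ ``min_forest``
    (inclusive) whose distance to every raster edge exceeds ``max_radius``.
    ``fa_smallest`` is indexed by location_id.
    """
    xmin, ymin, xmax, ymax = bounds
    fa = locations["location_id"].map(fa_smallest)
    interior = (
        (locations["x"] - xmin > max_radius)
        & (xmax - locations["x"] > max_radius)
        & (locations["y"] - ymin > max_radius)
        & (ymax - locations["y"] > max_radius)
    )
    return locations.loc[(fa >= min_forest) & interior].reset_index(drop=True)


class ScaleSelectingLinearModel(BaseEstimator):
    """Fit one standardized linear model per radius and select by AIC.

    Parameters
    ----------
    landscape_predictors : columns read from the per-scale metric table;
        a predictor absent (or all-missing) at a scale — URBHI at large
        radii, typically — is dropped from that scale's model.
    covariates_per_scale : continuous covariates measured per scale (the
        heterogeneity components H1/H2), read from the per-scale table.
    covariates_continuous, covariates_categorical : scale-free covariate
        columns of the location table.
    response_transform : "identity" or "negative-inverse" (zero-safe).
    ci_z : Wald interval half-width multiplier.

    Attributes (after ``fit``)
    --------------------------
    results_ : dict radius -> :class:`FitResult`.
    best_scale_, best_result_ : the AIC-selected scale and its fit.
    aic_table_ : frame of (radius, aic, n) with the best flagged.
    n_used_ : common location count after listwise deletion.
    """

    def __init__(
        self,
        landscape_predictors=("FA", "FPD", "FCI", "URB", "URBHI", "AG"),
        covariates_per_scale=(),
        covariates_continuous=(),
        covariates_categorical=(),
        response_transform: str = "identity",
        strict_inverse: bool = False,
        ci_z: float = 1.96,
    ):
        self.landscape_predictors = tuple(landscape_predictors)
        self.covariates_per_scale = tuple(covariates_per_scale)
        self.covariates_continuous = tuple(covariates_continuous)
        self.covariates_categorical = tuple(covariates_categorical)
        self.response_transform = response_transform
        self.strict_inverse = strict_inverse
        self.ci_z = ci_z

    def fit(self, X: pd.DataFrame, y: pd.Series, covariates: pd.DataFrame | None = None):
        """Fit across scales.

        ``X`` is the tidy per-location × radius table (location_id, radius,
        predictor columns); ``y`` a response Series indexed by location_id;
        ``covariates`` an optional per-location frame (location_id index or
        column) with the covariate columns.
        """
        radii = sorted(float(r) for r in X["radius"].unique())
        if covariates is not None and "location_id" in covariates.columns:
            covariates = covariates.set_index("location_id")

        # assemble the wide frame per scale and find the common complete set
        per_scale: dict[float, pd.DataFrame] = {}
        preds_at: dict[float, list[str]] = {}
        scale_covs_at: dict[float, list[str]] = {}
        for r in radii:
            sub = X[X["radius"] == r].set_index("location_id")
            preds = [
                p for p in self.landscape_predictors
                if p in sub.columns and sub[p].notna().any()
            ]
            scale_covs = [
                p for p in self.covariates_per_scale
                if p in sub.columns and sub[p].notna().any()
            ]
            frame = sub.loc[:, preds + scale_covs].copy()
            if covariates is not None:
                cov_cols = list(self.covariates_continuous) + list(
                    self.covariates_categorical
                )
                frame = frame.join(covariates.loc[:, cov_cols])
            per_scale[r] = frame
            preds_at[r] = preds
            scale_covs_at[r] = scale_covs

        y = pd.Series(y)
        complete = y.dropna().index
        for r in radii:
            complete = complete.intersection(per_scale[r].dropna().index)
        complete = complete.sort_values()
        self.n_used_ = len(complete)
        if self.n_used_ == 0:
            raise ValueError(
                f"no complete cases across scales for response "
                f"{self._response_name(y)!r}"
            )

        results: dict[float, FitResult] = {}
        for r in radii:
            data = per_scale[r].loc[complete].copy()
            data[self._response_name(y)] = y.loc[complete].to_numpy(dtype=float)
            data["location_id"] = complete
            spec = ModelSpec(
                response=self._response_name(y),
                scale=r,
                landscape_predictors=tuple(preds_at[r]),
                covariates_continuous=tuple(scale_covs_at[r])
                + self.covariates_continuous,
                covariates_categorical=self.covariates_categorical,
                transform=self.response_transform,
            )
            results[r] = fit_glm(spec, data, self.ci_z, self.strict_inverse)
        self.results_ = results
        self.best_result_ = select_scale(list(results.values()))
        self.best_scale_ = self.best_result_.scale
        self.aic_table_ = pd.DataFrame(
            {
                "radius": radii,
                "aic": [results[r].aic for r in radii],
                "n": [results[r].n for r in radii],
                "best": [r == self.best_scale_ for r in radii],
            }
        )
        self.effects_ = self.best_result_.effects
        return self

    @staticmethod
    def _response_name(y: pd.Series) -> str:
        return str(y.name) if y.name is not None else "response"
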