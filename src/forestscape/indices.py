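"""Composite urbanization and landscape-heterogeneity indices via PCA.

Both indices are principal components of standardized inputs (i.e. PCA on
the correlation matrix), fit per spatial scale:

* **Urbanization** — six inputs: the four developed-class proportions plus
  area-weighted population and housing density.  Components are retained by
  the Kaiser–Guttman criterion (eigenvalue > 1).  The first retained
  component ("URB") is oriented so it correlates positively with total
  developed proportion; a second retained component ("URBHI", present only
  when its eigenvalue exceeds 1) is oriented positively with the
  high-intensity developed proportion.
* **Landscape heterogeneity** — four inputs: elevation mean and range,
  Shannon cover diversity, and forest–developed edge density.  The first two
  components ("H1", "H2") are always returned, since downstream models name
  both.

PCA sign is arbitrary; anchoring each component's sign to a named input
makes scores comparable across scales and runs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DegenerateVariableError",
    "StandardizedPCA",
    "UrbanizationIndex",
    "HeterogeneityIndex",
    "urbanization_index",
    "heterogeneity_index",
]

URBANIZATION_FEATURES = (
    "dev_open", "dev_low", "dev_med", "dev_high", "pop_density", "housing_density",
)
HETEROGENEITY_FEATURES = ("elev_mean", "elev_range", "SHDI", "ED")


class DegenerateVariableError(ValueError):
    """An input variable has zero variance and cannot be standardized."""


class StandardizedPCA(BaseEstimator, TransformerMixin):
    """PCA on standardized variables with sign anchoring.

    Parameters
    ----------
    features : sequence of str
        Input columns, in fixed order.
    anchors : dict[int, str]
        Component index -> feature whose correlation with the component score
        must be nonnegative (sign convention).  A zero correlation leaves the
        sign unchanged.
    min_samples : int
        Minimum rows required to fit.

    Attributes
    ----------
    eigenvalues_ : eigenvalues of the correlation matrix, descending.
    loadings_ : (n_features, n_components) signed eigenvectors.
    variance_fractions_ : eigenvalues / n_features.
    retained_ : boolean flags, eigenvalue > 1 (Kaiser–Guttman).
    """

    def __init__(self, features, anchors=None, min_samples: int = 10):
        self.features = tuple(features)
        self.anchors = dict(anchors or {})
        self.min_samples = min_samples

    def fit(self, X: pd.DataFrame, y=None):
        Z, mean, scale = self._standardize(X, fit=True)
        self.mean_ = mean
        self.scale_ = scale
        pca = PCA(n_components=len(self.features))
        scores = pca.fit_transform(Z)
        # explained_variance_ uses the (n-1) denominator, so on standardized
        # inputs it equals the correlation-matrix eigenvalues
        self.eigenvalues_ = pca.explained_variance_.copy()
        loadings = pca.components_.T.copy()
        for comp, anchor in self.anchors.items():
            if comp >= loadings.shape[1]:
                continue
            anchor_vals = self._anchor_values(X, Z)
            r = np.corrcoef(scores[:, comp], anchor_vals[anchor])[0, 1]
            if np.isfinite(r) and r < 0:
                loadings[:, comp] *= -1
        self.loadings_ = loadings
        self.variance_fractions_ = self.eigenvalues_ / len(self.features)
        self.retained_ = self.eigenvalues_ > 1.0
        self.n_features_in_ = len(self.features)
        return self

    def _anchor_values(self, X: pd.DataFrame, Z: np.ndarray) -> dict[str, np.ndarray]:
        vals = {f: Z[:, i] for i, f in enumerate(self.features)}
        vals["_total_developed"] = sum(
            X[c].to_numpy(dtype=float)
            for c in ("dev_open", "dev_low", "dev_med", "dev_high")
            if c in X.columns
        ) if any(c.startswith("dev_") for c in X.columns) else np.zeros(len(X))
        return vals

    def _standardize(self, X: pd.DataFrame, fit: bool):
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise KeyError(f"missing input columns: {missing}")
        A = X.loc[:, list(self.features)].to_numpy(dtype=float)
        if np.isnan(A).any():
            raise ValueError("inputs contain missing values; drop them before PCA")
        if fit:
            if len(A) < self.min_samples:
                raise ValueError(
                    f"need at least {self.min_samples} observations, got {len(A)}"
                )
            mean = A.mean(axis=0)
            scale = A.std(axis=0, ddof=1)
            # a constant column's sd is ~1e-17, not exactly 0
            zero = np.flatnonzero(scale <= 1e-10 * np.maximum(1.0, np.abs(mean)))
            if zero.size:
                names = [self.features[i] for i in zero]
                raise DegenerateVariableError(
                    f"zero-variance input variable(s): {names}"
                )
        else:
            mean, scale = self.mean_, self.scale_
        return (A - mean) / scale, mean, scale

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        Z, _, _ = self._standardize(X, fit=False)
        return Z @ self.loadings_


class UrbanizationIndex(StandardizedPCA):
    """Urbanization (URB) and optional high-intensity urbanization (URBHI).

    ``transform`` returns the scores of the retained components; use
    :meth:`score_frame` for a labelled frame (URBHI column only when a
    second component passes the Kaiser–Guttman criterion).
    """

    def __init__(self, min_samples: int = 10):
        super().__init__(
            URBANIZATION_FEATURES,
            anchors={0: "_total_developed", 1: "dev_high"},
            min_samples=min_samples,
        )

    def fit(self, X: pd.DataFrame, y=None):
        super().fit(X)
        if not self.retained_.any():
            warnings.warn(
                "no urbanization component exceeded eigenvalue 1; retaining the "
                "first component so a URB score is always available",
                stacklevel=2,
            )
            self.retained_ = np.zeros_like(self.retained_)
            self.retained_[0] = True
        self.n_retained_ = int(min(self.retained_[:2].sum(), 2))
        return self

    # sklearn clone support: parent __init__ signature differs
    def get_params(self, deep=True):
        return {"min_samples": self.min_samples}

    def set_params(self, **params):
        if "min_samples" in params:
            self.min_samples = params.pop("min_samples")
        if params:
            raise ValueError(f"unknown parameters: {sorted(params)}")
        return self

    def score_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "n_retained_")
        scores = self.transform(X)
        out = pd.DataFrame({"URB": scores[:, 0]}, index=X.index)
        if self.n_retained_ >= 2:
            out["URBHI"] = scores[:, 1]
        return out


class HeterogeneityIndex(StandardizedPCA):
    """First two heterogeneity components (H1, H2), always returned."""

    def __init__(self, min_samples: int = 10):
        super().__init__(
            HETEROGENEITY_FEATURES,
            anchors={0: "SHDI", 1: "ED"},
            min_samples=min_samples,
        )

    def get_params(self, deep=True):
        return {"min_samples": self.min_samples}

    def set_params(self, **params):
        if "min_samples" in params:
            self.min_samples = params.pop("min_samples")
        if params:
            raise ValueError(f"unknown parameters: {sorted(params)}")
        return self

    def score_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "loadings_")
        scores = self.transform(X)
        return pd.DataFrame(
            {"H1": scores[:, 0], "H2": scores[:, 1]}, index=X.index
        )


def urbanization_index(metrics_at_scale: pd.DataFrame):
    """Fit-and-score convenience wrapper; returns (score frame, fitted estimator)."""
    est = UrbanizationIndex().fit(metrics_at_scale)
    return est.score_frame(metrics_at_scale), est


def heterogeneity_index(metrics_at_scale: pd.DataFrame):
    """Fit-and-score convenience wrapper; returns (score frame, fitted estimator)."""
    est = HeterogeneityIndex().fit(metrics_at_scale)
    return est.score_frame(metrics_at_scale), est
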