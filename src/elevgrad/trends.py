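"""Richness-elevation trend fits and information-theoretic machinery.

Polynomial (degree 1-3) regressions of per-band richness on elevation,
and the AICc / Akaike-weight toolkit shared with the driver-selection
stage.  Fits are Gaussian OLS; the log-likelihood uses the maximum-
likelihood residual variance, and the parameter count K includes that
variance (so a straight-line fit has K = 3).  Reported R^2 is ordinary
(not adjusted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LinearModelFit",
    "fit_ols",
    "fit_polynomial",
    "aicc",
    "akaike_weights",
    "compare_polynomials",
]


@dataclass(frozen=True)
class LinearModelFit:
    """A fitted Gaussian linear model with AICc bookkeeping.

    ``terms`` excludes the intercept label only if the model was fitted
    without one (never the case here); ``K`` counts every coefficient
    plus the residual variance.  ``aicc`` is NaN when ``n - K - 1 <= 0``
    (the small-sample correction is undefined there).
    """

    terms: tuple[str, ...]
    coefficients: tuple[float, ...]
    n: int
    K: int
    log_likelihood: float
    r_squared: float
    aicc: float
    residuals: tuple[float, ...] = field(repr=False, default=())
    std_errors: tuple[float, ...] = field(repr=False, default=())
    t_stats: tuple[float, ...] = field(repr=False, default=())
    t_pvalues: tuple[float, ...] = field(repr=False, default=())
    f_pvalue: float = math.nan

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(self.terms, self.coefficients))

    @property
    def tvalues(self) -> dict[str, float]:
        return dict(zip(self.terms, self.t_stats))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        cols = [t for t in self.terms if t != "intercept"]
        mat = np.column_stack(
            [np.ones(len(X))] + [np.asarray(X[c], dtype=float) for c in cols]
        )
        return mat @ np.asarray(self.coefficients)


def aicc(log_likelihood: float, n: int, K: int) -> float:
    """AICc = -2 logL + 2K + 2K(K+1)/(n - K - 1); NaN when the denominator <= 0."""
    if n - K - 1 <= 0:
        return math.nan
    return -2.0 * log_likelihood + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def fit_ols(y, X: pd.DataFrame, terms: tuple[str, ...] | None = None) -> LinearModelFit:
    """OLS of ``y`` on the columns of ``X`` plus an intercept.

    Raises on a rank-deficient design.  ``terms`` relabels the non-
    intercept columns in the output (defaults to the column names).
    """
    y = np.asarray(y, dtype=float)
    cols = list(X.columns)
    mat = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise ValueError(f"rank-deficient design for terms {cols}")
    res = sm.OLS(y, mat).fit()
    labels = ("intercept",) + tuple(terms if terms is not None else cols)
    n = int(res.nobs)
    K = mat.shape[1] + 1  # coefficients + residual variance
    return LinearModelFit(
        terms=labels,
        coefficients=tuple(float(c) for c in res.params),
        n=n,
        K=K,
        log_likelihood=float(res.llf),
        r_squared=float(res.rsquared) if y.std() > 0 else 1.0,
        aicc=aicc(float(res.llf), n, K),
        residuals=tuple(float(r) for r in res.resid),
        std_errors=tuple(float(s) for s in res.bse),
        t_stats=tuple(float(t) for t in res.tvalues),
        t_pvalues=tuple(float(p) for p in res.pvalues),
        f_pvalue=float(res.f_pvalue) if mat.shape[1] > 1 else math.nan,
    )


def fit_polynomial(elevation, richness, degree: int) -> LinearModelFit:
    """Degree-1..3 polynomial fit of richness on centered elevation.

    Elevation is centered before powering to tame the collinearity of raw
    polynomial terms; coefficients are reported on the centered basis.
    """
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    x = np.asarray(elevation, dtype=float)
    y = np.asarray(richness, dtype=float)
    if x.size != y.size:
        raise ValueError("elevation and richness differ in length")
    if np.unique(x).size < degree + 1:
        raise ValueError("too few distinct elevations for this degree")
    if x.size <= degree + 1:
        raise ValueError(f"need more than {degree + 1} points for degree {degree}")
    xc = x - x.mean()
    X = pd.DataFrame({f"elev^{d}": xc**d for d in range(1, degree + 1)})
    return fit_ols(y, X)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2).

    Non-finite entries (models whose AICc is undefined) get weight zero;
    at least one finite value is required.
    """
    a = np.asarray(aicc_values, dtype=float)
    finite = np.isfinite(a)
    if not finite.any():
        raise ValueError("no model with finite AICc")
    delta = a - a[finite].min()
    w = np.where(finite, np.exp(-0.5 * np.where(finite, delta, 0.0)), 0.0)
    return w / w.sum()


def compare_polynomials(elevation, richness) -> dict:
    """Fit degrees 1-3 and pick the best by lowest AICc (ties -> lower degree).

    Returns ``{"fits": {degree: LinearModelFit}, "best_degree": int}``.
    The AICc winner can differ from the R^2 winner: R^2 never decreases
    with degree, while AICc penalizes the extra coefficients.
    """
    if np.asarray(elevation).size < 6:
        raise ValueError("need at least 6 bands to compare degrees 1-3")
    fits = {d: fit_polynomial(elevation, richness, d) for d in (1, 2, 3)}
    finite = {d: f.aicc for d, f in fits.items() if math.isfinite(f.aicc)}
    if not finite:
        raise ValueError("AICc undefined for every candidate degree")
    best = min(finite, key=lambda d: (finite[d], d))
    return {"fits": fits, "best_degree": best}
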