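"""Drivers of richness: collinearity screen, all-subsets model selection,
model averaging, and spatial residual diagnostics.

The inference chain mirrors standard multimodel practice in gradient
ecology: (1) drop all but one of any set of predictors correlated at
|r| > 0.7, keeping the one highest on an explicit priority list; (2) fit
every admissible sub-model of a global model
``richness ~ slope * (MDE + area + NDVI + PSR)`` — interactions enter
only with both parents (marginality); (3) rank by AICc, select the best,
and average over the smallest set of top models whose Akaike weights
cumulate to 0.95, summing weights per term as relative importance;
(4) check the best model with VIFs and Moran's I on its residuals.

Covariates on the natural scale ("elevational variables": area, MAT,
MAH, NDVI, PSR) are log-transformed before entering models; the MDE
predictor (a null-model richness expectation, already on the richness
scale) enters untransformed, and slope is a two-level indicator.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .trends import LinearModelFit, aicc, akaike_weights, fit_ols

__all__ = [
    "BandCovariates",
    "CandidateModelSet",
    "AveragedModel",
    "SpatialWeights",
    "MoranResult",
    "LOG_TERMS",
    "correlation_screen",
    "enumerate_models",
    "build_driver_design",
    "fit_model",
    "fit_candidate_set",
    "select_best",
    "model_average",
    "variable_importance_best",
    "vif",
    "build_spatial_weights",
    "morans_i",
]

#: covariates entered on the log scale (natural log)
LOG_TERMS = ("area", "MAT", "MAH", "NDVI", "PSR")


@dataclass(frozen=True)
class BandCovariates:
    """Environmental covariates for one slope x band."""

    slope: str
    elevation: int
    area: float          # planimetric area, km^2
    MAT: float           # mean annual temperature, deg C
    MAH: float           # mean annual humidity, %
    NDVI: float
    PSR: float           # plant species richness
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"area must be positive ({self.slope}/{self.elevation})")
        if not -1.0 <= self.NDVI <= 1.0:
            raise ValueError(
                f"NDVI {self.NDVI} outside [-1, 1] ({self.slope}/{self.elevation})"
            )


@dataclass(frozen=True)
class CandidateModelSet:
    """All-subsets fits ranked by AICc, with Akaike weights.

    ``order`` ranks models best-first; ``confidence_set_95`` flags the
    smallest best-first prefix whose cumulative weight reaches 0.95.
    """

    fits: tuple[LinearModelFit, ...]
    delta_aicc: np.ndarray
    weights: np.ndarray
    order: np.ndarray
    confidence_set_95: np.ndarray
    excluded: tuple[tuple[str, ...], ...] = ()

    def ranked(self) -> list[LinearModelFit]:
        return [self.fits[i] for i in self.order]


@dataclass(frozen=True)
class AveragedModel:
    """Model-averaged coefficients and per-term summed-weight importance."""

    importance: dict[str, float]
    averaged_coefficients: dict[str, float]
    method: str = "full"


@dataclass(frozen=True)
class SpatialWeights:
    matrix: np.ndarray
    row_standardized: bool
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = self.matrix
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if not np.any(w > 0):
            raise ValueError("all-zero weight matrix")


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p_value: float


# ---------------------------------------------------------------------------
# collinearity screen

def correlation_screen(
    table: pd.DataFrame,
    threshold: float = 0.7,
    keep_priority: Sequence[str] = ("NDVI",),
) -> tuple[list[str], pd.DataFrame]:
    """Drop all but one of each cluster of predictors with |r| > threshold.

    Clusters are the connected components of the graph linking columns
    whose pairwise Pearson |r| exceeds ``threshold``; within a cluster
    the retained column is the first on ``keep_priority`` (columns not
    listed rank after, in table order).  Returns the retained column
    names (table order) and the full correlation matrix.
    """
    num = table.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise ValueError("need at least 3 rows to screen correlations")
    constant = [c for c in num.columns if num[c].nunique() <= 1]
    if constant:
        raise ValueError(f"correlation undefined for constant column(s): {constant}")
    corr = num.corr(method="pearson")
    cols = list(num.columns)

    # union-find over the |r| > threshold graph
    parent = {c: c for c in cols}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for a, b in itertools.combinations(cols, 2):
        if abs(corr.loc[a, b]) > threshold:
            parent[find(a)] = find(b)

    rank = {c: (keep_priority.index(c) if c in keep_priority else len(keep_priority) + i)
            for i, c in enumerate(cols)}
    keep: set[str] = set()
    for _, members in itertools.groupby(
        sorted(cols, key=find), key=find
    ):
        keep.add(min(members, key=lambda c: rank[c]))
    return [c for c in cols if c in keep], corr


# ---------------------------------------------------------------------------
# candidate-set enumeration

def _parents(interaction: str) -> tuple[str, str]:
    parts = interaction.split(":")
    if len(parts) != 2:
        raise ValueError(f"malformed interaction term {interaction!r}")
    return parts[0], parts[1]


def enumerate_models(
    main_terms: Sequence[str],
    interaction_terms: Sequence[str] = (),
    marginality: bool = True,
) -> list[tuple[str, ...]]:
    """All sub-models of the global model, intercept always included.

    Interactions are ``"a:b"`` strings referencing two main terms; under
    marginality an interaction is admissible only when both parents are
    in the subset.  The intercept-only model is the empty tuple.
    """
    mains = list(main_terms)
    for it in interaction_terms:
        a, b = _parents(it)
        if a not in mains or b not in mains:
            raise ValueError(f"interaction {it!r} references undeclared main terms")
    models: list[tuple[str, ...]] = []
    for k in range(len(mains) + 1):
        for sub in itertools.combinations(mains, k):
            ok_inter = [
                it for it in interaction_terms
                if not marginality
                or (_parents(it)[0] in sub and _parents(it)[1] in sub)
            ]
            for ki in range(len(ok_inter) + 1):
                for isub in itertools.combinations(ok_inter, ki):
                    models.append(tuple(sub) + tuple(isub))
    return models


# ---------------------------------------------------------------------------
# design construction and fitting

def build_driver_design(
    covariates: pd.DataFrame,
    mde: Sequence[float] | None = None,
    log_terms: Sequence[str] = LOG_TERMS,
) -> pd.DataFrame:
    """Analysis-scale design table from a slope x band covariate table.

    Applies natural logs to the elevational variables present, recodes
    ``slope`` as a 0/1 indicator (levels in sorted order), and attaches
    the MDE predictor untransformed when given.
    """
    out = pd.DataFrame(index=covariates.index)
    levels = sorted(covariates["slope"].unique())
    if len(levels) > 2:
        raise ValueError(f"slope must have at most 2 levels, got {levels}")
    out["slope"] = (covariates["slope"] == levels[-1]).astype(float)
    for col in covariates.columns:
        if col in ("slope", "elevation", "latitude", "longitude"):
            continue
        x = np.asarray(covariates[col], dtype=float)
        if col in log_terms:
            if np.any(x <= 0):
                raise ValueError(f"cannot log-transform non-positive {col}")
            out[col] = np.log(x)
        else:
            out[col] = x
    if mde is not None:
        out["MDE"] = np.asarray(mde, dtype=float)
    return out


def _model_matrix(design: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    cols = {}
    for t in terms:
        if ":" in t:
            a, b = _parents(t)
            cols[t] = np.asarray(design[a], dtype=float) * np.asarray(
                design[b], dtype=float
            )
        else:
            if t not in design.columns:
                raise KeyError(f"term {t!r} not in design")
            cols[t] = np.asarray(design[t], dtype=float)
    return pd.DataFrame(cols, index=design.index)


def fit_model(
    richness,
    design: pd.DataFrame,
    terms: Sequence[str],
    family: str = "gaussian",
) -> LinearModelFit:
    """Fit one candidate model of richness on analysis-scale predictors.

    Default family is Gaussian with identity link (OLS), whose R^2 is the
    quantity reported alongside the AICc ranking; a Poisson-log fit is
    available behind the flag for count-minded users.
    """
    terms = tuple(terms)
    X = _model_matrix(design, terms)
    if family == "gaussian":
        return fit_ols(richness, X, terms=terms)
    if family != "poisson":
        raise ValueError(f"unknown family {family!r}")
    y = np.asarray(richness, dtype=float)
    mat = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
    res = sm.GLM(y, mat, family=sm.families.Poisson()).fit()
    n = int(res.nobs)
    K = mat.shape[1]  # Poisson has no dispersion parameter
    return LinearModelFit(
        terms=("intercept",) + terms,
        coefficients=tuple(float(c) for c in res.params),
        n=n,
        K=K,
        log_likelihood=float(res.llf),
        r_squared=float(1.0 - res.deviance / res.null_deviance)
        if res.null_deviance > 0 else 1.0,
        aicc=aicc(float(res.llf), n, K),
        residuals=tuple(float(r) for r in res.resid_response),
        std_errors=tuple(float(s) for s in res.bse),
        t_stats=tuple(float(t) for t in res.tvalues),
        t_pvalues=tuple(float(p) for p in res.pvalues),
    )


def fit_candidate_set(
    richness,
    design: pd.DataFrame,
    models: Iterable[Sequence[str]] | None = None,
    family: str = "gaussian",
    cum_weight: float = 0.95,
) -> CandidateModelSet:
    """Fit every candidate model and rank by AICc.

    Models whose AICc is undefined at this sample size
    (``n - K - 1 <= 0``) are excluded from the ranked set with a warning;
    with 12 bands this removes the 10-coefficient global model, so the
    saturated model can never "win" at that design size.
    """
    if models is None:
        mains = ["slope"] + [c for c in design.columns if c != "slope"]
        inters = [f"slope:{c}" for c in mains[1:]]
        models = enumerate_models(mains, inters, marginality=True)
    fits: list[LinearModelFit] = []
    excluded: list[tuple[str, ...]] = []
    for terms in models:
        fit = fit_model(richness, design, terms, family=family)
        if math.isfinite(fit.aicc):
            fits.append(fit)
        else:
            excluded.append(tuple(terms))
    if excluded:
        warnings.warn(
            f"{len(excluded)} model(s) dropped: AICc undefined (n - K - 1 <= 0)",
            stacklevel=2,
        )
    if not fits:
        raise ValueError("no candidate model has a defined AICc")
    aiccs = np.array([f.aicc for f in fits])
    w = akaike_weights(aiccs)
    # rank: AICc, then fewer terms, then lexicographic term labels
    order = np.array(
        sorted(range(len(fits)),
               key=lambda i: (aiccs[i], len(fits[i].terms), fits[i].terms))
    )
    cum = np.cumsum(w[order])
    in_set = np.zeros(len(fits), dtype=bool)
    cutoff = int(np.searchsorted(cum, cum_weight) + 1)
    in_set[order[:cutoff]] = True
    return CandidateModelSet(
        fits=tuple(fits),
        delta_aicc=aiccs - aiccs.min(),
        weights=w,
        order=order,
        confidence_set_95=in_set,
        excluded=tuple(excluded),
    )


def select_best(candidates: CandidateModelSet) -> LinearModelFit:
    """The lowest-AICc model (ties: fewer terms, then lexicographic)."""
    return candidates.fits[candidates.order[0]]


def model_average(
    candidates: CandidateModelSet,
    cum_weight: float = 0.95,
    method: str = "full",
) -> AveragedModel:
    """Average over the confidence set of models cumulating ``cum_weight``.

    Weights are renormalized within the set.  Importance of a term is the
    summed weight of set members containing it.  Full averaging
    substitutes a zero coefficient where a term is absent; conditional
    averaging renormalizes over the containing models only.
    """
    if method not in ("full", "conditional"):
        raise ValueError(f"unknown averaging method {method!r}")
    idx = [i for i in candidates.order if candidates.confidence_set_95[i]]
    w = candidates.weights[idx]
    w = w / w.sum()
    terms: list[str] = []
    for i in idx:
        for t in candidates.fits[i].terms:
            if t not in terms:
                terms.append(t)
    importance: dict[str, float] = {}
    avg: dict[str, float] = {}
    for t in terms:
        contains = np.array([t in candidates.fits[i].terms for i in idx])
        importance[t] = float(w[contains].sum())
        betas = np.array(
            [candidates.fits[i].coef.get(t, 0.0) for i in idx]
        )
        if method == "full":
            avg[t] = float((w * betas).sum())
        else:
            avg[t] = float((w[contains] * betas[contains]).sum() / w[contains].sum())
    importance.pop("intercept", None)
    return AveragedModel(importance=importance, averaged_coefficients=avg,
                         method=method)


def variable_importance_best(
    fit: LinearModelFit, rescale: bool = False
) -> dict[str, float]:
    """|t|-statistic importance of each non-intercept term in the best model.

    With ``rescale`` the scores are mapped linearly to [0, 100] with the
    largest |t| at 100.
    """
    scores = {t: abs(v) for t, v in fit.tvalues.items() if t != "intercept"}
    if not scores:
        raise ValueError("model has no non-intercept terms")
    if rescale:
        top = max(scores.values())
        if top > 0:
            scores = {t: 100.0 * v / top for t, v in scores.items()}
    return scores


def vif(design: pd.DataFrame, terms: Sequence[str] | None = None) -> dict[str, float]:
    """Variance inflation factors: 1 / (1 - R^2_j) per predictor.

    R^2_j comes from regressing predictor j on the other predictors (with
    intercept).  Perfect collinearity is reported as ``inf``.  Values
    >= 5 are conventionally flagged as problematic collinearity.
    """
    X = _model_matrix(design, tuple(terms)) if terms is not None else design.copy()
    cols = list(X.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs at least 2 predictors")
    out: dict[str, float] = {}
    for j, c in enumerate(cols):
        others = X[[o for o in cols if o != c]]
        mat = sm.add_constant(np.asarray(others, dtype=float), has_constant="add")
        r2 = float(sm.OLS(np.asarray(X[c], dtype=float), mat).fit().rsquared)
        out[c] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


# ---------------------------------------------------------------------------
# spatial diagnostics

def build_spatial_weights(
    band_table: pd.DataFrame,
    scheme: str = "chain",
    row_standardize: bool = True,
) -> SpatialWeights:
    """Spatial weights over slope x band units.

    ``chain`` (default): binary adjacency between consecutive bands
    within a slope; slopes are disconnected blocks.  ``idw``: inverse
    distance on latitude/longitude (degrees, euclidean), all pairs.
    """
    n = len(band_table)
    if n < 2:
        raise ValueError("need at least 2 units")
    w = np.zeros((n, n))
    rows = band_table.reset_index(drop=True)
    if scheme == "chain":
        for slope, grp in rows.groupby("slope"):
            idx = grp.sort_values("elevation").index.to_numpy()
            for a, b in zip(idx[:-1], idx[1:]):
                w[a, b] = w[b, a] = 1.0
    elif scheme == "idw":
        if "latitude" not in rows or "longitude" not in rows:
            raise ValueError("idw scheme needs latitude/longitude columns")
        pts = rows[["latitude", "longitude"]].to_numpy(dtype=float)
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        with np.errstate(divide="ignore"):
            w = np.where(d > 0, 1.0 / d, 0.0)
        np.fill_diagonal(w, 0.0)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    zero_rows = np.where(w.sum(axis=1) == 0)[0]
    if zero_rows.size:
        if row_standardize:
            raise ValueError(f"unit(s) {zero_rows.tolist()} have no neighbors")
        warnings.warn(f"unit(s) {zero_rows.tolist()} have no neighbors", stacklevel=2)
    if row_standardize:
        w = w / w.sum(axis=1, keepdims=True)
    labels = tuple(
        f"{s}:{e}" for s, e in zip(rows["slope"], rows["elevation"])
    ) if "elevation" in rows else ()
    return SpatialWeights(matrix=w, row_standardized=row_standardize, labels=labels)


def morans_i(residuals, weights: SpatialWeights) -> MoranResult:
    """Moran's I of a residual vector under the normal approximation.

    I = (n / S0) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2) with z the
    centered residuals; E[I] = -1/(n-1); the variance uses the normality
    assumption, and p is two-sided.
    """
    z = np.asarray(residuals, dtype=float)
    n = z.size
    w = weights.matrix
    if n < 3:
        raise ValueError("need at least 3 observations")
    if w.shape[0] != n:
        raise ValueError("weights do not conform to the residual vector")
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("zero residual variance")
    s0 = float(w.sum())
    I = (n / s0) * float(z @ w @ z) / denom
    expected = -1.0 / (n - 1)
    s1 = 0.5 * float(((w + w.T) ** 2).sum())
    s2 = float(((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum())
    var = (n**2 * s1 - n * s2 + 3 * s0**2) / ((n**2 - 1) * s0**2) - expected**2
    zscore = (I - expected) / math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(zscore)))
    return MoranResult(I=float(I), expected=expected, variance=float(var),
                       z=float(zscore), p_value=p)
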