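"""Hypothesis comparison machinery: rank tests, ML regression fits,
AICc multimodel inference.

Five candidate regression hypotheses are compared for each tooth row
(upper and lower OPCR as response): the opposing tooth row alone, plus
relative lateral translation (rt), relative ventral rotational distance
(rd), both, or the sagittal occlusal angle (ln a).  Single-predictor
models are ordinary least squares fitted by maximum likelihood; models
with two or more predictors are generalized least squares with a
Gaussian (squared-exponential) residual correlation

    corr(e_i, e_j) = exp(-(s_ij / rho)**2)

where s_ij is the Euclidean distance between observations i and j in
the model's own (unscaled, log-transformed) predictor space.  beta and
sigma are profiled analytically; rho is optimized numerically by ML.
Models are ranked by the small-sample Akaike criterion

    AICc = -2 logLik + 2K + 2K(K+1)/(n - K - 1)

with K = number of coefficients + residual SD + (range parameter when a
correlation structure is used).  Akaike weights, 95% confidence sets and
weighted model averaging summarize selection uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "MannWhitneyResult",
    "mann_whitney_u",
    "pearson_r",
    "ModelSpec",
    "FitResult",
    "SelectionTable",
    "candidate_models",
    "ols_fit",
    "gls_fit",
    "aicc",
    "akaike_weights",
    "build_selection_table",
    "model_average",
]


# ---------------------------------------------------------------------------
# two-sample and association statistics
# ---------------------------------------------------------------------------


@dataclass
class MannWhitneyResult:
    U: float  # statistic of the first sample
    p: float
    method: str  # "exact" or "asymptotic"


def mann_whitney_u(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test, U reported for the first sample.

    U = #{(i, j): x_i > y_j} + 0.5 * #ties.  The p-value is exact when
    both samples have at most 25 observations and the pooled data holds
    no ties; otherwise a normal approximation with tie and continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and max(x.size, y.size) <= 25:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return MannWhitneyResult(U=float(res.statistic), p=float(res.pvalue), method=method)


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a sample has zero variance")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# model specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """One candidate hypothesis: response regressed on the opposing
    tooth row plus an optional subset of motion measures."""

    number: int
    response: str  # "ln_upper" | "ln_lower"
    predictors: tuple[str, ...]
    use_correlation: bool

    @property
    def name(self) -> str:
        return f"{self.response} ~ " + " + ".join(self.predictors)


def candidate_models(response: str) -> list[ModelSpec]:
    """The five candidate models for one response, numbered 1-5.

    The opposing tooth row's OPCR is always among the predictors; a
    Gaussian correlation structure is used whenever there are two or
    more predictors.
    """
    if response == "ln_upper":
        opp = "ln_lower"
    elif response == "ln_lower":
        opp = "ln_upper"
    else:
        raise ValueError("response must be 'ln_upper' or 'ln_lower'")
    combos = {
        1: (opp,),
        2: (opp, "rt"),
        3: (opp, "rd"),
        4: (opp, "rt", "rd"),
        5: (opp, "ln_a"),
    }
    return [ModelSpec(number=k, response=response, predictors=v,
                      use_correlation=len(v) >= 2)
            for k, v in combos.items()]


@dataclass
class FitResult:
    spec: ModelSpec | None
    coefficients: dict[str, float]  # "intercept" + one per predictor
    sigma: float  # residual SD, ML denominator n
    loglik: float
    K: int
    n: int
    aicc: float
    rho: float | None = None  # correlation range (GLS only)
    r_squared: float | None = None
    p_values: dict[str, float] = field(default_factory=dict)
    standard_errors: dict[str, float] = field(default_factory=dict)
    rho_at_bound: bool = False
    error: str | None = None


# ---------------------------------------------------------------------------
# maximum-likelihood fits
# ---------------------------------------------------------------------------


def _as_design(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def ols_fit(y, X, names: tuple[str, ...] | None = None,
            spec: ModelSpec | None = None) -> FitResult:
    """ML fit of an ordinary linear regression.

    sigma uses denominator n (not n - p) so that ``loglik`` is the
    maximized Gaussian likelihood; r-squared and coefficient p-values
    are attached for the association use-case.
    """
    y = np.asarray(y, dtype=float)
    X = _as_design(X)
    n, p = X.shape
    if names is None:
        names = tuple(f"x{i + 1}" for i in range(p))
    K = p + 2  # intercept + slopes + sigma
    if n <= K:
        raise ValueError(f"need n > K = {K} observations, got {n}")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    fit = sm.OLS(y, design).fit()
    coefs = {"intercept": float(fit.params[0])}
    pvals = {"intercept": float(fit.pvalues[0])}
    ses = {"intercept": float(fit.bse[0])}
    for i, nm in enumerate(names):
        coefs[nm] = float(fit.params[i + 1])
        pvals[nm] = float(fit.pvalues[i + 1])
        ses[nm] = float(fit.bse[i + 1])
    sigma = float(np.sqrt(np.mean(fit.resid ** 2)))
    ll = float(fit.llf)  # statsmodels llf is the ML (denominator-n) value
    return FitResult(spec=spec, coefficients=coefs, sigma=sigma, loglik=ll,
                     K=K, n=n, aicc=aicc(ll, K, n), r_squared=float(fit.rsquared),
                     p_values=pvals, standard_errors=ses)


def _gauss_profile_loglik(rho: float, y: np.ndarray, design: np.ndarray,
                          D: np.ndarray):
    """Profiled ML log-likelihood at a fixed correlation range rho.

    Returns (loglik, beta, sigma); loglik is -inf when the correlation
    matrix is not numerically positive definite.
    """
    n = len(y)
    C = np.exp(-((D / rho) ** 2))
    try:
        cf = cho_factor(C, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    Ciy = cho_solve(cf, y)
    CiX = cho_solve(cf, design)
    XtCiX = design.T @ CiX
    try:
        beta = np.linalg.solve(XtCiX, design.T @ Ciy)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    r = y - design @ beta
    quad = float(r @ cho_solve(cf, r))
    if quad <= 0:
        return -np.inf, None, None
    sigma2 = quad / n
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0) - 0.5 * logdet
    return float(ll), beta, float(np.sqrt(sigma2))


def gls_fit(y, X, positions=None, names: tuple[str, ...] | None = None,
            spec: ModelSpec | None = None,
            rho_bracket: tuple[float, float] = (1e-6, 1e3),
            n_grid: int = 60, tol: float = 1e-8) -> FitResult:
    """ML GLS with Gaussian residual correlation over ``positions``.

    corr(e_i, e_j) = exp(-(s_ij/rho)^2) with s_ij the Euclidean distance
    between positions (default: the predictor columns themselves).  beta
    and sigma are profiled analytically; rho is maximized on a log grid
    spanning ``rho_bracket`` x (median pairwise distance), then refined
    by bounded scalar optimization to ``tol`` in log-likelihood.  Ranges
    making the correlation matrix numerically singular are rejected, so
    the rho -> 0 limit (independent residuals) competes fairly with any
    interior optimum.
    """
    y = np.asarray(y, dtype=float)
    X = _as_design(X)
    n, p = X.shape
    if names is None:
        names = tuple(f"x{i + 1}" for i in range(p))
    K = p + 3  # intercept + slopes + sigma + rho
    if n <= K:
        raise ValueError(f"need n > K = {K} observations, got {n}")
    if positions is None:
        positions = X
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 1:
        positions = positions[:, None]
    D = squareform(pdist(positions))
    dmed = float(np.median(D[np.triu_indices(n, 1)]))
    if dmed <= 0:
        raise ValueError("positions are all identical: correlation range undefined")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")

    lo, hi = rho_bracket[0] * dmed, rho_bracket[1] * dmed
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), n_grid))
    lls = np.array([_gauss_profile_loglik(r, y, design, D)[0] for r in grid])
    if not np.isfinite(lls).any():
        raise RuntimeError("GLS correlation optimization failed at every range tried")
    k = int(np.nanargmax(np.where(np.isfinite(lls), lls, -np.inf)))
    lo_r = grid[max(k - 1, 0)]
    hi_r = grid[min(k + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda u: -_gauss_profile_loglik(np.exp(u), y, design, D)[0],
        bounds=(np.log(lo_r), np.log(hi_r)), method="bounded",
        options={"xatol": 1e-10})
    rho = float(np.exp(res.x))
    ll, beta, sigma = _gauss_profile_loglik(rho, y, design, D)
    if not np.isfinite(ll) or ll < lls[k] - tol:
        rho = float(grid[k])
        ll, beta, sigma = _gauss_profile_loglik(rho, y, design, D)
    at_bound = k in (0, n_grid - 1)
    coefs = {"intercept": float(beta[0])}
    coefs.update({nm: float(b) for nm, b in zip(names, beta[1:])})
    return FitResult(spec=spec, coefficients=coefs, sigma=sigma, loglik=ll,
                     K=K, n=n, aicc=aicc(ll, K, n), rho=rho, rho_at_bound=at_bound)


# ---------------------------------------------------------------------------
# information criteria and multimodel inference
# ---------------------------------------------------------------------------


def aicc(loglik: float, K: int, n: int) -> float:
    """Second-order (small-sample) Akaike information criterion."""
    if n - K - 1 <= 0:
        raise ValueError(f"AICc undefined: need n > K + 1 (n={n}, K={K})")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def akaike_weights(aiccs) -> np.ndarray:
    """Normalized exp(-delta/2) selection weights."""
    a = np.asarray(aiccs, dtype=float)
    if a.size < 1:
        raise ValueError("need at least one AICc value")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class SelectionTable:
    """Candidate fits ranked by AICc with selection-uncertainty columns."""

    rows: list[FitResult]  # sorted by aicc ascending
    delta: np.ndarray
    weight: np.ndarray
    in_conf_set: np.ndarray  # smallest weight-ordered prefix >= 0.95

    def to_frame(self) -> pd.DataFrame:
        """Mirror the selection-table layout: model number, coefficients,
        df, logLik, AICc, delta, weight."""
        predictor_order = []
        for r in self.rows:
            for p in (r.spec.predictors if r.spec else r.coefficients):
                if p != "intercept" and p not in predictor_order:
                    predictor_order.append(p)
        recs = []
        for i, r in enumerate(self.rows):
            rec = {"model": r.spec.number if r.spec else i + 1,
                   "intercept": r.coefficients.get("intercept")}
            for p in predictor_order:
                rec[p] = r.coefficients.get(p)
            rec.update({"df": r.K, "logLik": r.loglik, "AICc": r.aicc,
                        "delta_AICc": self.delta[i], "akaike_weight": self.weight[i],
                        "in_conf_set": bool(self.in_conf_set[i])})
            recs.append(rec)
        return pd.DataFrame(recs)

    @property
    def best(self) -> FitResult:
        return self.rows[0]

    def ranking(self) -> list[int]:
        return [r.spec.number for r in self.rows if r.spec is not None]


def _fit_one(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    y = data[spec.response].to_numpy()
    X = data[list(spec.predictors)].to_numpy()
    if spec.use_correlation:
        return gls_fit(y, X, names=spec.predictors, spec=spec)
    return ols_fit(y, X, names=spec.predictors, spec=spec)


def build_selection_table(specs: list[ModelSpec], data: pd.DataFrame,
                          conf_level: float = 0.95) -> SelectionTable:
    """Fit every candidate, rank by AICc, attach delta/weights/confidence set.

    Fit failures annotate the offending row (error string, excluded from
    the ranking) rather than aborting the table.
    """
    if len(specs) < 2:
        raise ValueError("need at least two candidate models")
    if len({s.response for s in specs}) != 1:
        raise ValueError("all candidate models must share a response")
    fits, failed = [], []
    for s in specs:
        try:
            fits.append(_fit_one(s, data))
        except Exception as e:  # annotate, keep going
            failed.append(FitResult(spec=s, coefficients={}, sigma=np.nan,
                                    loglik=np.nan, K=0, n=len(data), aicc=np.inf,
                                    error=str(e)))
    if len(fits) < 2:
        raise RuntimeError("fewer than two candidate models converged")
    fits.sort(key=lambda f: f.aicc)
    a = np.array([f.aicc for f in fits])
    delta = a - a.min()
    weight = akaike_weights(a)
    cum = np.cumsum(weight)
    cutoff = int(np.searchsorted(cum, conf_level) + 1)
    in_set = np.arange(len(fits)) < cutoff
    return SelectionTable(rows=fits + failed,
                          delta=np.concatenate([delta, np.full(len(failed), np.nan)]),
                          weight=np.concatenate([weight, np.zeros(len(failed))]),
                          in_conf_set=np.concatenate([in_set, np.zeros(len(failed), bool)]))


def model_average(table: SelectionTable, scope: str = "confidence_set",
                  convention: str = "natural") -> dict[str, float]:
    """Akaike-weighted average of coefficients over a model scope.

    scope: "confidence_set" (default) or "all".  convention: "natural"
    averages each term over the models that contain it (weights
    renormalized within those models); "zero_substitution" treats a
    missing term as a zero coefficient over the whole scope.
    """
    if scope == "confidence_set":
        idx = [i for i in range(len(table.rows)) if table.in_conf_set[i]]
    elif scope == "all":
        idx = [i for i in range(len(table.rows)) if table.rows[i].error is None]
    else:
        raise ValueError("scope must be 'confidence_set' or 'all'")
    if not idx:
        raise ValueError("empty model scope")
    w = table.weight[idx]
    w = w / w.sum()
    terms: list[str] = []
    for i in idx:
        for t in table.rows[i].coefficients:
            if t not in terms:
                terms.append(t)
    out = {}
    for t in terms:
        if convention == "zero_substitution":
            out[t] = float(sum(wi * table.rows[i].coefficients.get(t, 0.0)
                               for wi, i in zip(w, idx)))
        elif convention == "natural":
            pres = [(wi, table.rows[i].coefficients[t])
                    for wi, i in zip(w, idx) if t in table.rows[i].coefficients]
            wsum = sum(wi for wi, _ in pres)
            out[t] = float(sum(wi * c for wi, c in pres) / wsum)
        else:
            raise ValueError("convention must be 'natural' or 'zero_substitution'")
    return out
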