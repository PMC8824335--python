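"""Statistical inference on localization metrics and pattern categories.

Covers the analysis stage downstream of the metrics and the classifier:

- fixed-effects OLS of per-subject outcomes (e.g. overall RMS error) on
  patient factors, with onset-of-deafness group coded 0 = early (onset <= 5
  years) and 1 = late;
- a random-intercept linear mixed model of log per-angle RMS error on onset
  group (OD), squared target angle (STA, deg^2) and their interaction, REML
  by default, with Satterthwaite denominator degrees of freedom for the
  fixed-effect t tests;
- backward stepwise model selection by AIC with a collinearity screen
  (factor pairs with |r| > .75 may not enter the same selection);
- the uncorrected 2x2 Pearson chi-square test for category-count contrasts,
  and a Monte-Carlo power estimate for that test at given group rates;
- Pearson correlations (r and r^2).

Parameter estimation for the mixed model is delegated to
``statsmodels.MixedLM``; the Satterthwaite step is computed here from the
curvature of the profiled REML log-likelihood in the two variance
components, since statsmodels reports only large-sample z tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class RegressionResult:
    """Coefficient table and model-level statistics from one regression."""

    terms: pd.DataFrame   # columns: term, estimate, se, df, t, p
    model_stats: dict


@dataclass
class ContingencyTest:
    """Uncorrected Pearson chi-square on a 2x2 count table."""

    table: np.ndarray
    statistic: float
    df: int
    p: float


@dataclass
class PearsonResult:
    r: float
    r2: float
    n: int


# ---------------------------------------------------------------------------
# Design-matrix helpers
# ---------------------------------------------------------------------------

def _encode_column(data: pd.DataFrame, name: str) -> np.ndarray:
    if name == "onset_group":
        vals = data["onset_group"].astype(str)
        bad = ~vals.isin(["early", "late"])
        if bad.any():
            raise ValueError(f"onset_group values must be early/late, got "
                             f"{sorted(vals[bad].unique())}")
        return (vals == "late").to_numpy(dtype=float)
    return pd.to_numeric(data[name]).to_numpy(dtype=float)


def build_design(data: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Design matrix with intercept; ``a:b`` terms are elementwise products.

    ``onset_group`` is treatment-coded with "early" as the reference level
    (0 = early, 1 = late).
    """
    X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    for term in terms:
        parts = term.split(":")
        col = _encode_column(data, parts[0])
        for p in parts[1:]:
            col = col * _encode_column(data, p)
        X[term] = col
    return X


def _check_rank(X: pd.DataFrame) -> None:
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        # name the culprits: columns whose removal restores full rank
        cols = [c for c in X.columns if c != "Intercept"]
        culprits = [
            c for c in cols
            if np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy())
            == np.linalg.matrix_rank(X.to_numpy())
        ]
        raise ValueError(f"rank-deficient design; collinear column(s): {culprits}")


# ---------------------------------------------------------------------------
# Fixed-effects OLS
# ---------------------------------------------------------------------------

def ols(data: pd.DataFrame, response: str, predictors: list[str]) -> RegressionResult:
    """Fixed-effects multiple regression on complete cases.

    Reports per-term t tests on n - k - 1 residual df, the overall F with its
    (k, n - k - 1) df pair, adjusted R^2 and AIC.
    """
    use = data[[response] + sorted({p for t in predictors for p in t.split(":")})]
    use = use.dropna()
    if len(use) < len(predictors) + 2:
        raise ValueError("too few complete cases for the requested model")
    X = build_design(use, predictors)
    _check_rank(X)
    y = pd.to_numeric(use[response]).to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    df_resid = int(fit.df_resid)
    terms = pd.DataFrame(
        {
            "term": X.columns,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "df": df_resid,
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    stats_ = {
        "aic": float(fit.aic),
        "adjusted_r2": float(fit.rsquared_adj),
        "f_statistic": float(fit.fvalue) if len(predictors) else np.nan,
        "f_df": (int(fit.df_model), df_resid),
        "n": int(fit.nobs),
    }
    return RegressionResult(terms, stats_)


# ---------------------------------------------------------------------------
# Random-intercept mixed model with Satterthwaite df
# ---------------------------------------------------------------------------

def _group_blocks(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    order = np.argsort(groups, kind="stable")
    Xo, yo, go = X[order], y[order], groups[order]
    _, starts = np.unique(go, return_index=True)
    bounds = list(starts) + [len(go)]
    return [
        (Xo[bounds[i]:bounds[i + 1]], yo[bounds[i]:bounds[i + 1]])
        for i in range(len(bounds) - 1)
    ]


def _reml_pieces(blocks, s2b: float, s2e: float):
    """X'V^-1 X, X'V^-1 y, y'V^-1 y and log|V| for block-diagonal V."""
    p = blocks[0][0].shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for Xg, yg in blocks:
        ng = len(yg)
        c = s2b / (s2e + ng * s2b)
        xs, ys = Xg.sum(axis=0), yg.sum()
        xtvx += (Xg.T @ Xg - c * np.outer(xs, xs)) / s2e
        xtvy += (Xg.T @ yg - c * xs * ys) / s2e
        ytvy += (yg @ yg - c * ys * ys) / s2e
        logdet += (ng - 1) * np.log(s2e) + np.log(s2e + ng * s2b)
    return xtvx, xtvy, ytvy, logdet


def _reml_loglik(blocks, s2b: float, s2e: float) -> float:
    xtvx, xtvy, ytvy, logdet = _reml_pieces(blocks, s2b, s2e)
    beta = np.linalg.solve(xtvx, xtvy)
    quad = ytvy - beta @ xtvy
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    return -0.5 * (logdet + logdet_xtvx + quad)


def _cov_beta(blocks, s2b: float, s2e: float) -> np.ndarray:
    xtvx, *_ = _reml_pieces(blocks, s2b, s2e)
    return np.linalg.inv(xtvx)


def satterthwaite_df(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, s2b: float, s2e: float
) -> np.ndarray:
    """Satterthwaite denominator df for each fixed-effect coefficient.

    For coefficient i let f(theta) = Var(beta_hat_i) as a function of the
    variance components theta = (sigma_b^2, sigma_e^2). The df is
    ``2 f^2 / (g' A g)`` where g is the gradient of f and A the asymptotic
    covariance of theta_hat, taken as the inverse observed information of the
    profiled REML log-likelihood. Gradients and the information matrix are
    computed by central finite differences (forward at a zero boundary).
    """
    blocks = _group_blocks(X, y, groups)
    theta = np.array([max(s2b, 0.0), s2e], dtype=float)
    steps = np.maximum(1e-4 * np.maximum(theta, 1e-3), 1e-8)

    def cov_diag(th):
        return np.diag(_cov_beta(blocks, max(th[0], 0.0), max(th[1], 1e-12)))

    # gradient of each Var(beta_i) wrt theta: (2, p)
    grads = np.empty((2, X.shape[1]))
    for j in range(2):
        hi, lo = theta.copy(), theta.copy()
        hi[j] += steps[j]
        if theta[j] - steps[j] > 0:
            lo[j] -= steps[j]
            grads[j] = (cov_diag(hi) - cov_diag(lo)) / (2 * steps[j])
        else:
            grads[j] = (cov_diag(hi) - cov_diag(theta)) / steps[j]

    def ll(th):
        return _reml_loglik(blocks, max(th[0], 0.0), max(th[1], 1e-12))

    H = np.empty((2, 2))
    for j in range(2):
        for k in range(j, 2):
            ej = np.zeros(2); ej[j] = steps[j]
            ek = np.zeros(2); ek[k] = steps[k]
            base = theta
            if theta[0] - steps[0] <= 0:  # shift away from the boundary
                base = theta + np.array([steps[0], 0.0]) * 2
            H[j, k] = H[k, j] = (
                ll(base + ej + ek) - ll(base + ej - ek)
                - ll(base - ej + ek) + ll(base - ej - ek)
            ) / (4 * steps[j] * steps[k])
    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        A = np.full((2, 2), np.nan)

    f = cov_diag(theta)
    denom = np.einsum("jp,jk,kp->p", grads, A, grads)
    n, p = X.shape
    fallback = float(n - p)
    df = np.where(
        np.isfinite(denom) & (denom > 0), 2.0 * f**2 / np.where(denom > 0, denom, 1.0),
        fallback,
    )
    # the df can never exceed the residual df of the pooled model and never
    # drop below 1; clamp pathological finite-difference outcomes
    return np.clip(df, 1.0, fallback)


def mixed_model(
    long: pd.DataFrame,
    response: str = "log_rms",
    predictors: list[str] | None = None,
    group: str = "subject",
    *,
    reml: bool = True,
) -> RegressionResult:
    """Random-intercept linear mixed model of a long (subject x angle) table.

    Defaults fit ``log_rms ~ od + sta + od:sta + (1 | subject)`` where ``od``
    is the onset-group indicator and ``sta`` the squared target angle.
    Fixed-effect t tests use Satterthwaite df. A between-subject variance
    estimated at (or pushed to) zero is reported as 0 with a boundary
    warning; the fit still returns.
    """
    predictors = predictors if predictors is not None else ["od", "sta", "od:sta"]
    use = long.dropna(
        subset=[response] + sorted({p for t in predictors for p in t.split(":")})
    )
    X = build_design(use, predictors)
    _check_rank(X)
    y = pd.to_numeric(use[response]).to_numpy(dtype=float)
    groups = use[group].to_numpy()

    # column scaling for numerical conditioning (sta spans 0..8100); the
    # coefficient df is scale-invariant and estimates are unscaled below
    scales = np.maximum(np.abs(X.to_numpy()).max(axis=0), 1e-12)
    Xs = X / scales

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, Xs, groups=groups)
        fit = model.fit(reml=reml)
    s2b = float(np.asarray(fit.cov_re)[0, 0])
    s2e = float(fit.scale)
    if s2b <= 1e-3 * s2e:  # singular-fit threshold, as lme4 would flag it
        warnings.warn("between-subject variance estimated at the 0 boundary",
                      stacklevel=2)
        s2b = 0.0

    dfs = satterthwaite_df(Xs.to_numpy(), y, groups, s2b, s2e)
    est = np.asarray(fit.fe_params) / scales
    bse = np.asarray(fit.bse_fe) / scales
    tvals = est / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dfs)
    terms = pd.DataFrame(
        {"term": X.columns, "estimate": est, "se": bse, "df": dfs,
         "t": tvals, "p": pvals}
    )
    k_par = X.shape[1] + 2  # fixed effects + (sigma_b^2, sigma_e^2)
    stats_ = {
        "aic": float(-2.0 * fit.llf + 2.0 * k_par),
        "loglik": float(fit.llf),
        "reml": bool(reml),
        "random_intercept_variance": s2b,
        "residual_variance": s2e,
        "n": int(len(y)),
        "n_groups": int(pd.unique(groups).size),
    }
    return RegressionResult(terms, stats_)


# ---------------------------------------------------------------------------
# Stepwise AIC selection with collinearity screen
# ---------------------------------------------------------------------------

def stepwise_aic(
    data: pd.DataFrame,
    response: str,
    candidates: list[str],
    *,
    family: str = "ols",
    group: str = "subject",
    screened_pairs: list[tuple[str, str]] | None = None,
) -> tuple[RegressionResult, pd.DataFrame]:
    """Backward elimination by AIC from the full candidate model.

    At each step the term whose deletion lowers AIC the most is removed;
    interaction terms are removed before the main effects they contain.
    Mixed-family AICs are compared on ML fits (the final model is refit with
    REML). ``screened_pairs`` (from the |r| > .75 collinearity screen) may
    not both appear among the candidates.

    Returns the selected model and a trace table of each elimination step.
    """
    if not candidates:
        raise ValueError("candidate set must be nonempty")
    for a, b in screened_pairs or []:
        both = {a, b} <= {p for t in candidates for p in t.split(":")}
        if both:
            raise ValueError(
                f"factors {a!r} and {b!r} are collinear (|r| > .75); drop one "
                "before stepwise selection"
            )

    def fit_terms(terms):
        if not terms:
            terms = []
        if family == "ols":
            return ols(data, response, terms) if terms else _intercept_only(data, response)
        if family == "mixed":
            return mixed_model(data, response, terms or [], group=group, reml=False)
        raise ValueError(f"unknown family {family!r}")

    current = list(candidates)
    result = fit_terms(current)
    trace_rows = [{"step": 0, "dropped": "", "aic": result.model_stats["aic"],
                   "terms": "+".join(current)}]
    step = 0
    while current:
        droppable = [
            t for t in current
            if not any(":" in o and t in o.split(":") for o in current if o != t)
        ]
        options = []
        for t in droppable:
            reduced = [c for c in current if c != t]
            options.append((fit_terms(reduced).model_stats["aic"], t, reduced))
        options.sort(key=lambda o: (o[0], o[1]))
        best_aic, dropped, reduced = options[0]
        if best_aic >= result.model_stats["aic"] - 1e-9:
            break
        step += 1
        current = reduced
        result = fit_terms(current)
        trace_rows.append({"step": step, "dropped": dropped, "aic": best_aic,
                           "terms": "+".join(current) or "1"})
    if family == "mixed":
        result = mixed_model(data, response, current, group=group, reml=True)
    elif not current:
        result = _intercept_only(data, response)
    else:
        result = ols(data, response, current)
    return result, pd.DataFrame(trace_rows)


def _intercept_only(data: pd.DataFrame, response: str) -> RegressionResult:
    y = pd.to_numeric(data[response]).dropna().to_numpy(dtype=float)
    X = pd.DataFrame({"Intercept": np.ones(len(y))})
    fit = sm.OLS(y, X).fit()
    terms = pd.DataFrame(
        {"term": ["Intercept"], "estimate": fit.params.to_numpy(),
         "se": fit.bse.to_numpy(), "df": int(fit.df_resid),
         "t": fit.tvalues.to_numpy(), "p": fit.pvalues.to_numpy()}
    )
    return RegressionResult(terms, {"aic": float(fit.aic), "adjusted_r2": 0.0,
                                    "f_statistic": np.nan,
                                    "f_df": (0, int(fit.df_resid)),
                                    "n": int(fit.nobs)})


# ---------------------------------------------------------------------------
# Chi-square, power, correlation
# ---------------------------------------------------------------------------

def chi_square_2x2(table) -> ContingencyTest:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)) or np.any(t < 0):
            raise ValueError("counts must be nonnegative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a margin of the table is zero")
    statistic, p, df, _ = stats.chi2_contingency(t, correction=False)
    return ContingencyTest(t, float(statistic), int(df), float(p))


def power_simulation(
    p1: float,
    n1: int,
    p2: float,
    n2: int,
    alpha: float = 0.05,
    n_sims: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo power of the uncorrected 2x2 chi-square test.

    Each replicate draws group successes ``k1 ~ Binomial(n1, p1)`` and
    ``k2 ~ Binomial(n2, p2)``, forms the 2x2 table, and rejects when the
    uncorrected Pearson statistic exceeds the chi-square(1) critical value at
    ``alpha``; replicates whose table has a zero margin count as
    non-rejections. Returns ``(power, mc_se)`` with
    ``mc_se = sqrt(power (1 - power) / n_sims)``.
    """
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    k1 = gen.binomial(n1, p1, size=n_sims)
    k2 = gen.binomial(n2, p2, size=n_sims)
    a, b, c, d = k1, n1 - k1, k2, n2 - k2
    num = (n1 + n2) * (a * d - b * c).astype(float) ** 2
    den = ((a + b) * (c + d) * (a + c) * (b + d)).astype(float)
    ok = den > 0
    chi = np.zeros(n_sims)
    chi[ok] = num[ok] / den[ok]
    crit = stats.chi2.isf(alpha, df=1)
    power = float(np.mean(ok & (chi > crit)))
    se = float(np.sqrt(power * (1.0 - power) / n_sims))
    return power, se


def pearson(x, y) -> PearsonResult:
    """Product-moment correlation with r^2; NaN when a series is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return PearsonResult(np.nan, np.nan, int(x.size))
    r = float(np.corrcoef(x, y)[0, 1])
    return PearsonResult(r, r * r, int(x.size))
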