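"""Negative-binomial GLMs/GLMMs, pseudo-R², AICc selection, collinearity screen.

The inference layer relates Hill-number diversity responses to environmental
predictors:

* NB2 GLMs (log link, dispersion θ jointly ML-estimated) for pairwise
  attribute relationships and latitudinal trends, with the Cragg–Uhler
  (Nagelkerke) pseudo-R² as the fit index;
* NB2 GLMMs with a Gaussian random intercept per region, the marginal
  likelihood integrated by adaptive Gauss–Hermite quadrature (15 nodes by
  default; 1 node = Laplace);
* AICc model selection over all main-effect subsets of the four
  environmental predictors, with the rule: drop candidates with
  ΔAICc >= 2 from the best; among the rest select the most complex;
* Nakagawa marginal/conditional R² for mixed models on the latent scale.

Diversity responses are real-valued effective numbers; the NB likelihood is
evaluated through its gamma-function continuous extension, so non-integer
responses are accepted (this matches the de-facto behaviour of standard
NB-GLM implementations).  A strict integer mode (round-half-even) is
available via ``round_response=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.special import gammaln, logsumexp

import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial as _SMNegBin
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "pearson_matrix",
    "flag_collinear",
    "ModelFit",
    "aicc",
    "fit_nb_glm",
    "fit_nb_glmm",
    "cragg_uhler_r2",
    "nakagawa_r2",
    "select_model",
    "SelectionResult",
    "design_matrix",
    "attribute_cross_glms",
    "latitude_glms",
    "significance_stars",
]

THETA_CAP = 1e8  # Poisson limit: dispersion capped here, flagged


# ---------------------------------------------------------------------------
# collinearity screen

def pearson_matrix(data, variables: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix over ``variables``.

    ``data`` may be an EnvTable or a DataFrame.  Constant columns are an
    error (their correlation is undefined).
    """
    df = data.to_frame() if hasattr(data, "to_frame") else pd.DataFrame(data)
    if variables is not None:
        df = df.loc[:, list(variables)]
    df = df.select_dtypes(include=[np.number])
    if len(df) < 3:
        raise ValueError("need at least 3 observations for correlations")
    sd = df.std(ddof=1)
    constant = list(sd.index[sd == 0])
    if constant:
        raise ValueError(f"constant variables have undefined correlation: {constant}")
    return df.corr(method="pearson")


def flag_collinear(corr: pd.DataFrame, threshold: float = 0.7) -> list[tuple]:
    """Variable pairs with |r| >= threshold, sorted by descending |r|.

    The screen is advisory: it reports, it never drops variables.
    """
    pairs = []
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = float(corr.loc[a, b])
            if abs(r) >= threshold:
                pairs.append((a, b, r))
    return sorted(pairs, key=lambda t: (-abs(t[2]), t[0], t[1]))


# ---------------------------------------------------------------------------
# model containers

def aicc(llf: float, k: int, n: int) -> float:
    """Akaike information criterion with small-sample correction,
    -2 lnL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for k={k}, n={n} (need k < n - 1)")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class ModelFit:
    """A fitted NB GLM or GLMM.

    ``k`` counts every ML-estimated parameter: the fixed-effect
    coefficients, the NB dispersion θ, and (for mixed models) the
    random-intercept SD σ_α.
    """

    formula: str
    params: pd.Series = field(repr=False)
    bse: pd.Series = field(repr=False)
    theta: float
    llf: float
    n: int
    k: int
    aicc: float
    converged: bool
    sigma_alpha: float | None = None
    boundary_sigma: bool = False
    theta_capped: bool = False
    fitted_mean: np.ndarray | None = field(default=None, repr=False)

    @property
    def is_mixed(self) -> bool:
        return self.sigma_alpha is not None

    @property
    def n_terms(self) -> int:
        """Number of fixed-effect slope terms (intercept excluded)."""
        return sum(1 for name in self.params.index if name != "const")

    def wald_p(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _as_design(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        df = X.copy()
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = ["const" if np.allclose(arr[:, j], arr[0, j]) and arr[0, j] == 1
                 else f"x{j}" for j in range(arr.shape[1])]
        df = pd.DataFrame(arr, columns=names)
    if "const" not in df.columns:
        raise ValueError("design matrix must contain an intercept column 'const'")
    return df.astype(float)


def _prep_response(y, round_response: bool) -> np.ndarray:
    arr = np.asarray(y, dtype=float)
    if np.any(arr < 0):
        raise ValueError("NB responses must be non-negative")
    if round_response:
        arr = np.rint(arr)
    elif not np.allclose(arr, np.rint(arr)):
        warnings.warn(
            "non-integer responses: NB likelihood evaluated via its "
            "continuous gamma-function extension"
        )
    return arr


def design_matrix(
    table: pd.DataFrame, terms: Sequence[str], standardize: bool = True
) -> pd.DataFrame:
    """Build an intercept + main-effects design matrix.

    Predictors are z-standardised by default (mean 0, SD 1) which
    stabilises the optimisation; the transform is affine so model fit,
    likelihood and selection are unchanged.
    """
    X = pd.DataFrame({"const": np.ones(len(table))}, index=table.index)
    for t in terms:
        col = pd.to_numeric(table[t]).to_numpy(dtype=float)
        if standardize:
            sd = col.std(ddof=1)
            if sd == 0:
                raise ValueError(f"constant predictor: {t}")
            col = (col - col.mean()) / sd
        X[t] = col
    return X


# ---------------------------------------------------------------------------
# NB GLM (statsmodels-backed)

def fit_nb_glm(
    y, X, formula: str | None = None, round_response: bool = False
) -> ModelFit:
    """NB2 GLM with log link; β and θ jointly ML-estimated.

    Thin wrapper over statsmodels' discrete NegativeBinomial (which
    parametrises overdispersion as alpha = 1/θ).  Near-equidispersed data
    push alpha to the boundary; θ is then capped at 1e8 and flagged.
    """
    yv = _prep_response(y, round_response)
    Xfull = _as_design(X)
    # all-zero columns carry no information and make the observed
    # information singular; fit without them, report their slope as 0
    zero_cols = [c for c in Xfull.columns if (Xfull[c] == 0).all()]
    Xd = Xfull.drop(columns=zero_cols)
    n, p = Xd.shape
    if n <= p + 1:
        raise ValueError(f"too few observations (n={n}) for {p} coefficients")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = _SMNegBin(yv, Xd.to_numpy(), loglike_method="nb2")
        try:
            res = model.fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            res = model.fit(disp=0, method="nm", maxiter=2000)
            converged = bool(res.mle_retvals.get("converged", True))
        if not converged:
            res = model.fit(disp=0, method="nm", maxiter=5000,
                            start_params=res.params)
            converged = bool(res.mle_retvals.get("converged", True))
    beta = pd.Series(res.params[:p], index=Xd.columns)
    alpha = float(res.params[p])
    theta_capped = False
    if alpha <= 1.0 / THETA_CAP:
        theta = THETA_CAP
        theta_capped = True
    else:
        theta = 1.0 / alpha
    llf = float(res.llf)
    try:
        bse = pd.Series(res.bse[:p], index=Xd.columns)
    except Exception:  # singular observed information (e.g. boundary alpha)
        bse = pd.Series(np.full(p, np.nan), index=Xd.columns)
    if zero_cols:
        beta = beta.reindex(Xfull.columns, fill_value=0.0)
        bse = bse.reindex(Xfull.columns)
    k = p + 1  # θ is estimated
    return ModelFit(
        formula=formula or _default_formula(Xfull.columns),
        params=beta, bse=bse, theta=theta, llf=llf, n=n, k=k,
        aicc=aicc(llf, k, n), converged=converged,
        theta_capped=theta_capped,
        fitted_mean=np.exp(Xfull.to_numpy() @ beta.to_numpy()),
    )


def _default_formula(columns) -> str:
    terms = [c for c in columns if c != "const"]
    return "y ~ " + (" + ".join(terms) if terms else "1")


# ---------------------------------------------------------------------------
# NB log-density (continuous extension) and the GLMM marginal likelihood

def _nb_logpmf(y: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    return (gammaln(y + theta) - gammaln(theta) - gammaln(y + 1.0)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu)))


def _group_loglik(y, eta, theta, sigma, nodes, logw):
    """log integral over one group's random intercept (adaptive GH)."""
    # mode of the integrand via Newton on u
    u = 0.0
    for _ in range(100):
        mu = np.exp(eta + u)
        grad = float(np.sum(y - (y + theta) * mu / (theta + mu))) - u / sigma ** 2
        hess = -float(np.sum((y + theta) * theta * mu / (theta + mu) ** 2)) \
            - 1.0 / sigma ** 2
        step = grad / hess
        u -= step
        if abs(step) < 1e-12:
            break
    mu = np.exp(eta + u)
    hess = -float(np.sum((y + theta) * theta * mu / (theta + mu) ** 2)) \
        - 1.0 / sigma ** 2
    s = 1.0 / np.sqrt(-hess)
    z = u + np.sqrt(2.0) * s * nodes
    # integrand g(z) = sum_i ln NB(y_i | exp(eta_i + z)) + ln phi(z; 0, sigma)
    gz = np.array([
        float(np.sum(_nb_logpmf(y, np.exp(eta + zk), theta))) for zk in z
    ])
    gz += -0.5 * z ** 2 / sigma ** 2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
    return float(logsumexp(logw + nodes ** 2 + gz) + np.log(np.sqrt(2.0) * s))


def _glmm_negloglik(pars, y, Xarr, group_idx, nodes, logw):
    p = Xarr.shape[1]
    beta = pars[:p]
    theta = np.exp(pars[p])
    sigma = np.exp(pars[p + 1])
    eta = Xarr @ beta
    total = 0.0
    for idx in group_idx:
        total += _group_loglik(y[idx], eta[idx], theta, sigma, nodes, logw)
    return -total


def fit_nb_glmm(
    y, X, group, n_quad: int = 15, formula: str | None = None,
    round_response: bool = False,
) -> ModelFit:
    """NB2 GLMM with a single Gaussian random intercept.

    The marginal likelihood integrates the group intercept with adaptive
    Gauss–Hermite quadrature (default 15 nodes; ``n_quad=1`` gives the
    Laplace approximation).  β, log θ and log σ_α are optimised jointly
    (L-BFGS-B); starting values come from the fixed-effects NB GLM.

    A fitted σ_α below 1e-4 is reported as 0 with ``boundary_sigma=True``.
    """
    yv = _prep_response(y, round_response)
    Xd = _as_design(X)
    groups = pd.Series(list(group)).astype(str)
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    if len(groups) != len(yv):
        raise ValueError("group labels do not align with responses")
    group_idx = [np.flatnonzero((groups == g).to_numpy())
                 for g in sorted(groups.unique())]
    nodes, w = np.polynomial.hermite.hermgauss(n_quad)
    logw = np.log(w)
    Xarr = Xd.to_numpy()
    n, p = Xarr.shape

    glm = fit_nb_glm(yv, Xd, round_response=False)
    x0 = np.concatenate([
        glm.params.to_numpy(),
        [np.log(min(glm.theta, 1e6))],
        [np.log(0.2)],
    ])
    bounds = [(None, None)] * p + [(-10.0, np.log(THETA_CAP)), (-10.0, 3.0)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        opt = optimize.minimize(
            _glmm_negloglik, x0, args=(yv, Xarr, group_idx, nodes, logw),
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-8},
        )
        if not opt.success:
            # polish from the L-BFGS-B endpoint with a derivative-free pass
            opt2 = optimize.minimize(
                _glmm_negloglik, opt.x,
                args=(yv, Xarr, group_idx, nodes, logw),
                method="Nelder-Mead",
                options={"maxiter": 4000, "fatol": 1e-10, "xatol": 1e-8},
            )
            if opt2.fun <= opt.fun:
                opt = opt2
    pars = opt.x
    beta = pd.Series(pars[:p], index=Xd.columns)
    theta = float(np.exp(pars[p]))
    sigma = float(np.exp(pars[p + 1]))
    llf = float(-opt.fun)
    boundary = sigma < 1e-4
    theta_capped = theta >= THETA_CAP * 0.999
    # standard errors for beta from the observed information (numeric Hessian)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            H = approx_hess1(pars, _glmm_negloglik,
                             args=(yv, Xarr, group_idx, nodes, logw))
        cov = np.linalg.inv(H)
        bse = pd.Series(np.sqrt(np.clip(np.diag(cov)[:p], 0, np.inf)),
                        index=Xd.columns)
    except np.linalg.LinAlgError:
        bse = pd.Series(np.full(p, np.nan), index=Xd.columns)
    k = p + 2  # θ and σ_α are estimated
    terms = _default_formula(Xd.columns)
    return ModelFit(
        formula=formula or terms.replace("y ~ ", "y ~ (1|group) + ")
        .replace("~ (1|group) + 1", "~ (1|group)"),
        params=beta, bse=bse, theta=theta, llf=llf, n=n, k=k,
        aicc=aicc(llf, k, n), converged=bool(opt.success),
        sigma_alpha=0.0 if boundary else sigma,
        boundary_sigma=boundary, theta_capped=theta_capped,
        fitted_mean=np.exp(Xarr @ beta.to_numpy()),
    )


# ---------------------------------------------------------------------------
# fit indices

def cragg_uhler_r2(fit: ModelFit, null_fit: ModelFit) -> float:
    """Cragg–Uhler (Nagelkerke) pseudo-R²,
    [1 - (L0/L1)^(2/n)] / [1 - L0^(2/n)], clamped to [0, 1]."""
    if fit.n != null_fit.n:
        raise ValueError("fits compare different numbers of observations")
    n = fit.n
    num = 1.0 - np.exp(2.0 / n * (null_fit.llf - fit.llf))
    den = 1.0 - np.exp(2.0 / n * null_fit.llf)
    if den <= 0:
        return 1.0 if num > 0 else 0.0
    return float(min(1.0, max(0.0, num / den)))


def nakagawa_r2(
    fit: ModelFit, X, variant: str = "lognormal"
) -> tuple[float, float]:
    """Marginal and conditional R² for an NB GLMM on the latent scale.

    R²m = σ²_f / (σ²_f + σ²_α + σ²_d) (fixed effects only),
    R²c = (σ²_f + σ²_α) / (same) (fixed + random), where σ²_f is the
    variance of the fixed-effect linear predictor and σ²_d the
    distribution-specific variance of the NB log link: the lognormal
    approximation ln(1 + 1/μ̄ + 1/θ) with μ̄ = exp(β₀ + σ²_α/2)
    (``variant="trigamma"`` uses ψ₁((1/μ̄ + 1/θ)⁻¹) instead).
    """
    if not fit.is_mixed:
        raise ValueError("nakagawa_r2 applies to mixed-model fits")
    if not fit.converged:
        raise ValueError("fit did not converge")
    Xd = _as_design(X)
    eta = Xd.to_numpy() @ fit.params.reindex(Xd.columns).to_numpy()
    var_f = float(np.var(eta, ddof=1)) if len(eta) > 1 else 0.0
    var_a = float(fit.sigma_alpha) ** 2
    beta0 = float(fit.params.get("const", 0.0))
    mu_bar = float(np.exp(beta0 + var_a / 2.0))
    if variant == "lognormal":
        var_d = float(np.log1p(1.0 / mu_bar + 1.0 / fit.theta))
    elif variant == "trigamma":
        var_d = float(special.polygamma(1, 1.0 / (1.0 / mu_bar + 1.0 / fit.theta)))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    denom = var_f + var_a + var_d
    if denom == 0:
        return 0.0, 0.0
    return var_f / denom, (var_f + var_a) / denom


# ---------------------------------------------------------------------------
# model selection

@dataclass(frozen=True)
class SelectionResult:
    """AICc ladder and the selected model.

    Candidates are ordered by AICc; those with ΔAICc >= 2 from the best
    are rejected; among the remainder the fit with the most fixed-effect
    terms is selected (ties broken by lower AICc).
    """

    candidates: tuple
    delta_aicc: tuple
    selected: ModelFit

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fit, d in zip(self.candidates, self.delta_aicc):
            rows.append({
                "formula": fit.formula, "k": fit.k, "n_terms": fit.n_terms,
                "AICc": fit.aicc, "delta_AICc": d, "llf": fit.llf,
                "selected": fit is self.selected,
            })
        return pd.DataFrame(rows)


def select_model(candidates: Sequence[ModelFit]) -> SelectionResult:
    fits = [f for f in candidates if f.converged]
    if not fits:
        raise ValueError("no converged candidate models")
    fits = sorted(fits, key=lambda f: (f.aicc, -f.n_terms, f.formula))
    best = fits[0].aicc
    deltas = [f.aicc - best for f in fits]
    in_window = [f for f, d in zip(fits, deltas) if d < 2.0]
    selected = sorted(in_window, key=lambda f: (-f.n_terms, f.aicc, f.formula))[0]
    return SelectionResult(tuple(fits), tuple(deltas), selected)


# ---------------------------------------------------------------------------
# profile-level analyses

def _wide_profile(profiles: pd.DataFrame) -> pd.DataFrame:
    return profiles.pivot_table(index="plot", columns=["attribute", "q"],
                                values="value")


_PAIRS = (("TD", "FD"), ("TD", "PD"), ("FD", "PD"))


def _slope_p(fit: ModelFit, null: ModelFit, term: str) -> float:
    """Wald p-value for a slope; falls back to the likelihood-ratio test
    when the observed information is singular (e.g. dispersion at its
    boundary leaves the Wald SE undefined)."""
    p = float(fit.wald_p()[term])
    if np.isfinite(p):
        return p
    lr = max(0.0, 2.0 * (fit.llf - null.llf))
    return float(stats.chi2.sf(lr, df=1))


def attribute_cross_glms(
    profiles: pd.DataFrame, env=None, min_region_plots: int = 5,
) -> pd.DataFrame:
    """Pairwise NB GLMs between diversity attributes per order q.

    For each ordered pair (TD~FD, TD~PD, FD~PD) and each q, the first
    attribute is the response and the second the (z-scored) predictor;
    the table reports the Cragg–Uhler pseudo-R² and the Wald significance
    of the slope, overall and per region (regions with fewer than
    ``min_region_plots`` plots are skipped).
    """
    wide = _wide_profile(profiles)
    q_values = sorted({q for (_, q) in wide.columns})
    scopes = [("all", wide.index)]
    if env is not None:
        regions = env.to_frame()["region"]
        for reg in sorted(regions.unique()):
            plots = regions.index[regions == reg]
            plots = [p for p in plots if p in wide.index]
            if len(plots) >= min_region_plots:
                scopes.append((reg, pd.Index(plots)))
    rows = []
    for scope, plots in scopes:
        sub = wide.loc[plots]
        for q in q_values:
            for resp_attr, pred_attr in _PAIRS:
                if (resp_attr, q) not in sub.columns or \
                        (pred_attr, q) not in sub.columns:
                    continue
                pair_df = sub[[(resp_attr, q), (pred_attr, q)]].dropna()
                if len(pair_df) < 5:
                    rows.append({"scope": scope, "q": q,
                                 "pair": f"{resp_attr}~{pred_attr}",
                                 "n": len(pair_df), "pR2": np.nan,
                                 "p_slope": np.nan, "stars": "",
                                 "note": "insufficient data"})
                    continue
                yv = pair_df[(resp_attr, q)].to_numpy()
                x = pair_df[(pred_attr, q)].to_numpy()
                x = (x - x.mean()) / (x.std(ddof=1) if x.std(ddof=1) > 0 else 1.0)
                X = pd.DataFrame({"const": np.ones_like(x), "pred": x})
                X0 = pd.DataFrame({"const": np.ones_like(x)})
                fit = fit_nb_glm(yv, X)
                null = fit_nb_glm(yv, X0)
                pr2 = cragg_uhler_r2(fit, null)
                p_slope = _slope_p(fit, null, "pred")
                rows.append({"scope": scope, "q": q,
                             "pair": f"{resp_attr}~{pred_attr}",
                             "n": len(pair_df), "pR2": pr2,
                             "p_slope": p_slope,
                             "stars": significance_stars(p_slope), "note": ""})
    return pd.DataFrame(rows)


def latitude_glms(profiles: pd.DataFrame, env) -> pd.DataFrame:
    """NB GLM of each attribute x q response on signed latitude.

    A positive slope means diversity increases toward the Equator (the
    study plots sit at negative latitudes).
    """
    wide = _wide_profile(profiles)
    lat = env.to_frame()["latitude"].reindex(wide.index)
    rows = []
    for attr, q in wide.columns:
        pair_df = pd.DataFrame({
            "y": wide[(attr, q)], "lat": lat,
        }).dropna()
        yv = pair_df["y"].to_numpy()
        x = pair_df["lat"].to_numpy()
        xz = (x - x.mean()) / x.std(ddof=1)
        X = pd.DataFrame({"const": np.ones_like(xz), "latitude": xz})
        X0 = pd.DataFrame({"const": np.ones_like(xz)})
        fit = fit_nb_glm(yv, X)
        null = fit_nb_glm(yv, X0)
        p_slope = _slope_p(fit, null, "latitude")
        # slope back on the raw degree scale for interpretability
        slope_raw = float(fit.params["latitude"] / x.std(ddof=1))
        rows.append({
            "attribute": attr, "q": q, "n": len(pair_df),
            "slope_z": float(fit.params["latitude"]),
            "slope_per_degree": slope_raw,
            "pR2": cragg_uhler_r2(fit, null),
            "p_slope": p_slope, "stars": significance_stars(p_slope),
        })
    return pd.DataFrame(rows)
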