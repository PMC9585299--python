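"""NB GLM/GLMM fitting, pseudo-R², AICc and the model-selection rule."""

import numpy as np
import pandas as pd
import pytest

import statsmodels.api as sm

from divgrad import (
    ModelFit,
    aicc,
    attribute_cross_glms,
    cragg_uhler_r2,
    design_matrix,
    fit_nb_glm,
    fit_nb_glmm,
    flag_collinear,
    nakagawa_r2,
    pearson_matrix,
    select_model,
    significance_stars,
)


def _const_X(n):
    return pd.DataFrame({"const": np.ones(n)})


def _mk_fit(aicc_value, n_terms, formula, converged=True):
    names = ["const"] + [f"t{i}" for i in range(n_terms)]
    s = pd.Series(np.zeros(len(names)), index=names)
    return ModelFit(formula=formula, params=s, bse=s + 1.0, theta=2.0,
                    llf=-100.0, n=50, k=n_terms + 2, aicc=aicc_value,
                    converged=converged)


# ---------------------------------------------------------------------------
# correlation screen

def test_pearson_exact_cases():
    x = np.arange(10.0)
    df = pd.DataFrame({"x": x, "y": 2 * x + 3, "z": -x})
    corr = pearson_matrix(df)
    assert corr.loc["x", "y"] == pytest.approx(1.0)
    assert corr.loc["x", "z"] == pytest.approx(-1.0)


def test_pearson_orthogonal_zero():
    x = np.array([1.0, -1.0, 1.0, -1.0])
    y = np.array([1.0, 1.0, -1.0, -1.0])
    corr = pearson_matrix(pd.DataFrame({"x": x, "y": y}))
    assert corr.loc["x", "y"] == pytest.approx(0.0, abs=1e-12)


def test_pearson_constant_column_error():
    df = pd.DataFrame({"x": [1.0, 2, 3], "c": [5.0, 5, 5]})
    with pytest.raises(ValueError, match="c"):
        pearson_matrix(df)


def test_flag_collinear():
    corr = pd.DataFrame(
        [[1.0, 0.95, 0.1], [0.95, 1.0, -0.2], [0.1, -0.2, 1.0]],
        index=list("abc"), columns=list("abc"))
    assert flag_collinear(corr, 0.7) == [("a", "b", 0.95)]
    eye = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
    assert flag_collinear(eye, 0.7) == []
    assert flag_collinear(corr, 1.0) == []


# ---------------------------------------------------------------------------
# AICc

def test_aicc_formula_spot_check():
    # AIC = 100 with k = 5, n = 50 -> 100 + 2*5*6/44
    llf = -(100 - 2 * 5) / 2
    assert aicc(llf, 5, 50) == pytest.approx(101.363636, abs=1e-6)


def test_aicc_exceeds_aic_and_converges():
    llf, k = -123.4, 4
    aic = -2 * llf + 2 * k
    assert aicc(llf, k, 30) > aic
    assert aicc(llf, k, 10 ** 6) == pytest.approx(aic, abs=1e-4)


def test_aicc_requires_enough_observations():
    with pytest.raises(ValueError):
        aicc(-10.0, 5, 6)


# ---------------------------------------------------------------------------
# NB GLM

def test_intercept_only_recovers_mean(rng):
    y = rng.negative_binomial(3, 0.4, size=200)
    fit = fit_nb_glm(y, _const_X(200))
    assert np.exp(fit.params["const"]) == pytest.approx(y.mean(), abs=1e-6)


def test_glm_recovery_moderate_n(rng):
    n = 800
    x = rng.normal(size=n)
    mu = np.exp(1.0 + 0.5 * x)
    y = rng.negative_binomial(2, 2 / (2 + mu))
    fit = fit_nb_glm(y, pd.DataFrame({"const": np.ones(n), "x": x}))
    assert fit.converged
    assert fit.params["const"] == pytest.approx(1.0, abs=0.15)
    assert fit.params["x"] == pytest.approx(0.5, abs=0.15)
    assert fit.theta == pytest.approx(2.0, abs=0.6)


def test_poisson_limit_matches_poisson_glm(rng):
    n = 800
    x = rng.normal(size=n)
    y = rng.poisson(np.exp(1.0 + 0.5 * x))
    X = pd.DataFrame({"const": np.ones(n), "x": x})
    fit = fit_nb_glm(y, X)
    pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    assert np.abs(fit.params.to_numpy() - pois.params.to_numpy()).max() < 1e-3
    assert fit.theta > 100  # near-equidispersed


def test_non_integer_response_warns(rng):
    y = rng.negative_binomial(3, 0.4, size=100) + 0.37
    with pytest.warns(UserWarning, match="continuous"):
        fit_nb_glm(y, _const_X(100))


# ---------------------------------------------------------------------------
# Cragg-Uhler pseudo-R2

def test_cragg_uhler_cases():
    f = _mk_fit(0, 1, "m")
    base = dict(params=f.params, bse=f.bse, theta=2.0, n=10, k=2,
                aicc=0.0, converged=True)
    null = ModelFit(formula="null", llf=-20.0, **base)
    full = ModelFit(formula="full", llf=-15.0, **base)
    same = ModelFit(formula="same", llf=-20.0, **base)
    sat = ModelFit(formula="sat", llf=0.0, **base)
    # direct evaluation of [1 - (L0/L1)^(2/n)] / [1 - L0^(2/n)]
    assert cragg_uhler_r2(full, null) == pytest.approx(0.6439143, abs=1e-6)
    assert cragg_uhler_r2(same, null) == 0.0
    assert cragg_uhler_r2(sat, null) == pytest.approx(1.0)


def test_cragg_uhler_mismatched_n():
    a = _mk_fit(0, 1, "a")
    b = ModelFit(formula="b", params=a.params, bse=a.bse, theta=2.0,
                 llf=-10.0, n=40, k=2, aicc=0.0, converged=True)
    with pytest.raises(ValueError):
        cragg_uhler_r2(a, b)


def test_cragg_uhler_invariant_to_zero_column(rng):
    y = rng.negative_binomial(3, 0.5, size=80)
    x = rng.normal(size=80)
    X = pd.DataFrame({"const": np.ones(80), "x": x})
    Xz = X.assign(zero=0.0 * x)
    null = fit_nb_glm(y, _const_X(80))
    r1 = cragg_uhler_r2(fit_nb_glm(y, X), null)
    r2 = cragg_uhler_r2(fit_nb_glm(y, Xz), null)
    assert r1 == pytest.approx(r2, abs=1e-6)


# ---------------------------------------------------------------------------
# NB GLMM

def _sim_glmm(seed, sigma=0.3, beta=(2.0, -0.4), theta=5.0):
    r = np.random.default_rng(seed)
    g = np.repeat(np.arange(5), 10)
    x = r.normal(size=50)
    u = r.normal(scale=sigma, size=5) if sigma > 0 else np.zeros(5)
    mu = np.exp(beta[0] + beta[1] * x + u[g])
    y = r.negative_binomial(theta, theta / (theta + mu))
    return y, pd.DataFrame({"const": np.ones(50), "x": x}), g


def test_glmm_requires_two_groups(rng):
    y, X, _ = _sim_glmm(0)
    with pytest.raises(ValueError):
        fit_nb_glmm(y, X, np.zeros(50))


def test_glmm_reduces_to_glm_when_no_group_effect():
    """Data without a group effect: the variance component collapses to
    the boundary and the marginal likelihood matches the plain GLM."""
    y, X, g = _sim_glmm(3, sigma=0.0)
    glm = fit_nb_glm(y, X)
    glmm = fit_nb_glmm(y, X, g)
    assert glmm.sigma_alpha < 0.05
    assert abs(glmm.llf - glm.llf) < 0.05
    assert glmm.boundary_sigma


def test_glmm_nests_glm(rng):
    """The GLMM likelihood can never fall below the GLM's (nesting)."""
    for seed in (1, 6, 8):
        y, X, g = _sim_glmm(seed)
        assert fit_nb_glmm(y, X, g).llf >= fit_nb_glm(y, X).llf - 1e-6


def test_quadrature_refinement():
    y, X, g = _sim_glmm(7)
    f15 = fit_nb_glmm(y, X, g, n_quad=15)
    f31 = fit_nb_glmm(y, X, g, n_quad=31)
    assert abs(f15.llf - f31.llf) < 1e-4


def test_glmm_slope_recovery_short():
    est = [fit_nb_glmm(*_sim_glmm(1000 + i)).params["x"] for i in range(25)]
    assert np.mean(est) == pytest.approx(-0.4, abs=0.12)


# ---------------------------------------------------------------------------
# Nakagawa R2

def _fixed_glmm_fit(beta, sigma, theta, columns):
    s = pd.Series(beta, index=columns)
    return ModelFit(formula="m", params=s, bse=s * 0 + 1, theta=theta,
                    llf=-10.0, n=50, k=len(beta) + 2, aicc=0.0,
                    converged=True, sigma_alpha=sigma)


def test_nakagawa_hand_formula():
    X = pd.DataFrame({"const": np.ones(4), "x": [-1.5, -0.5, 0.5, 1.5]})
    fit = _fixed_glmm_fit([2.0, 0.3], sigma=0.4, theta=5.0,
                          columns=["const", "x"])
    rm, rc = nakagawa_r2(fit, X)
    # hand evaluation: var_f = 0.3^2 * var([-1.5..1.5], ddof=1)
    var_f = 0.09 * np.var([-1.5, -0.5, 0.5, 1.5], ddof=1)
    var_a = 0.16
    mu_bar = np.exp(2.0 + 0.16 / 2)
    var_d = np.log(1 + 1 / mu_bar + 1 / 5.0)
    assert rm == pytest.approx(var_f / (var_f + var_a + var_d), abs=1e-10)
    assert rc == pytest.approx((var_f + var_a) / (var_f + var_a + var_d),
                               abs=1e-10)
    assert 0 <= rm <= rc <= 1


def test_nakagawa_intercept_only_zero():
    X = _const_X(10)
    fit = _fixed_glmm_fit([1.0], sigma=0.0, theta=3.0, columns=["const"])
    assert nakagawa_r2(fit, X) == (0.0, 0.0)


def test_nakagawa_marginal_equals_conditional_without_random_effect():
    X = pd.DataFrame({"const": np.ones(6), "x": np.arange(6.0)})
    fit = _fixed_glmm_fit([1.0, 0.2], sigma=0.0, theta=3.0,
                          columns=["const", "x"])
    rm, rc = nakagawa_r2(fit, X)
    assert rm == pytest.approx(rc)
    rm_t, rc_t = nakagawa_r2(fit, X, variant="trigamma")
    assert rm_t == pytest.approx(rc_t)


# ---------------------------------------------------------------------------
# model selection

def test_selection_prefers_most_complex_within_two():
    fits = [_mk_fit(430.0, 2, "two"), _mk_fit(431.5, 4, "four"),
            _mk_fit(434.0, 3, "three")]
    assert select_model(fits).selected.formula == "four"


def test_selection_rejects_delta_over_two():
    fits = [_mk_fit(430.0, 2, "two"), _mk_fit(432.1, 4, "four")]
    assert select_model(fits).selected.formula == "two"


def test_selection_single_candidate_and_order_invariance(rng):
    only = _mk_fit(100.0, 1, "solo")
    assert select_model([only]).selected is only
    fits = [_mk_fit(430.0, 2, "a"), _mk_fit(431.5, 4, "b"),
            _mk_fit(430.9, 3, "c"), _mk_fit(435.0, 1, "d")]
    chosen = {select_model(list(rng.permutation(fits))).selected.formula
              for _ in range(10)}
    assert chosen == {"b"}


def test_selection_requires_converged():
    with pytest.raises(ValueError):
        select_model([_mk_fit(1.0, 1, "x", converged=False)])


def test_selection_complexity_preference_under_null(rng):
    """With no true effects, record how often the most complex model is
    still selected (the rule prefers complexity inside the AICc window);
    logged as a property of the rule, not bounded a priori."""
    import itertools as it
    picked_full = 0
    n_sims = 40
    for s in range(n_sims):
        r = np.random.default_rng(5000 + s)
        Z = r.normal(size=(50, 4))
        y = r.negative_binomial(5, 5 / (5 + np.exp(2.0 + 0 * Z[:, 0])))
        fits = []
        for k in range(5):
            for combo in it.combinations(range(4), k):
                X = pd.DataFrame({"const": np.ones(50)})
                for j in combo:
                    X[f"z{j}"] = Z[:, j]
                fits.append(fit_nb_glm(y, X, formula=f"terms={combo}"))
        if select_model(fits).selected.n_terms == 4:
            picked_full += 1
    frac = picked_full / n_sims
    print(f"null-data full-model selection fraction: {frac:.2f}")
    assert 0.0 <= frac <= 1.0


# ---------------------------------------------------------------------------
# cross-attribute GLMs

def test_cross_glms_basic(rng):
    plots = [f"p{i}" for i in range(30)]
    td = rng.negative_binomial(10, 0.1, size=30) + 5
    rows = []
    for plot, v in zip(plots, td):
        rows += [
            {"plot": plot, "attribute": "TD", "q": 0.0, "value": float(v)},
            {"plot": plot, "attribute": "FD", "q": 0.0, "value": float(v)},
            {"plot": plot, "attribute": "PD", "q": 0.0,
             "value": float(rng.permutation(td)[0])},
        ]
    prof = pd.DataFrame(rows)
    out = attribute_cross_glms(prof)
    td_fd = out[(out.pair == "TD~FD")].iloc[0]
    # response identical to predictor: near the upper boundary, never NaN
    assert td_fd.pR2 > 0.8
    assert td_fd.p_slope < 0.001
    assert np.isfinite(out.pR2).all()


def test_cross_glms_identical_regions_match(small_cm):
    from divgrad import EnvTable
    rng = np.random.default_rng(0)
    plots = [f"p{i}" for i in range(10)]
    vals = rng.negative_binomial(10, 0.2, size=10) + 3.0
    rows = []
    for i, plot in enumerate(plots):
        for attr in ("TD", "FD"):
            rows.append({"plot": plot, "attribute": attr, "q": 0.0,
                         "value": vals[i] + (0.5 if attr == "FD" else 0)})
    prof = pd.DataFrame(rows)
    prof2 = prof.copy()
    prof2["plot"] = prof2["plot"] + "_b"
    both = pd.concat([prof, prof2], ignore_index=True)
    env = EnvTable(pd.DataFrame({
        "region": ["r1"] * 10 + ["r2"] * 10,
        "latitude": -5.0, "temp_seasonality": 5.0, "annual_precip": 2000.0,
        "soil_pH": 4.0, "bulk_density": 0.8,
    }, index=plots + [p + "_b" for p in plots]))
    out = attribute_cross_glms(both, env)
    r1 = out[out.scope == "r1"].reset_index(drop=True)
    r2 = out[out.scope == "r2"].reset_index(drop=True)
    assert np.allclose(r1.pR2, r2.pR2, atol=1e-8)


def test_permuted_predictor_mostly_nonsignificant(rng):
    """A randomly permuted predictor should explain almost nothing."""
    n_sig = 0
    n_perm = 40
    base = rng.negative_binomial(10, 0.15, size=50) + 2.0
    for _ in range(n_perm):
        perm = rng.permutation(base)
        rows = []
        for i in range(50):
            rows += [{"plot": f"p{i}", "attribute": "TD", "q": 0.0,
                      "value": base[i]},
                     {"plot": f"p{i}", "attribute": "FD", "q": 0.0,
                      "value": perm[i]}]
        out = attribute_cross_glms(pd.DataFrame(rows))
        row = out[out.pair == "TD~FD"].iloc[0]
        if row.p_slope < 0.05:
            n_sig += 1
    assert n_sig <= 0.1 * n_perm + 2


def test_significance_stars():
    assert significance_stars(0.0001) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.2) == ""
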