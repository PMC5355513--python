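"""Spearman screening, quartile classes, logistic fit and standardization."""

import math

import numpy as np
import pandas as pd
import pytest

from guildscape.classify import (GuildHabitatModel, classification_table,
                                 derive_classes, fit_logistic, nagelkerke_r2,
                                 select_metrics, spearman,
                                 standardize_coefficients)

from _naive import logistic_ml, spearman_rho


# --- spearman ---------------------------------------------------------------

def test_spearman_monotone_extremes(rng):
    x = np.sort(rng.normal(size=20))
    up = spearman(x, np.exp(x))
    down = spearman(x, -(x**3))
    assert up.rho == pytest.approx(1.0)
    assert down.rho == pytest.approx(-1.0)


def test_spearman_tied_sample_matches_rank_oracle(rng):
    x = rng.integers(0, 5, size=20).astype(float)
    y = rng.integers(0, 4, size=20).astype(float)
    res = spearman(x, y)
    assert res.rho == pytest.approx(spearman_rho(x, y), abs=1e-12)
    # t-approximate two-sided p
    t = res.rho * math.sqrt((20 - 2) / (1 - res.rho**2))
    from scipy import stats
    assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), 18), rel=1e-6)


def test_spearman_constant_vector_flagged():
    res = spearman(np.ones(10), np.arange(10.0))
    assert not res.defined


# --- metric selection -------------------------------------------------------

def make_metrics_table(rng, lop, signal_noise):
    cols = {}
    for name, noise in signal_noise.items():
        cols[name] = lop + rng.normal(0, noise, size=len(lop))
    return pd.DataFrame(cols)


def test_select_orders_by_absolute_rho(rng):
    lop = rng.normal(size=80)
    table = make_metrics_table(rng, lop, {"A": 0.3, "B": 1.5, "C": 6.0, "D": 30.0})
    got = select_metrics(lop, table, k=3, collinearity_cutoff=0.999)
    assert got == ["A", "B", "C"]


def test_select_skips_collinear_duplicate(rng):
    lop = rng.normal(size=60)
    table = make_metrics_table(rng, lop, {"A": 0.2, "C": 2.0, "D": 8.0})
    table["A_COPY"] = 2.0 * table["A"] + 1.0  # rank-identical with A
    got = select_metrics(lop, table, k=3)
    assert "A" in got and "A_COPY" not in got


def test_select_matches_exhaustive_oracle(rng):
    lop = rng.normal(size=50)
    table = make_metrics_table(
        rng, lop, {"M1": 0.5, "M2": 1.0, "M3": 2.0, "M4": 4.0, "M5": 8.0})
    got = select_metrics(lop, table, k=3, collinearity_cutoff=0.95)
    # oracle: rank all metrics by |rho|, greedy with the same cutoff
    rhos = {m: abs(spearman_rho(lop, table[m].to_numpy())) for m in table}
    order = sorted(table.columns, key=lambda m: (-rhos[m], m))
    chosen = []
    for m in order:
        if all(abs(spearman_rho(table[s].to_numpy(), table[m].to_numpy())) < 0.95
               for s in chosen):
            chosen.append(m)
        if len(chosen) == 3:
            break
    assert got == chosen


def test_select_insufficient_survivors_errors(rng):
    lop = rng.normal(size=40)
    table = make_metrics_table(rng, lop, {"A": 0.3})
    table["B"] = table["A"] * 3.0
    table["C"] = -table["A"]
    with pytest.raises(ValueError, match="survive"):
        select_metrics(lop, table, k=3)


def test_selection_invariant_to_monotone_transform(rng):
    lop = rng.normal(size=70)
    table = make_metrics_table(rng, lop, {"A": 0.5, "B": 2.0, "C": 5.0, "D": 9.0})
    transformed = table.copy()
    transformed["B"] = np.exp(table["B"] / 3.0)
    transformed["D"] = table["D"] ** 3
    assert select_metrics(lop, table, 3) == select_metrics(lop, transformed, 3)


# --- habitat classes --------------------------------------------------------

def test_120_distinct_lops_give_30_per_class(rng):
    lop = rng.permutation(120).astype(float)
    hc = derive_classes(lop)
    assert hc.n_less_preferred == 30
    assert hc.n_preferred == 30


def test_degenerate_lop_distribution_errors():
    with pytest.raises(ValueError, match="concentrated"):
        derive_classes(np.full(20, 7.0))


def test_tied_lop_counts_match_strict_comparison(rng):
    lop = rng.integers(0, 6, size=40).astype(float)
    q25, q75 = np.quantile(lop, [0.25, 0.75])
    if q25 == q75:
        pytest.skip("degenerate draw")
    hc = derive_classes(lop)
    assert hc.n_less_preferred == int((lop < q25).sum())
    assert hc.n_preferred == int((lop > q75).sum())


# --- logistic regression ----------------------------------------------------

def simulate_logit(rng, n, beta):
    X = rng.normal(size=(n, len(beta) - 1))
    eta = beta[0] + X @ np.asarray(beta[1:])
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return X, y


def test_fit_matches_independent_ml_oracle(rng):
    X, y = simulate_logit(rng, 300, [0.3, 1.0, -0.7])
    fit = fit_logistic(X, y)
    oracle = logistic_ml(X, y)
    assert fit.converged
    assert np.allclose(fit.params, oracle, atol=1e-6)


def test_symmetry_flipping_labels_negates_coefficients(rng):
    X, y = simulate_logit(rng, 400, [0.0, 0.8, -0.5])
    a = fit_logistic(X, y)
    b = fit_logistic(X, 1 - y)
    assert np.allclose(a.params, -b.params, atol=1e-6)


def test_parameter_recovery_at_n500(rng):
    true = np.array([0.4, 1.2, -0.8, 0.5])
    reps = 40
    est = np.empty((reps, 4))
    for i in range(reps):
        X, y = simulate_logit(rng, 500, true)
        est[i] = fit_logistic(X, y).params
    mc_se = est.std(axis=0, ddof=1) / math.sqrt(reps)
    assert np.all(np.abs(est.mean(axis=0) - true) <= 3 * mc_se + 0.05)


def test_separation_reported_not_silently_fit():
    X = np.linspace(-1, 1, 30)[:, None]
    y = (X[:, 0] > 0).astype(int)  # perfectly separated
    fit = fit_logistic(X, y)
    assert not fit.converged
    assert np.isnan(fit.params).all()


def test_single_class_input_errors():
    with pytest.raises(ValueError):
        fit_logistic(np.random.default_rng(0).normal(size=(20, 2)), np.ones(20))


def test_nagelkerke_intercept_only_is_zero():
    from guildscape.classify import LogisticFit

    # a model that explains nothing has llf == llnull
    fit = LogisticFit(np.array([0.1]), np.array([0.2]), np.array([0.5]),
                      llf=-40.0, llnull=-40.0, nobs=60, converged=True)
    assert nagelkerke_r2(fit) == 0.0


def test_nagelkerke_hand_computed_small_dataset():
    X = np.array([[-1.5], [-1.0], [-0.5], [-0.2], [0.2], [0.5], [1.0], [1.5]])
    y = np.array([0, 0, 1, 0, 1, 0, 1, 1])
    fit = fit_logistic(X, y)
    n = 8
    cs = 1 - math.exp(2 / n * (fit.llnull - fit.llf))
    want = cs / (1 - math.exp(2 / n * fit.llnull))
    assert nagelkerke_r2(fit) == pytest.approx(want, abs=1e-12)
    assert 0.0 <= nagelkerke_r2(fit) <= 1.0


def test_nagelkerke_invariant_to_affine_input_rescaling(rng):
    X, y = simulate_logit(rng, 200, [0.2, 0.9, -0.6])
    a = nagelkerke_r2(fit_logistic(X, y))
    b = nagelkerke_r2(fit_logistic(X * 40.0 + 3.0, y))
    assert a == pytest.approx(b, abs=1e-8)


# --- standardized coefficients ----------------------------------------------

def test_standardized_coefficients_scale_invariant(rng):
    X, y = simulate_logit(rng, 300, [0.1, 0.8, -0.6])
    f1 = fit_logistic(X, y)
    X2 = X.copy()
    X2[:, 0] *= 2.0
    f2 = fit_logistic(X2, y)
    assert f2.params[1] == pytest.approx(f1.params[1] / 2.0, abs=1e-6)
    s1 = standardize_coefficients(f1, X)
    s2 = standardize_coefficients(f2, X2)
    assert np.allclose(s1, s2, atol=1e-6)


def test_equal_coefficients_equal_sds_give_equal_betastar(rng):
    X = rng.normal(size=(500, 2))
    fit = fit_logistic(X, (rng.random(500) < 0.5).astype(int))
    fit.params = np.array([0.0, 0.7, 0.7])
    X_std = (X - X.mean(0)) / X.std(0, ddof=1)
    s = standardize_coefficients(fit, X_std)
    assert s[0] == pytest.approx(s[1], abs=1e-12)


def test_zero_variance_input_errors(rng):
    X = np.column_stack([np.ones(50), rng.normal(size=50)])
    y = (rng.random(50) < 0.5).astype(int)
    fit = fit_logistic(rng.normal(size=(50, 2)), y)
    with pytest.raises(ValueError, match="zero-variance"):
        standardize_coefficients(fit, X)


# --- model / results object -------------------------------------------------

def build_synthetic_problem(rng, n=120):
    z = rng.normal(size=(n, 3))
    lop = np.clip(np.round(28 + 6 * z[:, 0] - 5 * z[:, 1] + 4 * z[:, 2]
                           + rng.normal(0, 9, n)), 0, 57)
    metrics = pd.DataFrame(
        {"SIDI": z[:, 0], "ED": z[:, 1], "SHAPE_MN": z[:, 2],
         "NOISE1": rng.normal(size=n), "NOISE2": rng.normal(size=n)},
        index=pd.Index([f"p{i}" for i in range(n)], name="plot_id"))
    return lop, metrics


def test_guild_model_end_to_end(rng):
    lop, metrics = build_synthetic_problem(rng)
    model = GuildHabitatModel(lop, metrics, guild_id="farmland")
    res = model.fit()
    assert res.converged
    assert set(res.metric_ids) == {"SIDI", "ED", "SHAPE_MN"}
    assert 0.0 <= res.nagelkerke_r2 <= 1.0
    assert res.confusion.sum() == res.classes.n_less_preferred + res.classes.n_preferred
    # training classification beats the majority-class floor
    majority = 100.0 * max(res.classes.n_less_preferred,
                           res.classes.n_preferred) / res.confusion.sum()
    assert res.correct_rate >= majority - 1e-9
    text = res.summary()
    assert "farmland" in text and "Nagelkerke" in text
    d = res.to_dict()
    assert len(d["b"]) == 4 and len(d["b_std"]) == 3


def test_classification_table_cut_point(rng):
    X, y = simulate_logit(rng, 200, [0.0, 1.5])
    fit = fit_logistic(X, y)
    confusion, correct = classification_table(fit, X, y, cut=0.5)
    assert confusion.sum() == 200
    assert correct >= 50.0


def test_predict_suitability_matches_fitted_values(rng):
    from guildscape.window import MetricSurface

    lop, metrics = build_synthetic_problem(rng)
    res = GuildHabitatModel(lop, metrics, guild_id="g").fit()
    # constant surfaces equal to one plot's inputs -> its fitted probability
    pid = metrics.index[5]
    surfaces = {}
    for mid in res.metric_ids:
        vals = np.full((4, 4), metrics.loc[pid, mid])
        surfaces[mid] = MetricSurface(mid, vals, np.ones((4, 4), bool), 250.0, 10.0)
    prob, binary, defined = res.predict_suitability(surfaces)
    want = res.predict(metrics.loc[[pid], res.metric_ids].to_numpy())[0]
    assert np.allclose(prob, want)
    assert defined.all()
    assert np.all((prob >= 0) & (prob <= 1))
    assert set(np.unique(binary)) <= {0.0, 1.0}


def test_predict_suitability_mismatched_grids_error(rng):
    from guildscape.window import MetricSurface

    lop, metrics = build_synthetic_problem(rng)
    res = GuildHabitatModel(lop, metrics).fit()
    surfaces = {mid: MetricSurface(mid, np.zeros((3 + i, 3)),
                                   np.ones((3 + i, 3), bool), 250.0, 10.0)
                for i, mid in enumerate(res.metric_ids)}
    with pytest.raises(ValueError, match="mismatched"):
        res.predict_suitability(surfaces)


def test_plot_suitability_returns_masked_map(rng):
    import matplotlib
    matplotlib.use("Agg")
    from guildscape.window import MetricSurface

    lop, metrics = build_synthetic_problem(rng)
    res = GuildHabitatModel(lop, metrics, guild_id="g").fit()
    surfaces = {}
    for mid in res.metric_ids:
        vals = rng.normal(size=(6, 6))
        defined = np.ones((6, 6), bool)
        defined[0, 0] = False
        surfaces[mid] = MetricSurface(mid, vals, defined, 250.0, 10.0)
    ax = res.plot_suitability(surfaces)
    assert ax.get_title().endswith("g")
    import matplotlib.pyplot as plt
    plt.close("all")
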