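"""Closed-loop validation experiments on synthetic data.

Two experiments quantify whether the analytical chain recovers what the
generative model put in:

* :func:`recovery_experiment` — simulate landscapes and guild occurrence
  from a known three-metric logistic dependence, run the LOP + Spearman
  screening, and measure how often the true metric triple is selected;
  per replicate, also refit the logistic to per-plot Bernoulli occurrence
  drawn from the true model, so the coefficient estimator can be checked
  for bias against the known truth.
* :func:`null_calibration` — simulate outcomes independent of the inputs
  and measure the Wald-test rejection rate at a nominal level, which
  should match that level.

Default problem sizes (64x64-cell mosaic, 50 m window, 200 single-cell
plots, 100 replicates) keep a full run in the minutes range on one core
while leaving the statistical questions intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import fit_logistic, select_metrics, spearman
from .metrics import METRIC_IDS
from .simulate import (DEFAULT_TRUE_B, DEFAULT_TRUE_B0, GuildTruth,
                       LandscapeSpec, OccurrenceSpec, generate_landscape,
                       random_cell_plots, simulate_surveys,
                       standardized_metrics)
from .survey import DEFAULT_DESIGN, Guild, lop_table
from .window import plot_metrics_table

TRUE_GUILD = Guild("mosaic", ("SPEC01", "SPEC02", "SPEC03"))
TRUE_B0 = DEFAULT_TRUE_B0
TRUE_B = DEFAULT_TRUE_B


@dataclass
class RecoveryResult:
    n_reps: int
    n_plots: int
    n_recovered: int
    coef_estimates: np.ndarray  # reps x 4 (intercept + 3 slopes)
    coef_truth: np.ndarray

    @property
    def recovery_rate(self):
        return self.n_recovered / self.n_reps

    @property
    def coef_bias_in_mc_se(self):
        """|mean estimate - truth| expressed in Monte-Carlo standard errors."""
        est = self.coef_estimates[np.all(np.isfinite(self.coef_estimates), axis=1)]
        mc_se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        return np.abs(est.mean(axis=0) - self.coef_truth) / mc_se


def _one_replicate(seed, n_plots, rows, cols, window_radius, margin_cells):
    """Simulate one landscape + survey campaign; return (selected, coefs)."""
    lspec = LandscapeSpec(rows=rows, cols=cols, seed=seed)
    raster = generate_landscape(lspec)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    plots = random_cell_plots(raster, n_plots, rng, margin_cells=margin_cells)

    table = plot_metrics_table(raster, plots, metric_ids=METRIC_IDS,
                               radius=window_radius)
    defined = table.dropna(axis=1, how="any")

    truth = GuildTruth(TRUE_GUILD, b0=TRUE_B0, b=dict(TRUE_B))
    ospec = OccurrenceSpec([truth], design=DEFAULT_DESIGN,
                           window_radius=window_radius, seed=seed)
    records, _ = simulate_surveys(raster, plots, ospec, metrics_table=table)
    lops = lop_table(records, [TRUE_GUILD], [p.plot_id for p in plots])

    lop = lops[TRUE_GUILD.guild_id].to_numpy(dtype=float)
    selected = select_metrics(lop, defined, k=3)

    # coefficient check: refit the generative per-survey occurrence model.
    # Each plot's LOP counts successes out of 3 species x 19 surveys = 57
    # independent Bernoulli trials at that plot's occurrence probability,
    # so the binomial logistic fit on the expanded trials is the exact
    # maximum-likelihood estimator of the generative coefficients.
    names = sorted(TRUE_B)
    z = standardized_metrics(table, names)[names].to_numpy()
    trials = 3 * DEFAULT_DESIGN.total_surveys
    k = lop.astype(int)
    X = np.repeat(z, trials, axis=0)
    y = np.concatenate([np.r_[np.ones(ki), np.zeros(trials - ki)] for ki in k])
    fit = fit_logistic(X, y)
    coefs = fit.params if fit.converged else np.full(len(names) + 1, np.nan)
    return selected, coefs


def recovery_experiment(n_reps=100, n_plots=200, rows=64, cols=64,
                        window_radius=50.0, margin_cells=6, seed=0):
    """Full-pipeline parameter recovery over independent replicates."""
    names = sorted(TRUE_B)
    truth = np.array([TRUE_B0] + [TRUE_B[m] for m in names])
    hits = 0
    coefs = np.empty((n_reps, len(truth)))
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    for i, s in enumerate(seeds):
        selected, c = _one_replicate(int(s), n_plots, rows, cols,
                                     window_radius, margin_cells)
        if set(selected) == set(TRUE_B):
            hits += 1
        coefs[i] = c
    return RecoveryResult(n_reps, n_plots, hits, coefs, truth)


def null_calibration(n_reps=2000, n=60, n_inputs=3, alpha=0.05, seed=0):
    """Wald-test type-I error under a null where y is independent of X.

    Returns the pooled rejection rate over all slope coefficients of all
    converged replicates; under a well-calibrated test it is close to
    ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    tests = 0
    for _ in range(n_reps):
        X = rng.normal(size=(n, n_inputs))
        y = (rng.random(n) < 0.5).astype(int)
        if y.min() == y.max():
            continue
        fit = fit_logistic(X, y)
        if not fit.converged:
            continue
        rejections += int(np.sum(fit.wald_p[1:] < alpha))
        tests += n_inputs
    return rejections / tests, tests
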