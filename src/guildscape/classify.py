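"""Guild habitat classification: Spearman screening, quartile classes,
binary logistic regression and suitability prediction.

The analytical chain, per guild:

1. Rank-correlate every candidate landscape metric with the guild's LOP
   (Spearman) and keep the three strongest, skipping candidates that are
   rank-collinear with an already-selected metric.
2. Split plots into *less preferred* (LOP strictly below the 25% quartile)
   and *preferred* (strictly above the 75% quartile); the middle half is
   excluded, leaving roughly n/4 cases per class.
3. Fit a binary logistic regression of class on the three metrics (all
   entered in a single step) and report unstandardized coefficients, Wald
   chi-square p-values, fully standardized coefficients, Nagelkerke R²
   and the correct-classification rate at the 0.5 cut point.
4. Apply the fitted equation to moving-window metric surfaces to map
   P(preferred) across the whole landscape.

``GuildHabitatModel`` packages the chain; ``fit`` returns a
``GuildHabitatResults`` with the estimates and a ``summary()`` table.
The standalone functions underneath are usable on their own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_COLLINEARITY_CUTOFF = 0.95
SEPARATION_NORM = 1e3


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    defined: bool = True

    @property
    def significant_5(self):
        return self.defined and self.p_value < 0.05

    @property
    def significant_1(self):
        return self.defined and self.p_value < 0.01


def spearman(x, y):
    """Spearman rank correlation with tie-averaged ranks.

    The two-sided p-value uses the t approximation
    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` on n - 2 degrees of freedom.
    A constant input leaves rho undefined (flagged, not NaN-propagated).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-D vectors")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(float("nan"), float("nan"), n, defined=False)
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(float(rho), float(p), n)


def select_metrics(lop, metrics, k=3,
                   collinearity_cutoff=DEFAULT_COLLINEARITY_CUTOFF):
    """Greedy screening of candidate metrics against a guild's LOP.

    Candidates are taken in order of decreasing |rho| with the LOP (ties
    broken by metric id, for determinism); a candidate whose |pairwise
    rho| with an already-selected metric reaches the collinearity cutoff
    is skipped, keeping the inputs as mutually independent as possible.
    Exactly ``k`` metrics are returned.
    """
    lop = np.asarray(lop, dtype=float)
    candidates = []
    for mid in metrics.columns:
        col = metrics[mid].to_numpy(dtype=float)
        if np.isnan(col).any():
            continue
        r = spearman(lop, col)
        if r.defined:
            candidates.append((mid, r.rho))
    candidates.sort(key=lambda t: (-abs(t[1]), t[0]))

    chosen = []
    for mid, rho in candidates:
        ok = True
        for sel in chosen:
            rr = spearman(metrics[sel].to_numpy(dtype=float),
                          metrics[mid].to_numpy(dtype=float))
            if rr.defined and abs(rr.rho) >= collinearity_cutoff:
                ok = False
                break
        if ok:
            chosen.append(mid)
        if len(chosen) == k:
            return chosen
    raise ValueError(
        f"only {len(chosen)} metrics survive screening (need {k}): {chosen}")


# ---------------------------------------------------------------------------
# habitat classes from LOP quartiles
# ---------------------------------------------------------------------------

LESS_PREFERRED, PREFERRED, EXCLUDED = 0, 1, -1


@dataclass
class HabitatClasses:
    labels: pd.Series  # plot_id -> 0 / 1 / -1
    q25: float
    q75: float

    @property
    def n_less_preferred(self):
        return int((self.labels == LESS_PREFERRED).sum())

    @property
    def n_preferred(self):
        return int((self.labels == PREFERRED).sum())


def derive_classes(lop, quantile_method="linear"):
    """Label plots below the 25% LOP quartile as less preferred and above
    the 75% quartile as preferred; the rest are excluded.

    Quartiles use inclusive linear interpolation (numpy's default, R type
    7); comparisons are strict, as the class definitions say below/above.
    """
    s = pd.Series(lop, dtype=float)
    if len(s) < 8:
        raise ValueError("need at least 8 plots to derive quartile classes")
    q25, q75 = np.quantile(s.to_numpy(), [0.25, 0.75], method=quantile_method)
    if q25 == q75:
        raise ValueError("LOP distribution too concentrated (q25 == q75)")
    labels = pd.Series(EXCLUDED, index=s.index, dtype=int)
    labels[s < q25] = LESS_PREFERRED
    labels[s > q75] = PREFERRED
    return HabitatClasses(labels, float(q25), float(q75))


# ---------------------------------------------------------------------------
# logistic regression and diagnostics
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    params: np.ndarray  # intercept first
    bse: np.ndarray
    wald_p: np.ndarray
    llf: float
    llnull: float
    nobs: int
    converged: bool
    diagnostic: str = ""

    def linear_predictor(self, X):
        X = np.asarray(X, dtype=float)
        return self.params[0] + X @ self.params[1:]

    def predict(self, X):
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(X)))


def fit_logistic(X, y):
    """Maximum-likelihood binary logistic regression (all inputs entered in
    one step).

    Standard errors come from the inverse observed information; per-input
    Wald chi-square p-values from chi2(1).  Quasi-complete separation
    (diverging coefficient norm or failed convergence) is reported with
    ``converged=False`` and coefficients withheld rather than a penalized
    refit.
    """
    import statsmodels.api as sm

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if len(y) <= 5:
        raise ValueError("too few observations for a logistic fit")

    design = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, design).fit(disp=False, maxiter=200)
        params = np.asarray(res.params, dtype=float)
        ok = bool(res.mle_retvals.get("converged", False))
        ok = ok and np.linalg.norm(params) <= SEPARATION_NORM
        bse = np.asarray(res.bse, dtype=float)
        ok = ok and np.all(np.isfinite(bse))
    except (np.linalg.LinAlgError, ValueError, Exception) as exc:  # noqa: BLE001
        return LogisticFit(np.full(X.shape[1] + 1, np.nan),
                           np.full(X.shape[1] + 1, np.nan),
                           np.full(X.shape[1] + 1, np.nan),
                           np.nan, np.nan, len(y), False, str(exc))
    if not ok:
        nan = np.full(X.shape[1] + 1, np.nan)
        return LogisticFit(nan, nan.copy(), nan.copy(), np.nan, np.nan,
                           len(y), False,
                           "non-convergence or quasi-complete separation")
    wald = (params / bse) ** 2
    wald_p = stats.chi2.sf(wald, df=1)
    return LogisticFit(params, bse, wald_p, float(res.llf), float(res.llnull),
                       int(res.nobs), True)


def nagelkerke_r2(fit):
    """Nagelkerke's rescaled likelihood-ratio pseudo-R² in [0, 1]."""
    n = fit.nobs
    cox_snell = 1.0 - math.exp(2.0 / n * (fit.llnull - fit.llf))
    max_cs = 1.0 - math.exp(2.0 / n * fit.llnull)
    if max_cs == 0:
        return 0.0
    return min(1.0, max(0.0, cox_snell / max_cs))


def standardize_coefficients(fit, X):
    """Fully standardized logistic coefficients.

    beta*_j = b_j * s_{x_j} / sqrt(var(eta_hat) + pi^2 / 3), with eta_hat
    the fitted linear predictor and pi^2/3 the variance of the standard
    logistic latent residual.  Comparable across inputs: larger |beta*|
    means a stronger predictor.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    sx = X.std(axis=0, ddof=1)
    if np.any(sx == 0):
        raise ValueError("zero-variance input")
    eta = fit.linear_predictor(X)
    denom = math.sqrt(eta.var(ddof=1) + math.pi**2 / 3.0)
    return fit.params[1:] * sx / denom


def classification_table(fit, X, y, cut=0.5):
    """Confusion table and percent correct at the given cut point."""
    pred = (fit.predict(X) >= cut).astype(int)
    y = np.asarray(y).astype(int)
    confusion = np.array([[np.sum((y == 0) & (pred == 0)),
                           np.sum((y == 0) & (pred == 1))],
                          [np.sum((y == 1) & (pred == 0)),
                           np.sum((y == 1) & (pred == 1))]])
    correct = 100.0 * np.trace(confusion) / confusion.sum()
    return confusion, float(correct)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class GuildHabitatModel:
    """Binary habitat-preference classifier for one bird guild.

    Parameters
    ----------
    lop : 1-D array or Series of per-plot LOP values (index = plot ids).
    metrics : DataFrame, plots x candidate landscape metrics, aligned to
        ``lop`` (e.g. from :func:`guildscape.window.plot_metrics_table`).
    guild_id : label used in reports.
    k : number of metrics entered into the regression (three keeps the
        interpretation transparent).
    collinearity_cutoff, quantile_method, cut : see the stage functions.
    """

    def __init__(self, lop, metrics, guild_id="guild", k=3,
                 collinearity_cutoff=DEFAULT_COLLINEARITY_CUTOFF,
                 quantile_method="linear", cut=0.5):
        self.lop = pd.Series(np.asarray(lop, dtype=float),
                             index=metrics.index)
        self.metrics = metrics
        self.guild_id = guild_id
        self.k = k
        self.collinearity_cutoff = collinearity_cutoff
        self.quantile_method = quantile_method
        self.cut = cut

    @classmethod
    def from_tables(cls, lop_table, metrics, guild_id, **kw):
        """Build from an LOP table (plot x guild) and a plot-metrics table."""
        common = metrics.index.intersection(lop_table.index)
        return cls(lop_table.loc[common, guild_id], metrics.loc[common],
                   guild_id=guild_id, **kw)

    def fit(self):
        classes = derive_classes(self.lop, self.quantile_method)
        selected = select_metrics(self.lop, self.metrics, self.k,
                                  self.collinearity_cutoff)
        keep = classes.labels != EXCLUDED
        X = self.metrics.loc[keep, selected].to_numpy(dtype=float)
        y = classes.labels[keep].to_numpy()
        fit = fit_logistic(X, y)
        if fit.converged:
            b_std = standardize_coefficients(fit, X)
            r2 = nagelkerke_r2(fit)
            confusion, correct = classification_table(fit, X, y, self.cut)
        else:
            b_std = np.full(len(selected), np.nan)
            r2 = float("nan")
            confusion = np.zeros((2, 2), dtype=int)
            correct = float("nan")
        screening = {mid: spearman(self.lop.to_numpy(),
                                   self.metrics[mid].to_numpy(dtype=float))
                     for mid in self.metrics.columns}
        return GuildHabitatResults(self, selected, classes, fit, b_std, r2,
                                   confusion, correct, screening)


@dataclass
class GuildHabitatResults:
    """Fitted guild habitat classifier with diagnostics."""

    model: GuildHabitatModel
    metric_ids: list
    classes: HabitatClasses
    fit_: LogisticFit
    std_params: np.ndarray
    nagelkerke_r2: float
    confusion: np.ndarray
    correct_rate: float
    screening: dict = field(default_factory=dict)

    @property
    def converged(self):
        return self.fit_.converged

    @property
    def params(self):
        """Unstandardized coefficients, intercept first."""
        return self.fit_.params

    @property
    def bse(self):
        return self.fit_.bse

    @property
    def wald_p(self):
        return self.fit_.wald_p

    @property
    def overestimation(self):
        """Off-diagonal asymmetry of the confusion table: positive when
        less-preferred habitat is over-predicted."""
        return int(self.confusion[1, 0] - self.confusion[0, 1])

    def predict(self, X):
        return self.fit_.predict(X)

    def predict_suitability(self, surfaces, cut=None):
        """P(preferred) surface and binary suitability map from metric surfaces.

        ``surfaces`` maps metric_id -> MetricSurface for every fitted input;
        cells where any input is undefined stay undefined.
        """
        cut = self.model.cut if cut is None else cut
        if not self.converged:
            raise ValueError("model did not converge; no prediction available")
        missing = [m for m in self.metric_ids if m not in surfaces]
        if missing:
            raise ValueError(f"missing surfaces for {missing}")
        shapes = {surfaces[m].values.shape for m in self.metric_ids}
        if len(shapes) != 1:
            raise ValueError("mismatched surface grids")
        defined = np.logical_and.reduce(
            [surfaces[m].defined for m in self.metric_ids])
        eta = np.full(next(iter(shapes)), self.params[0])
        for b, mid in zip(self.params[1:], self.metric_ids):
            eta = eta + b * surfaces[mid].values
        prob = np.where(defined, 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700))),
                        np.nan)
        binary = np.where(defined, (prob >= cut).astype(float), np.nan)
        return prob, binary, defined

    def plot_suitability(self, surfaces, cut=None, ax=None):
        """Map P(preferred) across the landscape (suitability surface).

        Returns the matplotlib Axes; undefined cells are masked out.
        """
        import matplotlib.pyplot as plt

        prob, _, defined = self.predict_suitability(surfaces, cut=cut)
        if ax is None:
            _, ax = plt.subplots()
        masked = np.ma.masked_where(~defined, prob)
        im = ax.imshow(masked, vmin=0.0, vmax=1.0, cmap="viridis")
        ax.figure.colorbar(im, ax=ax, label="P(preferred)")
        ax.set_title(f"Habitat suitability: {self.model.guild_id}")
        return ax

    def summary(self):
        """Plain-text report mirroring a per-guild classification table."""
        lines = [f"Guild habitat classification: {self.model.guild_id}",
                 f"  plots: {len(self.model.lop)}  "
                 f"(less preferred {self.classes.n_less_preferred}, "
                 f"preferred {self.classes.n_preferred}; "
                 f"LOP quartiles {self.classes.q25:.2f} / {self.classes.q75:.2f})"]
        if not self.converged:
            lines.append(f"  NOT CONVERGED: {self.fit_.diagnostic}")
            return "\n".join(lines)
        head = f"  {'input':<12}{'b':>10}{'std b':>10}{'Wald p':>10}"
        lines.append(head)
        for j, mid in enumerate(self.metric_ids, start=1):
            lines.append(f"  {mid:<12}{self.params[j]:>10.3f}"
                         f"{self.std_params[j - 1]:>10.3f}"
                         f"{self.wald_p[j]:>10.3f}")
        lines.append(f"  {'Constant':<12}{self.params[0]:>10.3f}{'':>10}"
                     f"{self.wald_p[0]:>10.3f}")
        lines.append(f"  Nagelkerke R2 = {self.nagelkerke_r2:.3f}   "
                     f"correct = {self.correct_rate:.1f}% at cut {self.model.cut}")
        c = self.confusion
        lines.append(f"  confusion [[{c[0,0]} {c[0,1]}] [{c[1,0]} {c[1,1]}]]"
                     f"   overestimation of less preferred = {self.overestimation}")
        return "\n".join(lines)

    def to_dict(self):
        """JSON-ready report (per-guild table plus diagnostics)."""
        return {
            "guild_id": self.model.guild_id,
            "inputs": list(self.metric_ids),
            "b": [float(v) for v in self.params],
            "se": [float(v) for v in self.bse],
            "wald_p": [float(v) for v in self.wald_p],
            "b_std": [float(v) for v in self.std_params],
            "nagelkerke_r2": float(self.nagelkerke_r2),
            "correct_rate": float(self.correct_rate),
            "confusion": self.confusion.tolist(),
            "converged": bool(self.converged),
            "q25": self.classes.q25,
            "q75": self.classes.q75,
        }
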