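"""Cohort-level association analysis for the 7-day survival endpoint.

Covers the modelling stages between the HRV indices and the final prediction
model: contingency tables and univariate odds ratios, maximum-likelihood
logistic regression with Wald inference, stepwise variable selection
(entry/stay at p = 0.15, final pruning at 0.05), smoother-based discovery of
a clinical cutpoint for a continuous index, Hosmer-Lemeshow calibration
testing, and Kaplan-Meier median survival.

Odds-ratio confidence intervals are Wald intervals on the log-odds scale;
the CI method is a reporting choice (profile-likelihood intervals differ
slightly) while point estimates are method-invariant.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy.stats import chi2, norm
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import InputError, ValidityError

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable2x2",
    "OddsRatioResult",
    "LogisticFit",
    "StepwiseResult",
    "CutpointResult",
    "HosmerLemeshowResult",
    "KMEstimate",
    "two_by_two",
    "odds_ratio",
    "fit_logistic",
    "stepwise_select",
    "gam_cutpoint",
    "hosmer_lemeshow",
    "km_estimate",
]


# --------------------------------------------------------------------------
# Contingency tables and odds ratios
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure x outcome counts: a = exposed events, b = unexposed events,
    c = exposed non-events, d = unexposed non-events."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValidityError(f"cell {name}={v!r} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swap_exposure(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.b, self.a, self.d, self.c)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    se_log: float
    p_value: float
    defined: bool = True


def two_by_two(cohort: pd.DataFrame, exposure, outcome="event_7d") -> ContingencyTable2x2:
    """Cross-tabulate an exposure predicate against the 7-day event.

    ``exposure`` and ``outcome`` are either column names of 0/1 columns or
    callables mapping the cohort frame to a boolean Series.  Rows where
    either predicate is missing are dropped listwise (with a logged count).
    """

    def evaluate(pred) -> pd.Series:
        s = pred(cohort) if callable(pred) else cohort[pred]
        return pd.Series(s, index=cohort.index).astype("boolean")

    if cohort.empty:
        return ContingencyTable2x2(0, 0, 0, 0)
    e = evaluate(exposure)
    o = evaluate(outcome)
    keep = e.notna() & o.notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("two_by_two: dropped %d rows with missing values", dropped)
    e, o = e[keep].astype(bool), o[keep].astype(bool)
    return ContingencyTable2x2(
        a=int((e & o).sum()),
        b=int((~e & o).sum()),
        c=int((e & ~o).sum()),
        d=int((~e & ~o).sum()),
    )


def odds_ratio(table: ContingencyTable2x2, haldane: bool = False) -> OddsRatioResult:
    """Cross-product odds ratio with a log-scale normal 95% CI.

    A zero cell leaves the estimate undefined unless ``haldane`` adds the
    0.5 continuity correction to every cell.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0:
        return OddsRatioResult(math.nan, math.nan, math.nan, math.nan, math.nan, False)
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(est)
    z = log_or / se
    return OddsRatioResult(
        odds_ratio=est,
        ci_low=math.exp(log_or - 1.96 * se),
        ci_high=math.exp(log_or + 1.96 * se),
        se_log=se,
        p_value=2 * norm.sf(abs(z)),
        defined=True,
    )


# --------------------------------------------------------------------------
# Logistic regression
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference.

    ``terms`` excludes the intercept; coefficient arrays are indexed
    ``['intercept', *terms]``.  ``converged`` is False on separation or
    optimizer failure, in which case estimates must not be trusted.
    """

    terms: tuple[str, ...]
    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    log_likelihood: float
    n_used: int
    converged: bool
    diagnostic: str = ""
    fitted: pd.Series = field(default=None, repr=False)

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.coefficients)

    @property
    def ci_95(self) -> pd.DataFrame:
        lo = np.exp(self.coefficients - 1.96 * self.std_errors)
        hi = np.exp(self.coefficients + 1.96 * self.std_errors)
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})


def _prepare(cohort: pd.DataFrame, terms, outcome):
    cols = list(terms) + [outcome]
    data = cohort[cols].apply(pd.to_numeric, errors="coerce").dropna()
    dropped = len(cohort) - len(data)
    if dropped:
        logger.info("fit_logistic: dropped %d rows with missing values", dropped)
    return data


def fit_logistic(
    cohort: pd.DataFrame, terms, outcome: str = "event_7d"
) -> LogisticFit:
    """Fit the event on numeric ``terms`` by maximum likelihood (IRLS)."""
    terms = list(terms)
    data = _prepare(cohort, terms, outcome)
    y = data[outcome].astype(float)
    if y.nunique() < 2:
        raise InputError("outcome takes a single value; cannot fit")
    if len(data) <= len(terms) + 1:
        raise InputError("more parameters than observations")
    X = sm.add_constant(data[terms].astype(float), has_constant="add") if terms else (
        pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
    )
    names = ["intercept"] + terms
    converged, diagnostic = True, ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
            params = pd.Series(res.params.to_numpy(), index=names)
            bse = pd.Series(res.bse.to_numpy(), index=names)
            pvals = pd.Series(res.pvalues.to_numpy(), index=names)
            llf = float(res.llf)
            fitted = pd.Series(res.predict(X), index=data.index)
        if not np.all(np.isfinite(bse)) or bse.max() > 1e3:
            converged = False
            diagnostic = "quasi-complete separation suspected (huge standard errors)"
        elif not converged:
            diagnostic = "optimizer did not converge"
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        nan = pd.Series(np.nan, index=names)
        return LogisticFit(
            terms=tuple(terms), coefficients=nan, std_errors=nan, p_values=nan,
            log_likelihood=math.nan, n_used=len(data), converged=False,
            diagnostic=f"separation: {exc}", fitted=None,
        )
    return LogisticFit(
        terms=tuple(terms),
        coefficients=params,
        std_errors=bse,
        p_values=pvals,
        log_likelihood=llf,
        n_used=len(data),
        converged=converged,
        diagnostic=diagnostic,
        fitted=fitted,
    )


@dataclass(frozen=True)
class StepwiseResult:
    selected: tuple[str, ...]
    fit: LogisticFit
    history: tuple[str, ...]


def stepwise_select(
    cohort: pd.DataFrame,
    candidates,
    outcome: str = "event_7d",
    sle: float = 0.15,
    sls: float = 0.15,
    prune_alpha: float = 0.05,
) -> StepwiseResult:
    """Stepwise logistic selection: forward entry at Wald p < ``sle``,
    backward elimination at p > ``sls``, then final manual-style pruning of
    terms with p > ``prune_alpha`` one at a time.

    Deterministic for a fixed candidate order; ties on p-values are broken
    by candidate-list position.
    """
    candidates = list(candidates)
    selected: list[str] = []
    history: list[str] = []

    def wald_p(fit: LogisticFit, term: str) -> float:
        p = fit.p_values.get(term, math.nan)
        return p if math.isfinite(p) else 1.0

    changed = True
    while changed:
        changed = False
        # forward step
        best_term, best_p = None, sle
        for term in candidates:
            if term in selected:
                continue
            try:
                trial = fit_logistic(cohort, selected + [term], outcome)
            except InputError:
                continue
            if not trial.converged:
                continue
            p = wald_p(trial, term)
            if p < best_p - 1e-12:
                best_term, best_p = term, p
        if best_term is not None:
            selected.append(best_term)
            history.append(f"+{best_term} (p={best_p:.4f})")
            changed = True
        # backward step(s)
        while selected:
            fit = fit_logistic(cohort, selected, outcome)
            worst = max(selected, key=lambda t: (wald_p(fit, t), -selected.index(t)))
            if wald_p(fit, worst) > sls:
                selected.remove(worst)
                history.append(f"-{worst} (p>{sls})")
                changed = True
            else:
                break

    # final pruning at prune_alpha, one term at a time
    while selected:
        fit = fit_logistic(cohort, selected, outcome)
        worst = max(selected, key=lambda t: (wald_p(fit, t), -selected.index(t)))
        if wald_p(fit, worst) > prune_alpha:
            selected.remove(worst)
            history.append(f"-{worst} (p>{prune_alpha})")
        else:
            break

    final = fit_logistic(cohort, selected, outcome)
    return StepwiseResult(tuple(selected), final, tuple(history))


# --------------------------------------------------------------------------
# Smoother-based cutpoint discovery
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CutpointResult:
    found: bool
    cutoff: float = math.nan
    raw_cutoff: float = math.nan
    grid: np.ndarray = field(default=None, repr=False)
    partial_log_odds: np.ndarray = field(default=None, repr=False)
    reason: str = ""


def gam_cutpoint(
    cohort: pd.DataFrame,
    index: str,
    adjust=(),
    outcome: str = "event_7d",
    round_to: float | None = 0.5,
    min_effect: float = 0.1,
    spline_df: int = 10,
) -> CutpointResult:
    """Locate a clinical cutpoint for a continuous index from a smoothed
    logistic generalized additive model.

    The event is regressed on a penalized B-spline of ``index`` (penalty
    weight chosen by generalized cross-validation) with linear ``adjust``
    terms.  The returned cutoff is where the centred partial log-odds of the
    index crosses zero (its mean level), rounded to the nearest ``round_to``
    for clinical use.  If the smooth's excursion never exceeds ``min_effect``
    on the log-odds scale, or no crossing is bracketed, a no-cutoff flag is
    returned instead.
    """
    adjust = list(adjust)
    data = _prepare(cohort, [index] + adjust, outcome)
    x = data[index].to_numpy(dtype=float)
    if np.unique(x).size < 20:
        raise InputError("need at least 20 distinct index values for smoothing")
    y = data[outcome].to_numpy(dtype=float)
    # the spline basis spans no constant, so the intercept must sit in the
    # linear part for a flat-risk fit to be representable
    exog = sm.add_constant(data[adjust].astype(float), has_constant="add") if adjust else (
        pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
    )

    smoother = BSplines(x[:, None], df=[spline_df], degree=[3])

    def make(alpha):
        return GLMGam(
            y, exog=exog, smoother=smoother, alpha=alpha,
            family=sm.families.Binomial(),
        )

    # penalty weight by grid search on the effective-dof information
    # criterion (the library's built-in penalty optimizer does not support
    # binomial families)
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for alpha in np.logspace(-1, 7, 17):
            try:
                cand = make(alpha).fit()
                score = float(cand.aic)
            except Exception:
                continue
            if math.isfinite(score) and (best is None or score < best[0]):
                best = (score, cand)
        if best is None:
            best = (math.nan, make(1.0).fit())
    res = best[1]

    # partial log-odds contribution of the smooth term on a fine grid,
    # centred at its mean level over the data
    span = x.max() - x.min()
    grid = np.linspace(x.min() + 1e-9 * span, x.max() - 1e-9 * span, 512)
    basis_grid = smoother.smoothers[0].transform(grid[:, None])
    k_lin = exog.shape[1] if exog is not None else 0
    nb = basis_grid.shape[1]
    smooth_params = np.asarray(res.params)[k_lin: k_lin + nb]
    # centring contrast: subtract the mean level over the data, and push the
    # same contrast through the covariance so pointwise SEs stay consistent
    center_row = np.mean(smoother.smoothers[0].basis, axis=0)
    contrast = basis_grid - center_row
    partial = contrast @ smooth_params
    cov = np.asarray(res.cov_params())[k_lin: k_lin + nb, k_lin: k_lin + nb]
    se_grid = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", contrast, cov, contrast), 0.0))
    if np.ptp(partial) < min_effect:
        return CutpointResult(False, grid=grid, partial_log_odds=partial,
                              reason="smooth effect below the materiality threshold")
    if np.all(np.abs(partial) < 2.0 * se_grid):
        return CutpointResult(False, grid=grid, partial_log_odds=partial,
                              reason="smooth effect nowhere distinguishable from flat")
    crossings = []
    for i in range(partial.size - 1):
        y0, y1_ = partial[i], partial[i + 1]
        if y0 == 0.0:
            crossings.append(float(grid[i]))
        elif y0 * y1_ < 0:
            crossings.append(float(grid[i] - y0 * (grid[i + 1] - grid[i]) / (y1_ - y0)))
    if not crossings:
        return CutpointResult(False, grid=grid, partial_log_odds=partial,
                              reason="smoothed log-odds never crosses its mean level")
    center = float(np.median(x))
    raw = min(crossings, key=lambda c: (abs(c - center), c))
    cut = round(raw / round_to) * round_to if round_to else raw
    return CutpointResult(True, cutoff=float(cut), raw_cutoff=float(raw),
                          grid=grid, partial_log_odds=partial)


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HosmerLemeshowResult:
    statistic: float
    df: int
    p_value: float
    n_groups: int
    testable: bool
    table: pd.DataFrame = field(default=None, repr=False)
    reason: str = ""


def hosmer_lemeshow(
    fitted_probs, observed, groups: int = 10
) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow goodness-of-fit test on deciles of fitted risk.

    When the model yields fewer distinct fitted probabilities than requested
    groups (e.g. two binary predictors give at most 4 risk strata), patients
    are grouped by distinct fitted value instead.  Fewer than 3 effective
    groups makes the test untestable (df would be <= 0).
    """
    p = np.asarray(fitted_probs, dtype=float)
    y = np.asarray(observed, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise InputError("fitted_probs and observed must be aligned 1-D arrays")
    distinct = np.unique(p)
    if distinct.size < groups:
        labels = np.searchsorted(distinct, p)
    else:
        labels = pd.qcut(pd.Series(p).rank(method="first"), groups, labels=False).to_numpy()
    frame = pd.DataFrame({"g": labels, "p": p, "y": y})
    tab = frame.groupby("g").agg(n=("y", "size"), observed=("y", "sum"), expected=("p", "sum"))
    g_eff = len(tab)
    if g_eff < 3:
        return HosmerLemeshowResult(math.nan, 0, math.nan, g_eff, False, tab,
                                    reason="fewer than 3 risk strata")
    o, e, n = tab["observed"].to_numpy(), tab["expected"].to_numpy(), tab["n"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.nansum((o - e) ** 2 / e + ((n - o) - (n - e)) ** 2 / (n - e))
    df = g_eff - 2
    return HosmerLemeshowResult(float(stat), df, float(chi2.sf(stat, df)), g_eff, True, tab)


# --------------------------------------------------------------------------
# Kaplan-Meier
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival curve with median and its 95% CI.

    ``median`` is the smallest time at which survival drops to 0.5 or below;
    it is NaN (``median_defined`` False) when the curve never reaches 0.5.
    CI bounds use the log(-log) (exponential Greenwood) transform and may be
    infinite when the curve is uninformative at the tail.
    """

    times: np.ndarray
    survival_prob: np.ndarray
    median: float
    median_ci_95: tuple[float, float]
    median_defined: bool


def km_estimate(times, death_observed) -> KMEstimate:
    t = np.asarray(times, dtype=float)
    d = np.asarray(death_observed, dtype=bool)
    if t.ndim != 1 or t.shape != d.shape or t.size == 0:
        raise InputError("times and death_observed must be aligned non-empty arrays")
    if np.any(t < 0):
        raise InputError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=d)
    surv = kmf.survival_function_["KM_estimate"]
    median = float(kmf.median_survival_time_)
    defined = math.isfinite(median)
    if defined:
        ci_frame = median_survival_times(kmf.confidence_interval_)
        lo = float(ci_frame.iloc[0, 0])
        hi = float(ci_frame.iloc[0, 1])
    else:
        median, lo, hi = math.nan, math.nan, math.nan
    return KMEstimate(
        times=surv.index.to_numpy(dtype=float),
        survival_prob=surv.to_numpy(dtype=float),
        median=median,
        median_ci_95=(lo, hi),
        median_defined=defined,
    )
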