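"""End-to-end driver: cohort in (or simulated), prognostic report out.

Stages mirror the analysis plan of the underlying study design:

1. descriptives of the admission cohort and 7-day event rate,
2. univariate odds ratios of each binary covariate for death within 7 days,
3. cutpoint discovery for the chosen continuous HRV index (penalized-spline
   logistic smoother, adjusted for ECOG), then dichotomization,
4. stepwise multivariable logistic selection (entry/stay 0.15, pruning 0.05)
   over the configured candidates plus the dichotomized index,
5. Hosmer-Lemeshow calibration of the final model,
6. Kaplan-Meier median survival,
7. ROC / AUC / closest-top-left operating point and diagnostic metrics for
   the final model's fitted risk, plus the single-cell clinical rule
   (index below cut AND ECOG 3-4).

A run is fully reproducible from (config, seed): the report embeds both and
contains no timestamps.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    fit_logistic,
    gam_cutpoint,
    hosmer_lemeshow,
    km_estimate,
    odds_ratio,
    stepwise_select,
    two_by_two,
)
from .config import PipelineConfig
from .evaluate import ConfusionCounts, closest_topleft, diagnostics, roc_curve
from .exceptions import StageError
from .io import read_cohort_csv
from .simulate import CohortSimSpec, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunReport", "run_pipeline", "write_report"]

#: binary covariates reported in the univariate stage, in table order
UNIVARIATE_BINARIES = (
    ("male", lambda df: df["sex"].eq("M")),
    ("cognitive_impairment", "cognitive_impairment"),
    ("edema", "edema"),
    ("jaundice", "jaundice"),
    ("ascites", "ascites"),
    ("ecog_34", "ecog_34"),
)


@dataclass(frozen=True)
class RunReport:
    """All stage outputs plus provenance; serializable to JSON/Markdown."""

    descriptives: dict
    univariate: dict
    cutpoint: dict
    final_model: dict
    calibration: dict
    survival: dict
    evaluation: dict
    provenance: dict
    roc_vertices: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "descriptives": self.descriptives,
            "univariate": self.univariate,
            "cutpoint": self.cutpoint,
            "final_model": self.final_model,
            "calibration": self.calibration,
            "survival": self.survival,
            "evaluation": self.evaluation,
            "provenance": self.provenance,
        }


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
            logger.info("stage %-12s %.2f s", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def _round(x, nd=6):
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return None
    return round(float(x), nd)


def _or_entry(result) -> dict:
    return {
        "or": _round(result.odds_ratio, 4),
        "ci_low": _round(result.ci_low, 4),
        "ci_high": _round(result.ci_high, 4),
        "p_value": _round(result.p_value, 4),
        "defined": result.defined,
    }


@_stage("descriptives")
def _descriptives(cohort: pd.DataFrame) -> dict:
    n = len(cohort)
    events = int(cohort["event_7d"].sum())
    return {
        "n": n,
        "events_7d": events,
        "event_rate_pct": _round(100.0 * events / n, 2),
        "male_pct": _round(100.0 * cohort["sex"].eq("M").mean(), 2),
        "mean_age": _round(cohort["age"].mean(), 2),
        "ecog_34_pct": _round(100.0 * cohort["ecog_34"].mean(), 2),
    }


@_stage("univariate")
def _univariate(cohort: pd.DataFrame) -> dict:
    out = {}
    for name, predicate in UNIVARIATE_BINARIES:
        out[name] = _or_entry(odds_ratio(two_by_two(cohort, predicate)))
    for cont in ("age", "muscle_power", "ln_tp", "ln_hfp", "ln_lf_hf"):
        fit = fit_logistic(cohort, [cont])
        if fit.converged:
            out[cont] = {
                "or": _round(fit.odds_ratios[cont], 4),
                "ci_low": _round(fit.ci_95.loc[cont, "ci_low"], 4),
                "ci_high": _round(fit.ci_95.loc[cont, "ci_high"], 4),
                "p_value": _round(fit.p_values[cont], 4),
                "defined": True,
            }
        else:
            out[cont] = {"or": None, "defined": False, "note": fit.diagnostic}
    return out


def run_pipeline(
    config: PipelineConfig,
    cohort: pd.DataFrame | None = None,
    cohort_path=None,
    simulate: bool = False,
) -> RunReport:
    """Run every stage and return the report; see the module docstring."""
    if cohort is None:
        if simulate:
            cohort = simulate_cohort(CohortSimSpec(n=config.simulate_n, seed=config.seed))
        elif cohort_path is not None:
            cohort = read_cohort_csv(cohort_path)
        else:
            raise StageError("input", "provide a cohort, a cohort_path, or simulate=True")

    mc = config.model
    descriptives = _descriptives(cohort)
    univariate = _univariate(cohort)

    # -- cutpoint discovery, then dichotomization of the HRV index
    if mc.cutpoint is not None:
        cut_info = {"index": mc.hrv_index, "cutoff": mc.cutpoint, "source": "configured"}
        cut = float(mc.cutpoint)
    else:
        cp = gam_cutpoint(cohort, mc.hrv_index, adjust=mc.adjust_terms)
        if cp.found:
            cut = cp.cutoff
            cut_info = {
                "index": mc.hrv_index, "cutoff": _round(cp.cutoff, 4),
                "raw_cutoff": _round(cp.raw_cutoff, 4), "source": "gam",
            }
        else:
            cut = float(np.median(cohort[mc.hrv_index]))
            cut_info = {
                "index": mc.hrv_index, "cutoff": _round(cut, 4),
                "source": "median-fallback", "reason": cp.reason,
            }
    dichotomized = f"{mc.hrv_index}_lt_cut"
    cohort = cohort.copy()
    cohort[dichotomized] = (cohort[mc.hrv_index] < cut).astype(int)

    # -- stepwise multivariable selection
    candidates = [dichotomized] + [c for c in mc.candidates if c != dichotomized]
    step = stepwise_select(
        cohort, candidates, sle=mc.sle, sls=mc.sls, prune_alpha=mc.prune_alpha
    )
    fit = step.fit
    final_model = {
        "selected": list(step.selected),
        "history": list(step.history),
        "converged": fit.converged,
        "n_used": fit.n_used,
        "terms": {
            term: {
                "coef": _round(fit.coefficients[term], 4),
                "or": _round(fit.odds_ratios[term], 4),
                "ci_low": _round(fit.ci_95.loc[term, "ci_low"], 4),
                "ci_high": _round(fit.ci_95.loc[term, "ci_high"], 4),
                "p_value": _round(fit.p_values[term], 4),
            }
            for term in ("intercept", *step.selected)
        },
    }

    # -- calibration
    if fit.fitted is not None and len(step.selected) > 0:
        hl = hosmer_lemeshow(fit.fitted.to_numpy(), cohort.loc[fit.fitted.index, "event_7d"])
        calibration = {
            "statistic": _round(hl.statistic, 4), "df": hl.df,
            "p_value": _round(hl.p_value, 4), "n_groups": hl.n_groups,
            "testable": hl.testable,
        }
    else:
        calibration = {"testable": False, "reason": "no predictors selected"}

    # -- Kaplan-Meier
    km = km_estimate(cohort["survival_days"], cohort["death_observed"])
    survival = {
        "median_days": _round(km.median, 2),
        "median_ci_95": [_round(km.median_ci_95[0], 2), _round(km.median_ci_95[1], 2)],
        "median_defined": km.median_defined,
    }

    # -- evaluation of the final model and the clinical cell rule
    evaluation: dict = {}
    roc_frame = None
    if fit.fitted is not None and len(step.selected) > 0:
        y = cohort.loc[fit.fitted.index, "event_7d"].to_numpy()
        scores = fit.fitted.to_numpy()
        curve = roc_curve(scores, y)
        tl = closest_topleft(curve)
        counts = ConfusionCounts.from_scores(scores, y, tl.threshold)
        diag = diagnostics(counts, ci_method=config.evaluation.ci_method)
        evaluation["final_model"] = {
            "auc": _round(curve.auc, 4),
            "auc_ci_95": [_round(curve.auc_ci_95[0], 4), _round(curve.auc_ci_95[1], 4)],
            "threshold": _round(tl.threshold, 6),
            "topleft_distance": _round(tl.distance, 4),
            "confusion": {"tp": counts.tp, "fn": counts.fn, "fp": counts.fp, "tn": counts.tn},
            "metrics": {
                name: {
                    "value": _round(m.value, 4),
                    "ci_low": _round(m.ci_low, 4),
                    "ci_high": _round(m.ci_high, 4),
                }
                for name, m in (
                    ("sensitivity", diag.sensitivity), ("specificity", diag.specificity),
                    ("ppv", diag.ppv), ("npv", diag.npv),
                )
            },
        }
        roc_frame = pd.DataFrame(
            {
                "threshold": curve.thresholds,
                "sensitivity": curve.sensitivity,
                "specificity": curve.specificity,
            }
        )
    rule_scores = ((cohort[dichotomized] == 1) & (cohort["ecog_34"] == 1)).astype(int)
    rule_counts = ConfusionCounts.from_scores(
        rule_scores.to_numpy(), cohort["event_7d"].to_numpy(), 1
    )
    rule_diag = diagnostics(rule_counts, ci_method=config.evaluation.ci_method)
    evaluation["cell_rule"] = {
        "definition": f"{mc.hrv_index} < {cut:g} AND ecog_34",
        "confusion": {
            "tp": rule_counts.tp, "fn": rule_counts.fn,
            "fp": rule_counts.fp, "tn": rule_counts.tn,
        },
        "metrics": {
            name: {"value": _round(m.value, 4), "ci_low": _round(m.ci_low, 4),
                   "ci_high": _round(m.ci_high, 4)}
            for name, m in (
                ("sensitivity", rule_diag.sensitivity),
                ("specificity", rule_diag.specificity),
                ("ppv", rule_diag.ppv), ("npv", rule_diag.npv),
            )
        },
    }

    provenance = {
        "package": "hrvsurv",
        "version": __version__,
        "config_hash": config.config_hash,
        "seed": config.seed,
        "config": config.to_dict(),
        "format_version": 1,
    }
    return RunReport(
        descriptives=descriptives,
        univariate=univariate,
        cutpoint=cut_info,
        final_model=final_model,
        calibration=calibration,
        survival=survival,
        evaluation=evaluation,
        provenance=provenance,
        roc_vertices=roc_frame,
    )


def _markdown(report: RunReport) -> str:
    d = report.to_dict()
    lines = [
        "# 7-day survival prognosis report",
        "",
        f"(hrvsurv {d['provenance']['version']}, config {d['provenance']['config_hash']}, "
        f"seed {d['provenance']['seed']}, format v{d['provenance']['format_version']})",
        "",
        "## Cohort",
        "",
        f"- n = {d['descriptives']['n']}, 7-day events = {d['descriptives']['events_7d']} "
        f"({d['descriptives']['event_rate_pct']}%)",
        f"- male {d['descriptives']['male_pct']}%, mean age {d['descriptives']['mean_age']}, "
        f"ECOG 3-4 {d['descriptives']['ecog_34_pct']}%",
        f"- Kaplan-Meier median survival {d['survival']['median_days']} days "
        f"(95% CI {d['survival']['median_ci_95'][0]}-{d['survival']['median_ci_95'][1]})",
        "",
        "## Univariate odds ratios (death within 7 days)",
        "",
        "| Variable | OR | 95% CI | p |",
        "|---|---|---|---|",
    ]
    for name, entry in d["univariate"].items():
        if entry.get("defined"):
            lines.append(
                f"| {name} | {entry['or']:.2f} | {entry['ci_low']:.2f}-{entry['ci_high']:.2f} "
                f"| {entry['p_value']:.3f} |"
            )
        else:
            lines.append(f"| {name} | undefined | - | - |")
    lines += [
        "",
        "## Cutpoint",
        "",
        f"- {d['cutpoint']['index']} dichotomized at {d['cutpoint']['cutoff']} "
        f"(source: {d['cutpoint']['source']})",
        "",
        "## Final multivariable model",
        "",
        "| Term | OR | 95% CI | p |",
        "|---|---|---|---|",
    ]
    for term, entry in d["final_model"]["terms"].items():
        if term == "intercept":
            continue
        lines.append(
            f"| {term} | {entry['or']:.2f} | {entry['ci_low']:.2f}-{entry['ci_high']:.2f} "
            f"| {entry['p_value']:.3f} |"
        )
    if d["calibration"].get("testable"):
        lines.append(
            f"\nHosmer-Lemeshow: chi2 = {d['calibration']['statistic']}, "
            f"df = {d['calibration']['df']}, p = {d['calibration']['p_value']}"
        )
    if "final_model" in d["evaluation"]:
        ev = d["evaluation"]["final_model"]
        m = ev["metrics"]
        lines += [
            "",
            "## Prediction performance (final model)",
            "",
            f"- AUC {ev['auc']} (95% CI {ev['auc_ci_95'][0]}-{ev['auc_ci_95'][1]})",
            f"- closest-top-left threshold {ev['threshold']} "
            f"(distance {ev['topleft_distance']})",
            f"- sensitivity {m['sensitivity']['value']}, specificity {m['specificity']['value']}, "
            f"PPV {m['ppv']['value']}, NPV {m['npv']['value']}",
        ]
    return "\n".join(lines) + "\n"


def write_report(report: RunReport, out_dir) -> Path:
    """Write report.json, report.md and roc_vertices.csv; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    (out / "report.md").write_text(_markdown(report))
    if report.roc_vertices is not None:
        report.roc_vertices.to_csv(out / "roc_vertices.csv", index=False, float_format="%.9g")
    return out
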