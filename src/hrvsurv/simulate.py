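"""Synthetic beat series and patient cohorts with known ground truth.

Two generators back the test strategy of the whole package:

* :func:`simulate_rr` builds R-R (PPI) series as a base interval plus
  sinusoidal oscillations (a respiratory-band component and, optionally, a
  low-frequency component) plus white noise.  Each sinusoid of amplitude
  ``A`` ms contributes a band power of ``A^2 / 2`` ms^2, so every spectral
  index the pipeline computes has a closed-form target.
* :func:`simulate_cohort` draws hospice-admission cohorts whose covariate
  marginals match a published advanced-cancer hospice population (n = 138,
  21% seven-day mortality, 55% male, 64% ECOG 3-4, ...) and whose 7-day
  mortality follows a logistic model in the two final-model predictors,
  lnHFP < 2 and ECOG 3-4, with odds ratios 3.80 and 3.42 by default.

Covariates other than (lnHFP, ECOG) are drawn independently of the outcome
model; the association between the dichotomized lnHFP and ECOG 3-4 is
controlled by a configurable odds ratio (independent by default).  Survival
times are discrete days: events die uniformly on days 1-7, non-events follow
a geometric tail calibrated so the cohort median sits near 20 days, and
follow-up is administratively censored at 180 days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .exceptions import InputError, ValidityError
from .spectral import BeatSeries, EcgTrace

__all__ = [
    "RRSimSpec",
    "GaussianComponent",
    "CovariateMarginals",
    "OutcomeModel",
    "SurvivalTimeModel",
    "CohortSimSpec",
    "simulate_rr",
    "simulate_ecg",
    "simulate_cohort",
    "COHORT_COLUMNS",
]


# --------------------------------------------------------------------------
# R-R series
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RRSimSpec:
    """Recipe for an oscillatory R-R series.

    ``components`` is a sequence of ``(frequency_hz, amplitude_ms)`` pairs;
    defaults place one low-frequency and one respiratory-band sinusoid on an
    800-ms base rhythm.  ``base_rr`` must exceed the summed amplitudes so no
    interval can go non-positive.
    """

    base_rr: float = 800.0
    components: tuple[tuple[float, float], ...] = ((0.1, 8.0), (0.25, 10.0))
    noise_sd: float = 2.0
    duration: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if self.base_rr <= sum(a for _, a in self.components):
            raise ValidityError("component amplitudes must sum below base_rr")
        if self.duration < 288:
            raise ValidityError("duration must cover at least one 288-s segment")
        if self.noise_sd < 0:
            raise ValidityError("noise_sd must be non-negative")


def simulate_rr(spec: RRSimSpec) -> BeatSeries:
    """Generate beats whose PPI is ``base + sum A sin(2 pi f t) + noise``.

    The sinusoids are evaluated at the (accumulated) time of each beat, and
    beat times advance by the realized PPI.  Reproducible per ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    times = [0.0]
    ppi = []
    while times[-1] < spec.duration:
        t = times[-1]
        interval = spec.base_rr + sum(
            amp * math.sin(2.0 * math.pi * freq * t) for freq, amp in spec.components
        )
        if spec.noise_sd > 0:
            interval += spec.noise_sd * rng.standard_normal()
        if interval <= 0:
            raise ValidityError("generated a non-positive PPI; lower noise_sd")
        ppi.append(interval)
        times.append(t + interval / 1000.0)
    return BeatSeries(np.array(times), np.array(ppi))


# P-QRS-T template: (center offset s, amplitude a.u., width s)
_ECG_TEMPLATE = (
    (-0.200, 0.12, 0.030),   # P
    (-0.030, -0.15, 0.010),  # Q
    (0.000, 1.00, 0.008),    # R
    (0.030, -0.20, 0.010),   # S
    (0.250, 0.30, 0.050),    # T
)


def simulate_ecg(beats: BeatSeries, sampling_rate: float = 1024.0) -> EcgTrace:
    """Render a beat series as a synthetic single-lead ECG trace.

    A Gaussian-bump P-QRS-T template is centred at each beat time.  The trace
    ends one median PPI after the final beat, so a recording of beats spaced
    over ``T`` seconds yields about ``T * sampling_rate`` samples.
    """
    if sampling_rate < 200:
        raise InputError("sampling_rate below 200 Hz cannot resolve the QRS")
    if beats.n_beats < 2:
        raise InputError("need at least 2 beats to simulate an ECG")
    duration = beats.beat_times[-1] + float(np.median(beats.ppi)) / 1000.0
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    x = np.zeros(n)
    for beat in beats.beat_times:
        for off, amp, width in _ECG_TEMPLATE:
            c = beat + off
            lo = np.searchsorted(t, c - 5 * width)
            hi = np.searchsorted(t, c + 5 * width)
            if hi > lo:
                x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / width) ** 2)
    return EcgTrace(x, sampling_rate)


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianComponent:
    mean: float
    sd: float


@dataclass(frozen=True)
class CovariateMarginals:
    """Marginal distributions of the admission covariates.

    Binary prevalences and the two-group Gaussian mixtures (component weights
    21% / 79%, the 7-day event split) default to the published hospice
    cohort's descriptive table.  Log-HRV indices are mixtures of the
    event-group and non-event-group Gaussians; lnHFP is dichotomized at 2
    downstream.
    """

    age: GaussianComponent = GaussianComponent(67.6, 12.6)
    male: float = 76 / 138
    muscle_power: GaussianComponent = GaussianComponent(3.5, 1.15)
    cognitive_impairment: float = 57 / 138
    edema: float = 73 / 138
    jaundice: float = 52 / 138
    ascites: float = 43 / 138
    ecog_34: float = 88 / 138
    mixture_weight_event: float = 29 / 138
    ln_tp: tuple[GaussianComponent, GaussianComponent] = (
        GaussianComponent(4.76, 1.59),
        GaussianComponent(5.49, 2.25),
    )
    ln_hfp: tuple[GaussianComponent, GaussianComponent] = (
        GaussianComponent(0.92, 2.26),
        GaussianComponent(2.25, 3.07),
    )
    ln_lf_hf: tuple[GaussianComponent, GaussianComponent] = (
        GaussianComponent(-0.33, 0.82),
        GaussianComponent(-0.18, 0.97),
    )

    def __post_init__(self):
        for name in ("male", "cognitive_impairment", "edema", "jaundice",
                     "ascites", "ecog_34", "mixture_weight_event"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValidityError(f"prevalence {name}={p} outside [0, 1]")

    def lnhfp_lt2_probability(self) -> float:
        """Marginal P(lnHFP < 2) under the mixture."""
        w = self.mixture_weight_event
        ev, ne = self.ln_hfp
        return float(
            w * norm.cdf((2.0 - ev.mean) / ev.sd)
            + (1 - w) * norm.cdf((2.0 - ne.mean) / ne.sd)
        )


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic model for the 7-day death event.

    Log-odds are ``intercept + b1 * [lnHFP < 2] + b2 * [ECOG 3-4]``.  When
    ``intercept`` is None it is solved so the marginal event rate equals
    ``target_event_rate`` (21% by default) given the covariate marginals.
    """

    beta_lnhfp_lt2: float = math.log(3.80)
    beta_ecog34: float = math.log(3.42)
    intercept: float | None = None
    target_event_rate: float = 29 / 138


@dataclass(frozen=True)
class SurvivalTimeModel:
    """Discrete survival-day generator.

    Events die uniformly on days 1-7.  Non-events survive ``7 + G`` days with
    ``G`` geometric; its rate is solved (given the event rate) so the cohort
    median equals ``median_target`` days.  Deaths after ``censor_day`` are
    administratively censored there.
    """

    median_target: float = 20.0
    censor_day: int = 180
    tail_p: float | None = None

    def solve_tail_p(self, event_rate: float) -> float:
        if self.tail_p is not None:
            return self.tail_p
        # P(T > median_target) = (1 - event_rate) * P(G > median_target - 7) = 1/2
        surv_needed = 0.5 / (1.0 - event_rate)
        if not 0 < surv_needed < 1:
            raise ValidityError("event rate incompatible with target median")
        k = self.median_target - 7.0
        return 1.0 - surv_needed ** (1.0 / k)


@dataclass(frozen=True)
class CohortSimSpec:
    """Full recipe for one simulated cohort of ``n`` patients."""

    n: int = 138
    seed: int = 0
    marginals: CovariateMarginals = field(default_factory=CovariateMarginals)
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    survival: SurvivalTimeModel = field(default_factory=SurvivalTimeModel)
    lnhfp_ecog_odds_ratio: float = 1.0

    def __post_init__(self):
        if self.n < 1:
            raise ValidityError("n must be at least 1")
        if self.lnhfp_ecog_odds_ratio <= 0:
            raise ValidityError("association odds ratio must be positive")


#: Column dictionary of the cohort table (CSV) produced by simulate_cohort.
COHORT_COLUMNS = {
    "patient_id": "integer identifier, 1..n",
    "age": "years",
    "sex": "'M' or 'F'",
    "muscle_power": "mean muscle power on the 0-5 MRC scale",
    "cognitive_impairment": "0/1",
    "edema": "0/1",
    "jaundice": "0/1",
    "ascites": "0/1",
    "ecog": "ECOG performance status, grade 1-4",
    "ecog_34": "0/1 indicator of ECOG grade 3 or 4",
    "ln_tp": "natural log of total spectral power (ms^2)",
    "ln_hfp": "natural log of high-frequency power (ms^2)",
    "ln_lf_hf": "natural log of the LFP/HFP ratio",
    "lnhfp_lt2": "0/1 indicator of lnHFP < 2",
    "survival_days": "days from admission to death or censoring",
    "death_observed": "0/1; 0 means administratively censored",
    "event_7d": "0/1 indicator of death within 7 days of admission",
}


def _joint_cell_p11(p1: float, p2: float, theta: float) -> float:
    """P(X1=1, X2=1) for Bernoulli margins p1, p2 with odds ratio theta
    (Plackett construction)."""
    if abs(theta - 1.0) < 1e-12:
        return p1 * p2
    s = 1.0 + (p1 + p2) * (theta - 1.0)
    disc = s * s - 4.0 * theta * (theta - 1.0) * p1 * p2
    return (s - math.sqrt(disc)) / (2.0 * (theta - 1.0))


def solve_intercept(
    marginals: CovariateMarginals, outcome: OutcomeModel, association_or: float = 1.0
) -> float:
    """Intercept giving the target marginal event rate under the generator."""
    if outcome.intercept is not None:
        return outcome.intercept
    p1 = marginals.lnhfp_lt2_probability()
    p2 = marginals.ecog_34
    p11 = _joint_cell_p11(p1, p2, association_or)
    cells = {
        (0, 0): 1.0 - p1 - p2 + p11,
        (1, 0): p1 - p11,
        (0, 1): p2 - p11,
        (1, 1): p11,
    }

    def rate(b0: float) -> float:
        return sum(
            w * expit(b0 + outcome.beta_lnhfp_lt2 * x1 + outcome.beta_ecog34 * x2)
            for (x1, x2), w in cells.items()
        ) - outcome.target_event_rate

    return float(brentq(rate, -20.0, 10.0))


def _draw_mixture_given_side(
    rng: np.random.Generator,
    components: tuple[GaussianComponent, GaussianComponent],
    weight_first: float,
    below: np.ndarray,
    threshold: float = 2.0,
    max_rounds: int = 1_000,
) -> np.ndarray:
    """Sample the Gaussian mixture conditional on the side of a cut, one
    value per entry of the boolean ``below`` array (batched rejection)."""
    n = below.size
    out = np.empty(n)
    pending = np.arange(n)
    for _ in range(max_rounds):
        k = pending.size
        comp_first = rng.random(k) < weight_first
        means = np.where(comp_first, components[0].mean, components[1].mean)
        sds = np.where(comp_first, components[0].sd, components[1].sd)
        draws = means + sds * rng.standard_normal(k)
        ok = (draws < threshold) == below[pending]
        out[pending[ok]] = draws[ok]
        pending = pending[~ok]
        if pending.size == 0:
            return out
    raise ValidityError("mixture conditional sampling failed to converge")


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Draw one cohort table (see :data:`COHORT_COLUMNS`).

    The dichotomized lnHFP and the ECOG 3-4 indicator are drawn jointly with
    the configured odds-ratio association; continuous lnHFP is then sampled
    from the Gaussian mixture conditional on the drawn side of the cut.  The
    7-day event follows the logistic outcome model, and survival days are
    consistent with event status by construction.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.marginals
    n = spec.n

    p1 = m.lnhfp_lt2_probability()
    p2 = m.ecog_34
    p11 = _joint_cell_p11(p1, p2, spec.lnhfp_ecog_odds_ratio)
    if min(p11, p1 - p11, p2 - p11, 1 - p1 - p2 + p11) < -1e-9:
        raise ValidityError("prevalences and association odds ratio incompatible")

    u = rng.random(n)
    lnhfp_lt2 = np.zeros(n, dtype=int)
    ecog_34 = np.zeros(n, dtype=int)
    both = u < p11
    only1 = (u >= p11) & (u < p1)
    only2 = (u >= p1) & (u < p1 + p2 - p11)
    lnhfp_lt2[both | only1] = 1
    ecog_34[both | only2] = 1

    w = m.mixture_weight_event
    ln_hfp = _draw_mixture_given_side(rng, m.ln_hfp, w, below=lnhfp_lt2.astype(bool))

    def mixture(components):
        comp_is_event = rng.random(n) < w
        means = np.where(comp_is_event, components[0].mean, components[1].mean)
        sds = np.where(comp_is_event, components[0].sd, components[1].sd)
        return means + sds * rng.standard_normal(n)

    ln_tp = mixture(m.ln_tp)
    ln_lf_hf = mixture(m.ln_lf_hf)

    intercept = solve_intercept(m, spec.outcome, spec.lnhfp_ecog_odds_ratio)
    eta = (
        intercept
        + spec.outcome.beta_lnhfp_lt2 * lnhfp_lt2
        + spec.outcome.beta_ecog34 * ecog_34
    )
    event = (rng.random(n) < expit(eta)).astype(int)

    event_rate = float(
        sum(
            wgt * expit(intercept + spec.outcome.beta_lnhfp_lt2 * x1
                        + spec.outcome.beta_ecog34 * x2)
            for (x1, x2), wgt in {
                (0, 0): 1 - p1 - p2 + p11, (1, 0): p1 - p11,
                (0, 1): p2 - p11, (1, 1): p11,
            }.items()
        )
    )
    tail_p = spec.survival.solve_tail_p(event_rate)
    days = np.where(
        event == 1,
        rng.integers(1, 8, size=n),
        7 + rng.geometric(tail_p, size=n),
    ).astype(int)
    censored = days > spec.survival.censor_day
    days = np.minimum(days, spec.survival.censor_day)

    ecog = np.where(ecog_34 == 1, rng.integers(3, 5, size=n), rng.integers(1, 3, size=n))
    return pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "age": np.round(m.age.mean + m.age.sd * rng.standard_normal(n), 1),
            "sex": np.where(rng.random(n) < m.male, "M", "F"),
            "muscle_power": np.clip(
                np.round(m.muscle_power.mean + m.muscle_power.sd * rng.standard_normal(n), 1),
                0.0,
                5.0,
            ),
            "cognitive_impairment": (rng.random(n) < m.cognitive_impairment).astype(int),
            "edema": (rng.random(n) < m.edema).astype(int),
            "jaundice": (rng.random(n) < m.jaundice).astype(int),
            "ascites": (rng.random(n) < m.ascites).astype(int),
            "ecog": ecog,
            "ecog_34": ecog_34,
            "ln_tp": ln_tp,
            "ln_hfp": ln_hfp,
            "ln_lf_hf": ln_lf_hf,
            "lnhfp_lt2": lnhfp_lt2,
            "survival_days": days,
            "death_observed": (~censored).astype(int),
            "event_7d": event,
        }
    )
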