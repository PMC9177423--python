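"""Age at clonal onset under a two-phase Wright-Fisher growth model.

A clone observed to grow at annual logit-scale rate ``b_total`` with birth
offset ``u`` is back-extrapolated to a single founding cell in a population
of ``n`` HSCs. The naive deterministic extrapolation gives

    t0 = (log(1/n) - u) / b_total

while the two-phase model first finds when the clone entered deterministic
growth, then subtracts the expected duration of the initial stochastic
(drift-dominated) phase:

    t0_adjusted = t0 + log(g / b_total) / b_total - 1 / b_total

with ``g`` the number of HSC generations per year. Onsets earlier than
conception (age -1) are infeasible; the smallest growth rate that places
onset exactly at conception is the clone's minimal historical growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logit

__all__ = [
    "OnsetEstimate",
    "HistoricalGrowth",
    "age_at_onset",
    "minimal_historical_growth",
    "detection_latency",
    "onset_table",
]

DEFAULT_N_HSC = 50_000
DEFAULT_GENERATIONS_PER_YEAR = 2.0
CONCEPTION_AGE = -1.0  # feasibility bound for clone onset, in years
DEFAULT_DETECTION_VAF = 0.002


class OnsetUndefinedError(ValueError):
    """Raised when onset algebra is requested for a non-growing clone."""


@dataclass(frozen=True)
class OnsetEstimate:
    t0: float
    t0_adjusted: float
    feasible: bool
    n_hsc: int
    generations_per_year: float


@dataclass(frozen=True)
class HistoricalGrowth:
    observed_rate: float
    minimal_historical_rate: float
    capped: bool

    @property
    def ratio(self) -> float:
        """Observed / minimal historical growth; <= 1 when onset was infeasible."""
        return self.observed_rate / self.minimal_historical_rate


def _t0(b: np.ndarray | float, u: np.ndarray | float, n_hsc: int):
    return (math.log(1.0 / n_hsc) - u) / b


def _t0_adjusted(b, u, n_hsc, g):
    return _t0(b, u, n_hsc) + np.log(g / b) / b - 1.0 / b


def age_at_onset(
    b_total: float,
    u: float,
    n_hsc: int = DEFAULT_N_HSC,
    g: float = DEFAULT_GENERATIONS_PER_YEAR,
    conception: float = CONCEPTION_AGE,
) -> OnsetEstimate:
    """Closed-form onset age for a clone with fitted growth ``b_total`` and
    birth offset ``u``. ``feasible`` is True when the stochastic-phase
    corrected onset falls after conception."""
    if b_total <= 0:
        raise OnsetUndefinedError("onset undefined for b_total <= 0 (clone never grew)")
    if g <= 0:
        raise ValueError("g must be > 0")
    t0 = float(_t0(b_total, u, n_hsc))
    t0_adj = float(_t0_adjusted(b_total, u, n_hsc, g))
    return OnsetEstimate(
        t0=t0,
        t0_adjusted=t0_adj,
        feasible=t0_adj > conception,
        n_hsc=n_hsc,
        generations_per_year=g,
    )


def minimal_historical_growth(
    latest_vaf: float,
    age_t: float,
    observed_b: float,
    n_hsc: int = DEFAULT_N_HSC,
    g: float = DEFAULT_GENERATIONS_PER_YEAR,
    conception: float = CONCEPTION_AGE,
    b_max: float = 10.0,
    tol: float = 1e-8,
) -> HistoricalGrowth:
    """Smallest lifelong growth rate consistent with the observed VAF.

    If back-extrapolating at ``observed_b`` already places onset after
    conception, the observed rate is returned unchanged. Otherwise the rate
    is raised until a clone founded exactly at conception, growing through
    the two-phase model with offset ``u(b) = logit(latest_vaf) - b * age_t``,
    reaches the observed VAF; the root is found by bracketed bisection.
    """
    if not 0 < latest_vaf < 1:
        raise ValueError("latest_vaf must be in (0, 1)")
    if age_t <= 0:
        raise ValueError("age_t must be > 0")
    lv = float(logit(latest_vaf))

    def onset_gap(b):
        return float(_t0_adjusted(b, lv - b * age_t, n_hsc, g)) - conception

    if observed_b > 0 and onset_gap(observed_b) > 0:
        return HistoricalGrowth(
            observed_rate=observed_b, minimal_historical_rate=observed_b, capped=False
        )
    lo = max(observed_b, 1e-4)
    if onset_gap(b_max) < 0:
        raise ValueError("no feasible growth rate in (0, 10] per year")
    while onset_gap(lo) > 0:  # observed_b <= 0: walk down to a negative bracket
        lo /= 2.0
        if lo < 1e-12:
            raise ValueError("could not bracket the minimal historical rate")
    root = float(brentq(onset_gap, lo, b_max, xtol=tol))
    return HistoricalGrowth(
        observed_rate=observed_b, minimal_historical_rate=root, capped=True
    )


def detection_latency(
    b_total: float,
    u: float,
    threshold_vaf: float = DEFAULT_DETECTION_VAF,
    n_hsc: int = DEFAULT_N_HSC,
    g: float = DEFAULT_GENERATIONS_PER_YEAR,
) -> float:
    """Years between clone foundation (t0_adjusted) and the age at which the
    fitted trajectory crosses the peripheral-blood detection threshold."""
    if not 0 < threshold_vaf < 0.5:
        raise ValueError("threshold_vaf must be in (0, 0.5)")
    if b_total <= 0:
        raise OnsetUndefinedError("clone never reaches the detection threshold")
    t_detect = (float(logit(threshold_vaf)) - u) / b_total
    onset = age_at_onset(b_total, u, n_hsc=n_hsc, g=g)
    return t_detect - onset.t0_adjusted


def onset_table(
    fit,
    n_hsc: int = DEFAULT_N_HSC,
    g: float = DEFAULT_GENERATIONS_PER_YEAR,
    conception: float = CONCEPTION_AGE,
    threshold_vaf: float = DEFAULT_DETECTION_VAF,
    last_ages: dict[str, float] | None = None,
    mass: float = 0.90,
    min_valid_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-clone onset summary with posterior-propagated intervals.

    The closed forms are applied to every posterior draw of (b_total, u);
    draws with non-positive growth are dropped (clones where more than
    ``1 - min_valid_fraction`` of draws are non-growing report NaN). When
    ``last_ages`` maps clone_id to the clone's final observed age and VAF
    draws are available, the minimal historical rate is solved per clone at
    the posterior-mean terminal VAF.
    """
    from clonekinetics.model import hpdi

    rows = []
    for cid in fit.clone_ids:
        b = fit.b_total(cid)
        u = fit.u_draws(cid)
        valid = b > 1e-6
        if valid.mean() < min_valid_fraction or valid.sum() < 10:
            rows.append((cid, *[float("nan")] * 9, False))
            continue
        bb, uu = b[valid], u[valid]
        t0 = _t0(bb, uu, n_hsc)
        t0a = _t0_adjusted(bb, uu, n_hsc, g)
        latency = (logit(threshold_vaf) - uu) / bb - t0a
        t0a_capped = np.maximum(t0a, conception)
        iv = hpdi(t0a, mass)
        b_mean = float(np.mean(bb))
        u_mean = float(np.mean(uu))
        min_hist = float("nan")
        capped = False
        if last_ages and cid in last_ages:
            age_last = last_ages[cid]
            q_last = fit.vaf_ceiling / (1.0 + math.exp(-(b_mean * age_last + u_mean)))
            hg = minimal_historical_growth(
                q_last, age_last, b_mean, n_hsc=n_hsc, g=g, conception=conception
            )
            min_hist, capped = hg.minimal_historical_rate, hg.capped
        rows.append(
            (
                cid,
                float(np.mean(t0)),
                float(np.mean(t0a)),
                float(np.mean(t0a_capped)),
                iv.lower,
                iv.upper,
                float(np.mean(t0a > conception)),
                float(np.mean(latency)),
                min_hist,
                b_mean,
                capped,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "clone_id",
            "t0_mean",
            "t0_adjusted_mean",
            "t0_adjusted_capped_mean",
            "t0_adjusted_hpdi_low",
            "t0_adjusted_hpdi_high",
            "feasible_posterior_prob",
            "latency_mean",
            "minimal_historical_rate",
            "b_total_mean",
            "capped",
        ],
    )
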