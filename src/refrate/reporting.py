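"""Posterior summaries: relative-risk tables, intervention effects,
interaction-plot predictions and raw-data summaries.

Coefficients of the referral model are reported as relative risks
(exponentiated log rate ratios) with equal-tailed credible intervals; an
effect is called significant at the 5% level when its 95% interval
excludes 1.  The full-intervention effect for a year combines the
coverage main effect with that year's interaction *per posterior draw*
before exponentiating, which is why published percentage changes need not
match powers of the rounded relative risks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm import GLMMPosterior, ReferralPanel

__all__ = [
    "EffectSummary",
    "rr_summary",
    "percent_change",
    "full_intervention_effect",
    "interaction_predictions",
    "summarize_annual",
    "compare_adjustment",
    "scale_up_reduction",
]


@dataclass(frozen=True)
class EffectSummary:
    """One coefficient on the relative-risk scale."""

    parameter: str
    rr: float
    lower: float
    upper: float
    significant: bool

    def __post_init__(self) -> None:
        if not self.lower <= self.rr <= self.upper:
            raise ValueError("interval must bracket the median")


def rr_summary(posterior: GLMMPosterior, level: float = 0.95) -> pd.DataFrame:
    """Relative-risk table: median and equal-tailed interval per coefficient.

    Relative risks are rounded to 3 decimal places, the convention for
    near-unity per-percentage-point effects; significance (interval
    excluding 1) is assessed on the unrounded interval.
    """
    if posterior.n_draws < 100:
        raise ValueError("need at least 100 retained draws to summarise")
    alpha = (1.0 - level) / 2.0
    rows = []
    for k, name in enumerate(posterior.coef_names):
        rr = np.exp(posterior.gamma[:, k])
        lo, med, hi = np.percentile(rr, [100 * alpha, 50, 100 * (1 - alpha)])
        rows.append(
            {
                "parameter": name,
                "rr": round(float(med), 3),
                "lower": round(float(lo), 3),
                "upper": round(float(hi), 3),
                "significant": bool(lo > 1.0 or hi < 1.0),
            }
        )
    return pd.DataFrame(rows)


def percent_change(rr: float) -> float:
    """(rr - 1) x 100, to 1 decimal place: the narrative form of an RR."""
    if rr <= 0:
        raise ValueError("relative risk must be positive")
    return round((rr - 1.0) * 100.0, 1)


def full_intervention_effect(
    posterior: GLMMPosterior,
    year: int,
    coverage_delta: float = 100.0,
    level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Percent change in referral rate for a coverage increase in a year.

    Per draw, the combined per-percentage-point coefficient (coverage main
    effect plus, for non-baseline years, that year's interaction) is
    multiplied by ``coverage_delta`` and exponentiated; the percent
    changes are then summarised by their median and equal-tailed interval.
    ``coverage_delta = 100`` contrasts full intervention with none.
    """
    if not 0.0 < coverage_delta <= 100.0:
        raise ValueError("coverage_delta must lie in (0, 100]")
    names = list(posterior.coef_names)
    combined = posterior.gamma[:, names.index("mbrn")].copy()
    if year != posterior.baseline_year:
        key = f"mbrn_{year}"
        if key not in names:
            raise ValueError(f"no coverage interaction for year {year}")
        combined = combined + posterior.gamma[:, names.index(key)]
    pct = (np.exp(combined * coverage_delta) - 1.0) * 100.0
    alpha = (1.0 - level) / 2.0
    lo, med, hi = np.percentile(pct, [100 * alpha, 50, 100 * (1 - alpha)])
    return round(float(med), 1), (round(float(lo), 1), round(float(hi), 1))


def interaction_predictions(
    posterior: GLMMPosterior,
    design_medians: dict,
    coverage_levels: tuple = (0.0, 100.0),
    level: float = 0.95,
) -> pd.DataFrame:
    """Predicted referrals per 100 patients by year and coverage level.

    ``design_medians`` maps the non-year covariates (age65_74, age75plus,
    male, distance_km, imd) to their data-set medians.  For each retained
    draw, year and coverage level, the linear predictor is evaluated with
    the year indicator set, coverage and its interaction at the requested
    level, the random intercept at its prior mean 0, and the rate scaled
    to 100 patients.  Returns one row per (year, coverage) with the
    posterior median and equal-tailed interval.
    """
    needed = ("age65_74", "age75plus", "male", "distance_km", "imd")
    missing = [c for c in needed if c not in design_medians]
    if missing:
        raise ValueError(f"design medians missing for: {missing}")
    names = list(posterior.coef_names)
    alpha = (1.0 - level) / 2.0
    rows = []
    for year in posterior.years:
        for cov in coverage_levels:
            d = np.zeros(len(names))
            d[names.index("intercept")] = 1.0
            for c in needed:
                d[names.index(c)] = design_medians[c]
            if year != posterior.baseline_year:
                d[names.index(f"year_{year}")] = 1.0
                d[names.index(f"mbrn_{year}")] = cov
            d[names.index("mbrn")] = cov
            rate = 100.0 * np.exp(posterior.gamma @ d)
            lo, med, hi = np.percentile(rate, [100 * alpha, 50, 100 * (1 - alpha)])
            rows.append(
                {
                    "year": year,
                    "coverage_pct": cov,
                    "rate_per_100": float(med),
                    "lower": float(lo),
                    "upper": float(hi),
                }
            )
    return pd.DataFrame(rows)


def summarize_annual(referrals: ReferralPanel, n_areas: int | None = None) -> pd.DataFrame:
    """Per-year referral totals and the average per area (2 dp)."""
    n_areas = n_areas or referrals.n_areas
    if n_areas <= 0:
        raise ValueError("n_areas must be positive")
    totals = referrals.data.groupby("year")["y"].sum()
    return pd.DataFrame(
        {
            "year": totals.index,
            "total": totals.to_numpy(dtype=int),
            "average_per_area": np.round(totals.to_numpy() / n_areas, 2),
        }
    ).reset_index(drop=True)


def compare_adjustment(raw_totals, adjusted_totals) -> np.ndarray:
    """Signed percentage difference (adjusted - raw) / raw x 100, 1 dp."""
    raw = np.asarray(raw_totals, dtype=float)
    adj = np.asarray(adjusted_totals, dtype=float)
    if raw.shape != adj.shape:
        raise ValueError("series must have equal length")
    if (raw <= 0).any():
        raise ValueError("raw totals must be positive")
    return np.round((adj - raw) / raw * 100.0, 1)


def scale_up_reduction(
    rate_none_per_100: float, rate_full_per_100: float, population: float
) -> float:
    """Annual referral difference implied by a rate gap over a population.

    Scales the per-100-patient rate difference between no-intervention and
    full-intervention predictions up to a patient population, rounded to
    the nearest whole referral.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    return round((rate_none_per_100 - rate_full_per_100) / 100.0 * population)
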