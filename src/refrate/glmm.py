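"""Stage two: Poisson random-intercept model of outpatient referral rates.

Annual referral counts Y_it for area i and study year t are modelled as

    Y_it ~ Poisson( R_hat_it * exp(d_it' gamma + Z_i) ),   Z_i ~ N(0, kappa^2)

where the offset R_hat_it is the stage-one adjusted count of chronic
respiratory disease patients, giving the coefficients a rate-per-patient
interpretation.  The covariates d_it comprise area demography (percentage
of adults aged 65-74 and 75+, percentage male), road distance to the
nearest hospital with respiratory outpatient clinics, deprivation score,
study-year factor levels (first year as baseline), the percentage of the
area's registered population at a practice that joined the integrated-care
network in 2017 (computed for every year, pre-intervention included, to
absorb baseline differences), and year-by-coverage interactions — the
interaction terms carry the intervention signal.

Stage-one uncertainty is propagated by re-drawing the offset each MCMC
iteration: one stage-one posterior draw index is selected uniformly at
random and the adjusted counts for imputed-denominator cells recomputed
before the Poisson likelihood is evaluated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import MCMCConfig
from .population import AdjustedDenominator

logger = logging.getLogger(__name__)

__all__ = [
    "ReferralPanel",
    "GLMMPosterior",
    "build_design",
    "classify_mbrn",
    "fit_referral_glmm",
]

GAMMA_PRIOR_VAR = 1e5
IG_SHAPE = 1.0
IG_RATE = 0.01

#: covariate columns expected in a referral panel table
COVARIATE_COLS = ("age65_74", "age75plus", "male", "distance_km", "imd", "mbrn_pct")


def classify_mbrn(coverage_percent: float) -> str:
    """Dichotomise network coverage: "MBRN" iff strictly above 50 percent."""
    if not 0.0 <= coverage_percent <= 100.0:
        raise ValueError(f"coverage must lie in [0, 100], got {coverage_percent}")
    return "MBRN" if coverage_percent > 50.0 else "non-MBRN"


def build_design(
    covariates: pd.DataFrame, baseline_year: int | None = None
) -> pd.DataFrame:
    """Expand a covariate table into the fixed-effect design block.

    ``covariates`` has one row per area-year with columns ``year`` plus
    :data:`COVARIATE_COLS` (percentages on the 0-100 scale, distance in
    km).  The returned frame has, in fixed order: intercept, the two age
    percentages, percentage male, distance, deprivation score, one 0/1
    indicator per non-baseline year, the coverage main effect, and one
    coverage-by-year product per non-baseline year.  With 8 study years
    this is 21 columns, so each coefficient is a per-unit (for percentages,
    per-percentage-point) log rate ratio.
    """
    years = sorted(covariates["year"].unique())
    if baseline_year is None:
        baseline_year = years[0]
    if baseline_year not in years:
        raise ValueError(f"baseline year {baseline_year} not present in table")
    unknown = set(covariates["year"]) - set(years)
    if unknown:
        raise ValueError(f"unknown year labels: {sorted(unknown)}")
    out = pd.DataFrame(index=covariates.index)
    out["intercept"] = 1.0
    for col in ("age65_74", "age75plus", "male", "distance_km", "imd"):
        out[col] = covariates[col].to_numpy(dtype=float)
    non_base = [y for y in years if y != baseline_year]
    for y in non_base:
        out[f"year_{y}"] = (covariates["year"] == y).astype(float)
    out["mbrn"] = covariates["mbrn_pct"].to_numpy(dtype=float)
    for y in non_base:
        out[f"mbrn_{y}"] = out[f"year_{y}"] * out["mbrn"]
    return out


@dataclass
class ReferralPanel:
    """Referral counts and covariates, one row per area-year.

    ``data`` must contain columns (area_id, year, y) plus
    :data:`COVARIATE_COLS`; rows are sorted area-major (all years of the
    first area, then the next) so arrays reshape cleanly to (N, T).
    """

    data: pd.DataFrame
    baseline_year: int | None = None

    def __post_init__(self) -> None:
        need = {"area_id", "year", "y", *COVARIATE_COLS}
        missing = need - set(self.data.columns)
        if missing:
            raise ValueError(f"referral table lacks columns: {sorted(missing)}")
        df = self.data.copy()
        order = {a: k for k, a in enumerate(pd.unique(df["area_id"]))}
        df = df.sort_values(
            ["area_id", "year"], key=lambda s: s.map(order) if s.name == "area_id" else s
        ).reset_index(drop=True)
        y = df["y"].to_numpy()
        if (y < 0).any() or not np.allclose(y, np.round(y)):
            raise ValueError("referral counts must be nonnegative integers")
        for col in ("age65_74", "age75plus", "male", "mbrn_pct"):
            v = df[col].to_numpy(dtype=float)
            if (v < 0).any() or (v > 100).any():
                raise ValueError(f"{col} must lie in [0, 100]")
        if (df["distance_km"].to_numpy(dtype=float) < 0).any():
            raise ValueError("distance must be nonnegative")
        self.data = df
        if self.baseline_year is None:
            self.baseline_year = int(df["year"].min())

    @property
    def area_ids(self) -> tuple:
        return tuple(pd.unique(self.data["area_id"]))

    @property
    def years(self) -> tuple:
        return tuple(sorted(self.data["year"].unique()))

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def counts(self) -> np.ndarray:
        """(N, T) referral counts."""
        return self.data["y"].to_numpy(dtype=float).reshape(self.n_areas, -1)

    def design(self) -> pd.DataFrame:
        return build_design(self.data, baseline_year=self.baseline_year)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "ReferralPanel":
        return cls(pd.read_csv(path), **kw)


@dataclass
class GLMMPosterior:
    """Retained draws from the referral-rate random-intercept model."""

    gamma: np.ndarray  # (n_draws, n_coef)
    kappa2: np.ndarray  # (n_draws,)
    Z: np.ndarray  # (n_draws, N)
    coef_names: tuple
    area_ids: tuple
    years: tuple
    baseline_year: int
    acceptance: dict = field(default_factory=dict)
    config: MCMCConfig | None = None

    @property
    def n_draws(self) -> int:
        return self.gamma.shape[0]

    def to_csv(self, path: str | Path) -> None:
        cols = {name: self.gamma[:, i] for i, name in enumerate(self.coef_names)}
        cols["kappa2"] = self.kappa2
        pd.DataFrame(cols).to_csv(path, index=False)


def _poisson_loglik(y: np.ndarray, log_off: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Per-cell Poisson log-likelihood, constant term dropped."""
    log_mu = log_off + eta
    return y * log_mu - np.exp(log_mu)


def fit_referral_glmm(
    referrals: ReferralPanel,
    offset: AdjustedDenominator | np.ndarray,
    mcmc: MCMCConfig | None = None,
    offset_seed: int | None = None,
    fixed: dict | None = None,
) -> GLMMPosterior:
    """Metropolis-within-Gibbs for the Poisson random-intercept model.

    The fixed effects gamma are updated jointly by random-walk Metropolis
    whose proposal covariance is the inverse Fisher information of a
    fixed-offset Poisson regression (scale adapted during burn-in); each
    area intercept Z_i has an independent univariate random walk, updated
    for all areas simultaneously since their conditionals are independent;
    kappa^2 is conjugate inverse-gamma.

    ``offset`` is either the stage-one :class:`AdjustedDenominator` — in
    which case one draw index is re-selected uniformly at random *every
    iteration* and the offset recalculated before the likelihood is
    evaluated, so every stage-one draw is represented with equal weight
    and the chain spreads over the mixture of fixed-offset posteriors
    (multiple-imputation semantics) — or a fixed (N, T) array.  The index
    stream comes from a generator seeded by ``offset_seed``, kept separate
    from the parameter chain so resampling never perturbs the
    parameter-proposal stream.

    ``fixed`` may clamp ``Z`` (length-N array) and/or ``kappa2``; their
    update steps are then skipped (restricted fits and oracle checks).
    """
    mcmc = mcmc or MCMCConfig(iterations=30_000, burn_in=10_000, thinning=10)
    fixed = dict(fixed or {})
    unknown = set(fixed) - {"Z", "kappa2"}
    if unknown:
        raise ValueError(f"cannot fix unknown parameters: {sorted(unknown)}")
    rng = np.random.default_rng(mcmc.seed)
    rng_off = np.random.default_rng(
        mcmc.seed + 1_000_003 if offset_seed is None else offset_seed
    )

    n, years = referrals.n_areas, referrals.years
    t = len(years)
    y = referrals.counts  # (N, T)
    D = referrals.design()
    names = tuple(D.columns)
    Dm = D.to_numpy(dtype=float)  # (N*T, p) area-major rows
    p = Dm.shape[1]

    # align the offset draws with the referral cells
    if isinstance(offset, AdjustedDenominator):
        if tuple(offset.area_ids) != tuple(referrals.area_ids):
            raise ValueError("offset areas do not match referral areas")
        cols = [offset.years.index(yy) for yy in years]
        off_draws = offset.draws[:, :, cols]  # (n_draws, N, T)
    else:
        off_draws = np.asarray(offset, dtype=float)[None, :, :]
    if off_draws.shape[1:] != (n, t):
        raise ValueError(f"offset must cover all {n}x{t} cells")
    if (off_draws <= 0).any():
        raise ValueError("every offset cell must be positive")
    n_off = off_draws.shape[0]
    log_off = np.log(off_draws)  # (n_off, N, T)
    log_off_med = np.log(np.median(off_draws, axis=0))

    # proposal geometry from a fixed-offset Poisson regression
    glm = sm.GLM(
        y.ravel(), Dm, family=sm.families.Poisson(), offset=log_off_med.ravel()
    ).fit()
    prop_chol = np.linalg.cholesky(np.asarray(glm.cov_params()))
    gamma = np.asarray(glm.params)
    Z = np.asarray(fixed["Z"], dtype=float) if "Z" in fixed else np.zeros(n)
    kappa2 = float(fixed.get("kappa2", 0.02))

    # proposal cov approximates the posterior cov, so start near 2.38/sqrt(d)
    step_g = 2.38 / np.sqrt(p)
    step_z = 0.5
    acc_g = acc_z = 0
    win_g = win_z = 0
    cnt = 0
    n_keep = mcmc.n_retained
    out_g = np.empty((n_keep, p))
    out_k = np.empty(n_keep)
    out_z = np.empty((n_keep, n))
    keep = 0
    post_n = 0
    post_acc_g = 0
    post_acc_z = 0.0

    eta_fix = (Dm @ gamma).reshape(n, t)
    for it in range(mcmc.iterations):
        adapting = mcmc.adapt and it < mcmc.burn_in
        j = rng_off.integers(n_off) if n_off > 1 else 0
        off = log_off[j]  # (N, T)

        # --- gamma block (random-walk Metropolis, preconditioned)
        prop = gamma + step_g * (prop_chol @ rng.standard_normal(p))
        eta_prop = (Dm @ prop).reshape(n, t)
        ll_cur = _poisson_loglik(y, off, eta_fix + Z[:, None]).sum()
        ll_prop = _poisson_loglik(y, off, eta_prop + Z[:, None]).sum()
        lp = (gamma @ gamma - prop @ prop) / (2 * GAMMA_PRIOR_VAR)
        if np.log(rng.uniform()) < ll_prop - ll_cur + lp:
            gamma, eta_fix = prop, eta_prop
            acc_g += 1
            post_acc_g += not adapting
        win_g += 1

        # --- Z block (independent univariate random walks, vectorised)
        if "Z" not in fixed:
            z_prop = Z + step_z * rng.standard_normal(n)
            ll_cur_a = _poisson_loglik(y, off, eta_fix + Z[:, None]).sum(axis=1)
            ll_prop_a = _poisson_loglik(y, off, eta_fix + z_prop[:, None]).sum(axis=1)
            lp_a = (Z**2 - z_prop**2) / (2 * kappa2)
            accept_a = np.log(rng.uniform(size=n)) < ll_prop_a - ll_cur_a + lp_a
            Z = np.where(accept_a, z_prop, Z)
            acc_z += accept_a.mean()
            post_acc_z += accept_a.mean() if not adapting else 0.0
        win_z += 1

        # --- kappa^2 (conjugate inverse-gamma)
        if "kappa2" not in fixed:
            kappa2 = 1.0 / rng.gamma(
                IG_SHAPE + 0.5 * n, 1.0 / (IG_RATE + 0.5 * float(Z @ Z))
            )

        if adapting and win_g == 50:
            step_g *= np.exp(0.3 * (acc_g / win_g - 0.234))
            step_z *= np.exp(0.3 * (acc_z / win_z - 0.44))
            acc_g = 0
            acc_z = 0.0
            win_g = win_z = 0
        if not adapting:
            post_n += 1

        if not np.isfinite(kappa2):
            raise FloatingPointError(f"divergent chain at iteration {it}")

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thinning == 0:
            if keep < n_keep:
                out_g[keep] = gamma
                out_k[keep] = kappa2
                out_z[keep] = Z
                keep += 1

    acceptance = {
        "gamma": post_acc_g / max(post_n, 1),
        "Z": float(post_acc_z) / max(post_n, 1),
    }
    logger.info("stage-two acceptance rates: %s", acceptance)
    return GLMMPosterior(
        gamma=out_g[:keep],
        kappa2=out_k[:keep],
        Z=out_z[:keep],
        coef_names=names,
        area_ids=referrals.area_ids,
        years=years,
        baseline_year=int(referrals.baseline_year),
        acceptance=acceptance,
        config=mcmc,
    )
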