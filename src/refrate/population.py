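"""Stage one: correcting biased routinely-collected population denominators.

Routine primary-care registers (the "CDW" counts ``P_cdw``) systematically
mis-state the true GP-registered adult population of each small area:
practices outside the data-sharing agreement leave spatially clustered
gaps, de-registrations are only proxied so the error compounds going back
in time, and address histories are not kept.  Official estimates
(``P_nhs``) exist only for later years.

The adjustment model regresses the official log-count on the routine count
and measurable error sources, with spatio-temporal random effects:

    log(P_nhs_it) ~ N(x_it' beta + S_it,  sigma^2)
    S_t | S_{t+1} ~ N(rho_T S_{t+1},  tau^2 Q(rho_S, W)^{-1}),  t = 1..T
    S_{T+1}       ~ N(0,  tau^2 Q(rho_S, W)^{-1})

where Q is the Leroux precision matrix.  The autoregression is conditioned
in *reverse* time order: the registers are extracted retrospectively, so
the most recent year is the most accurate and error accumulates backwards.
Years with no official estimate are treated as missing responses and drawn
from their posterior predictive distribution at every MCMC iteration.

The chronic-respiratory-disease (CRD) patient count used downstream as a
rate denominator is then rescaled cell-wise,

    R_hat_it = R_cdw_it / P_cdw_it * P_nhs_it,

holding the register prevalence fixed; for missing years P_nhs is replaced
by exp of a posterior-predictive draw, one per retained iteration, so the
denominator carries the full imputation uncertainty forward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import MCMCConfig
from .spatial import AreaLattice, lag1_autocorrelation, morans_i

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationPanel",
    "STCARPosterior",
    "AdjustedDenominator",
    "nhs_population_estimate",
    "glm_residual_diagnostics",
    "fit_stcar",
    "adjust_denominator",
]

#: weakly informative defaults: flat-ish Gaussian slopes, IG(1, 0.01) variances
BETA_PRIOR_VAR = 1e5
IG_SHAPE = 1.0
IG_RATE = 0.01

STAGE1_COVARIATES = ("intercept", "log_p_cdw", "time", "nonsharing_prop")


@dataclass
class PopulationPanel:
    """Area-by-year panel of register counts and stage-one covariates.

    Arrays are (N areas, Tp time points); ``p_nhs`` may contain NaN for
    years with no official estimate (typically the first two study years).
    """

    area_ids: tuple
    years: tuple
    p_cdw: np.ndarray
    p_nhs: np.ndarray
    r_cdw: np.ndarray
    nonsharing_prop: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.area_ids), len(self.years))
        for name in ("p_cdw", "p_nhs", "r_cdw", "nonsharing_prop"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            setattr(self, name, arr)
        if np.isnan(self.p_cdw).any() or np.isnan(self.r_cdw).any():
            raise ValueError("missing values are only allowed in p_nhs")
        if (self.p_cdw < 0).any() or (self.r_cdw < 0).any():
            raise ValueError("counts must be nonnegative")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.p_nhs) < 0:
                raise ValueError("counts must be nonnegative")
        if (self.r_cdw > self.p_cdw).any():
            raise ValueError("r_cdw cannot exceed p_cdw")

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def missing_mask(self) -> np.ndarray:
        """(N, Tp) boolean mask of cells with no official estimate."""
        return np.isnan(self.p_nhs)

    def design(self) -> np.ndarray:
        """Stage-one covariates x_it, shape (N, Tp, 4).

        Columns: intercept, log routine count, linear time index 1..Tp,
        proportion of the area's registered population at a non-sharing
        practice.
        """
        n, tp = self.n_areas, self.n_years
        X = np.empty((n, tp, 4))
        X[:, :, 0] = 1.0
        X[:, :, 1] = np.log(self.p_cdw)
        X[:, :, 2] = np.arange(1, tp + 1)[None, :]
        X[:, :, 3] = self.nonsharing_prop
        return X

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per area-year."""
        n, tp = self.n_areas, self.n_years
        return pd.DataFrame(
            {
                "area_id": np.repeat(self.area_ids, tp),
                "year": np.tile(self.years, n),
                "p_cdw": self.p_cdw.ravel(),
                "p_nhs": self.p_nhs.ravel(),
                "r_cdw": self.r_cdw.ravel(),
                "nonsharing_prop": self.nonsharing_prop.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PopulationPanel":
        area_ids = tuple(pd.unique(df["area_id"]))
        years = tuple(sorted(pd.unique(df["year"])))
        wide = {}
        for col in ("p_cdw", "p_nhs", "r_cdw", "nonsharing_prop"):
            piv = df.pivot(index="area_id", columns="year", values=col)
            wide[col] = piv.loc[list(area_ids), list(years)].to_numpy(dtype=float)
        return cls(area_ids=area_ids, years=years, **wide)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PopulationPanel":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class STCARPosterior:
    """Retained MCMC draws from the spatio-temporal adjustment model."""

    beta: np.ndarray  # (n_draws, 4)
    sigma2: np.ndarray  # (n_draws,)
    tau2: np.ndarray  # (n_draws,)
    rho_s: np.ndarray  # (n_draws,)
    rho_t: np.ndarray  # (n_draws,)
    S: np.ndarray  # (n_draws, N, Tp)
    log_p_nhs_pred: np.ndarray  # (n_draws, n_missing) posterior predictive
    missing_mask: np.ndarray  # (N, Tp)
    area_ids: tuple
    years: tuple
    acceptance: dict = field(default_factory=dict)
    config: MCMCConfig | None = None

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def summary(self) -> pd.DataFrame:
        rows = []
        names = list(STAGE1_COVARIATES) + ["sigma2", "tau2", "rho_s", "rho_t"]
        draws = [self.beta[:, i] for i in range(self.beta.shape[1])]
        draws += [self.sigma2, self.tau2, self.rho_s, self.rho_t]
        for name, d in zip(names, draws):
            lo, med, hi = np.percentile(d, [2.5, 50, 97.5])
            rows.append({"parameter": name, "median": med, "lower": lo, "upper": hi})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        """Columnar store of the scalar-parameter draws."""
        cols = {f"beta_{n}": self.beta[:, i] for i, n in enumerate(STAGE1_COVARIATES)}
        cols.update(
            sigma2=self.sigma2, tau2=self.tau2, rho_s=self.rho_s, rho_t=self.rho_t
        )
        pd.DataFrame(cols).to_csv(path, index=False)


@dataclass
class AdjustedDenominator:
    """Per-draw adjusted CRD patient counts R_hat (n_draws, N, Tp)."""

    draws: np.ndarray
    area_ids: tuple
    years: tuple

    @property
    def median(self) -> np.ndarray:
        """(N, Tp) posterior median of the adjusted count."""
        return np.median(self.draws, axis=0)

    def summary_frame(self) -> pd.DataFrame:
        lo, med, hi = np.percentile(self.draws, [2.5, 50, 97.5], axis=0)
        n, tp = med.shape
        return pd.DataFrame(
            {
                "area_id": np.repeat(self.area_ids, tp),
                "year": np.tile(self.years, n),
                "r_hat_median": med.ravel(),
                "r_hat_lower": lo.ravel(),
                "r_hat_upper": hi.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# official population estimates from practice registers


def nhs_population_estimate(
    registers: Iterable, area_ids: Sequence
) -> pd.DataFrame:
    """Estimate the adult (25+) population per area-year from GP registers.

    Official register releases give, per quarter, each practice's count of
    registered patients by area (all ages) and the practice-level fraction
    aged 25 or over.  The area-quarter adult estimate is
    ``sum_practices count * frac_25plus``; the annual figure is the
    unweighted mean over that year's quarterly releases.

    Each register must expose a ``quarterly`` DataFrame with columns
    (year, quarter, area_id, count, frac_25plus).  Quarters missing for a
    practice are simply absent from its table and are logged as excluded.
    """
    frames = []
    for reg in registers:
        q = reg.quarterly
        all_pairs = {(y, k) for y in q["year"].unique() for k in (1, 2, 3, 4)}
        missing = all_pairs - set(map(tuple, q[["year", "quarter"]].values))
        if missing:
            logger.info(
                "register %s: %d quarterly releases absent, excluded",
                getattr(reg, "practice_id", "?"),
                len(missing),
            )
        frames.append(q.assign(adult=q["count"] * q["frac_25plus"]))
    allq = pd.concat(frames, ignore_index=True)
    per_quarter = (
        allq.groupby(["area_id", "year", "quarter"])["adult"].sum().reset_index()
    )
    annual = (
        per_quarter.groupby(["area_id", "year"])["adult"].mean().reset_index()
    )
    out = annual.pivot(index="area_id", columns="year", values="adult")
    return out.reindex(list(area_ids))


# ---------------------------------------------------------------------------
# GLM residual diagnostics


def glm_residual_diagnostics(
    panel: PopulationPanel,
    lattice: AreaLattice,
    n_perm: int = 9999,
    seed: int = 0,
) -> dict:
    """Spatio-temporal autocorrelation of a plain regression's residuals.

    Fits log(P_nhs) on the stage-one covariates by OLS over the observed
    cells, then computes Moran's I per year (permutation p-values) and the
    lag-1 temporal autocorrelation per area.  Strong positive values on
    both axes indicate the need for spatio-temporal random effects.
    """
    obs = ~panel.missing_mask
    obs_years = np.flatnonzero(obs.all(axis=0))
    if len(obs_years) < 3:
        raise ValueError("need P_nhs observed for at least 3 years")
    X = panel.design()[:, obs_years, :].reshape(-1, 4)
    y = np.log(panel.p_nhs[:, obs_years]).reshape(-1)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular stage-one design")
    fit = sm.OLS(y, X).fit()
    resid = fit.resid.reshape(panel.n_areas, len(obs_years))

    rng = np.random.default_rng(seed)
    rows = []
    for k, ti in enumerate(obs_years):
        stat, pval = morans_i(resid[:, k], lattice, n_perm=n_perm, seed=rng)
        rows.append({"year": panel.years[ti], "morans_i": stat, "p_value": pval})
    acf, acf_mean = lag1_autocorrelation(resid)
    return {
        "morans_by_year": pd.DataFrame(rows),
        "lag1_acf": acf,
        "lag1_acf_mean": acf_mean,
        "residuals": resid,
        "ols_params": fit.params,
    }


# ---------------------------------------------------------------------------
# ST-CAR Gibbs sampler


def _logit(p: float) -> float:
    return float(np.log(p) - np.log1p(-p))


def _expit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


class _AdaptiveStep:
    """Robbins-Monro style step-size adaptation toward a target rate."""

    def __init__(self, scale: float, target: float = 0.44, window: int = 50):
        self.scale = scale
        self.target = target
        self.window = window
        self._accepts = 0
        self._count = 0

    def update(self, accepted: bool, adapting: bool) -> None:
        self._accepts += accepted
        self._count += 1
        if adapting and self._count == self.window:
            rate = self._accepts / self._count
            self.scale *= np.exp(0.3 * (rate - self.target))
            self._accepts = 0
            self._count = 0


def fit_stcar(
    panel: PopulationPanel,
    lattice: AreaLattice,
    mcmc: MCMCConfig | None = None,
    fixed: dict | None = None,
) -> STCARPosterior:
    """Fit the spatio-temporal adjustment model by Metropolis-within-Gibbs.

    Conjugate Gibbs updates are used for beta, sigma^2, tau^2 and each
    time-slice of the random-effect field S (Gaussian full conditionals,
    sampled in the eigenbasis of the graph Laplacian so each block draw is
    O(N^2)); logit-scale adaptive random-walk Metropolis for rho_S and
    rho_T.  Cells with missing P_nhs are redrawn each iteration from
    N(x'beta + S, sigma^2) and their retained draws form the posterior
    predictive sample used downstream.

    ``fixed`` may hold values for any of ``beta``, ``sigma2``, ``tau2``,
    ``rho_s``, ``rho_t``; those parameters are clamped and their update
    steps skipped (useful for oracle checks and restricted fits).
    """
    mcmc = mcmc or MCMCConfig()
    fixed = dict(fixed or {})
    unknown = set(fixed) - {"beta", "sigma2", "tau2", "rho_s", "rho_t"}
    if unknown:
        raise ValueError(f"cannot fix unknown parameters: {sorted(unknown)}")
    if tuple(lattice.area_ids) != tuple(panel.area_ids):
        raise ValueError("lattice areas do not match panel areas")
    rng = np.random.default_rng(mcmc.seed)

    n, tp = panel.n_areas, panel.n_years
    if tp < 2:
        raise ValueError("need at least 2 time points")
    miss = panel.missing_mask
    if miss.any() and (~miss).any(axis=0).sum() < 3:
        raise ValueError("imputation needs P_nhs observed in >= 3 years")

    # eigenbasis of the Laplacian D - W: Q(rho) = V diag(q) V', q = rho*lam + 1-rho
    W = lattice.W
    lap = np.diag(W.sum(axis=1)) - W
    lam, V = np.linalg.eigh(lap)
    lam = np.clip(lam, 0.0, None)

    X = panel.design()  # (n, tp, 4)
    Xf = X.reshape(n * tp, 4, order="C")  # row order: area-major, year within
    XtX = Xf.T @ Xf
    p = Xf.shape[1]

    y = np.where(miss, np.nan, np.log(panel.p_nhs))
    obs = ~miss
    # initial values from OLS on observed cells
    ols = np.linalg.lstsq(Xf[obs.ravel()], y[obs], rcond=None)
    beta = ols[0]
    mu0 = (X @ beta)
    y[miss] = mu0[miss]
    sigma2 = float(np.var(y[obs] - mu0[obs])) or 1e-4
    tau2 = max(sigma2, 1e-4)
    rho_s, rho_t = 0.5, 0.5
    if "beta" in fixed:
        beta = np.asarray(fixed["beta"], dtype=float)
        y[miss] = (X @ beta)[miss]
    sigma2 = float(fixed.get("sigma2", sigma2))
    tau2 = float(fixed.get("tau2", tau2))
    rho_s = float(fixed.get("rho_s", rho_s))
    rho_t = float(fixed.get("rho_t", rho_t))
    Se = np.zeros((n, tp))  # random effects in the eigenbasis

    step_s = _AdaptiveStep(mcmc.proposal_scale * 5)
    step_t = _AdaptiveStep(mcmc.proposal_scale * 5)
    n_keep = mcmc.n_retained
    out = {
        "beta": np.empty((n_keep, p)),
        "sigma2": np.empty(n_keep),
        "tau2": np.empty(n_keep),
        "rho_s": np.empty(n_keep),
        "rho_t": np.empty(n_keep),
        "S": np.empty((n_keep, n, tp)),
        "pred": np.empty((n_keep, int(miss.sum()))),
    }
    acc = {"rho_s": 0, "rho_t": 0, "post_adapt_n": 0}
    keep = 0

    q = rho_s * lam + (1.0 - rho_s)

    def quad_terms(Se_: np.ndarray, rho_t_: float) -> np.ndarray:
        """Per-eigencomponent sum of squared AR(1) innovations, (n,)."""
        D = Se_.copy()
        D[:, :-1] -= rho_t_ * Se_[:, 1:]
        return (D**2).sum(axis=1)

    for it in range(mcmc.iterations):
        adapting = mcmc.adapt and it < mcmc.burn_in
        S = V @ Se  # random effects in the original basis
        mu = X @ beta + S

        # --- impute missing log P_nhs from the posterior predictive
        y[miss] = mu[miss] + rng.standard_normal(int(miss.sum())) * np.sqrt(sigma2)

        # --- beta | rest (conjugate Gaussian)
        if "beta" not in fixed:
            u = (y - S).ravel()
            A = XtX / sigma2 + np.eye(p) / BETA_PRIOR_VAR
            b = Xf.T @ u / sigma2
            chol = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, b)
            beta = mean + np.linalg.solve(chol.T, rng.standard_normal(p))

        # --- S blocks | rest, sequential in t, in the eigenbasis
        R = V.T @ (y - (X @ beta))  # (n, tp) rotated residuals
        for t in range(tp):
            c_t = 1.0 if t == 0 else 1.0 + rho_t**2
            prec = c_t * q / tau2 + 1.0 / sigma2
            lin = R[:, t] / sigma2
            if t + 1 < tp:
                lin = lin + q * rho_t * Se[:, t + 1] / tau2
            if t > 0:
                lin = lin + q * rho_t * Se[:, t - 1] / tau2
            Se[:, t] = lin / prec + rng.standard_normal(n) / np.sqrt(prec)

        # --- sigma^2 | rest (conjugate inverse-gamma)
        S = V @ Se
        if "sigma2" not in fixed:
            resid = y - (X @ beta) - S
            ssr = float((resid**2).sum())
            sigma2 = 1.0 / rng.gamma(
                IG_SHAPE + 0.5 * n * tp, 1.0 / (IG_RATE + 0.5 * ssr)
            )

        # --- tau^2 | rest
        sk = quad_terms(Se, rho_t)
        if "tau2" not in fixed:
            quad = float(q @ sk)
            tau2 = 1.0 / rng.gamma(
                IG_SHAPE + 0.5 * n * tp, 1.0 / (IG_RATE + 0.5 * quad)
            )

        # --- rho_S | rest: logit random walk; quad is linear in rho_S
        if "rho_s" not in fixed:
            theta = _logit(rho_s) + step_s.scale * rng.standard_normal()
            prop = _expit(theta)
            q_prop = prop * lam + (1.0 - prop)
            if np.all(q_prop > 0):
                lp_cur = 0.5 * tp * np.log(q).sum() - 0.5 * (q @ sk) / tau2
                lp_cur += np.log(rho_s) + np.log1p(-rho_s)
                lp_prop = 0.5 * tp * np.log(q_prop).sum() - 0.5 * (q_prop @ sk) / tau2
                lp_prop += np.log(prop) + np.log1p(-prop)
                accept = np.log(rng.uniform()) < lp_prop - lp_cur
            else:
                accept = False  # singular precision proposal rejected
                logger.debug("rejected rho_s proposal %.4f (non-PD precision)", prop)
            if accept:
                rho_s, q = prop, q_prop
            step_s.update(accept, adapting)
            if not adapting:
                acc["rho_s"] += accept

        # --- rho_T | rest: logit random walk; quad is quadratic in rho_T
        if "rho_t" not in fixed:
            a0 = float(q @ (Se[:, :-1] ** 2).sum(axis=1))
            a1 = float(q @ (Se[:, :-1] * Se[:, 1:]).sum(axis=1))
            a2 = float(q @ (Se[:, 1:] ** 2).sum(axis=1))
            tail = float(q @ Se[:, -1] ** 2)  # marginal term, rho_T-free

            def lp_rho_t(r: float) -> float:
                quad_r = a0 - 2.0 * r * a1 + r * r * a2 + tail
                return -0.5 * quad_r / tau2 + np.log(r) + np.log1p(-r)

            theta = _logit(rho_t) + step_t.scale * rng.standard_normal()
            prop = _expit(theta)
            accept = np.log(rng.uniform()) < lp_rho_t(prop) - lp_rho_t(rho_t)
            if accept:
                rho_t = prop
            step_t.update(accept, adapting)
            if not adapting:
                acc["rho_t"] += accept
        if not adapting:
            acc["post_adapt_n"] += 1

        if not np.isfinite(sigma2) or not np.isfinite(tau2):
            raise FloatingPointError(
                f"divergent chain at iteration {it}: sigma2={sigma2}, tau2={tau2}"
            )

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thinning == 0:
            if keep < n_keep:
                out["beta"][keep] = beta
                out["sigma2"][keep] = sigma2
                out["tau2"][keep] = tau2
                out["rho_s"][keep] = rho_s
                out["rho_t"][keep] = rho_t
                out["S"][keep] = V @ Se
                out["pred"][keep] = y[miss]
                keep += 1

    n_post = max(acc["post_adapt_n"], 1)
    acceptance = {
        "rho_s": acc["rho_s"] / n_post,
        "rho_t": acc["rho_t"] / n_post,
    }
    logger.info("stage-one acceptance rates: %s", acceptance)
    return STCARPosterior(
        beta=out["beta"][:keep],
        sigma2=out["sigma2"][:keep],
        tau2=out["tau2"][:keep],
        rho_s=out["rho_s"][:keep],
        rho_t=out["rho_t"][:keep],
        S=out["S"][:keep],
        log_p_nhs_pred=out["pred"][:keep],
        missing_mask=miss,
        area_ids=panel.area_ids,
        years=panel.years,
        acceptance=acceptance,
        config=mcmc,
    )


def adjust_denominator(
    posterior: STCARPosterior, panel: PopulationPanel
) -> AdjustedDenominator:
    """Rescale CRD counts by the official-to-routine population ratio.

    For cells with an observed official estimate the adjustment
    R_hat = R_cdw / P_cdw * P_nhs is deterministic (identical across
    draws); for missing cells P_nhs is replaced by exp of that draw's
    posterior-predictive log-population, so R_hat inherits stage-one
    uncertainty.  The prevalence ratio R_cdw / P_cdw is held fixed
    throughout (the register population is assumed representative).
    """
    if (panel.p_cdw == 0).any():
        raise ValueError("P_cdw = 0 leaves the register prevalence undefined")
    miss = panel.missing_mask
    if posterior.log_p_nhs_pred.shape[1] != int(miss.sum()):
        raise ValueError("posterior predictive draws do not match missing cells")
    ratio = panel.r_cdw / panel.p_cdw
    base = np.where(miss, 0.0, ratio * np.nan_to_num(panel.p_nhs))
    draws = np.broadcast_to(base, (posterior.n_draws,) + base.shape).copy()
    draws[:, miss] = ratio[miss][None, :] * np.exp(posterior.log_p_nhs_pred)
    return AdjustedDenominator(
        draws=draws, area_ids=panel.area_ids, years=panel.years
    )
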