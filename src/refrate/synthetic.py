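"""Synthetic studies with known ground truth.

The primary data for this kind of analysis are confidential NHS records,
so every downstream stage is exercised on generated studies that emulate
the documented structure of the real ones:

* a regular grid of small areas standing in for the study lattice;
* GP practices with spatially concentrated catchments, whose quarterly
  register releases (patient count per area, practice-level fraction aged
  25+) are the raw material for the official population estimates;
* a routine-register extract distorted by the three documented error
  processes — practices outside the data-sharing agreement (spatially
  clustered gaps), proxy de-registration dates (multiplicative attrition
  whose magnitude compounds per retrospective year), and unrecorded moves
  (a fraction of each area's register assigned to a neighbouring area);
* official estimates withheld for the first two study years;
* referral counts drawn from the stage-two Poisson random-intercept model
  at the *true* (undistorted) patient counts.

Default parameter values are chosen to resemble the published study
scale: 100 areas (10 x 10 queen grid) instead of 204, 12 practices
instead of 32, 8 study years plus one extra, areas of roughly 1,150
adults, CRD prevalence near 9% rising over time, and stage-two effects
near the published relative risks.  All randomness flows from a single
seeded generator in a documented order, so one seed reproduces a study
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .glmm import ReferralPanel, build_design
from .population import PopulationPanel, nhs_population_estimate
from .spatial import AreaLattice, build_grid_lattice, leroux_precision, write_edge_list

__all__ = [
    "SyntheticTruth",
    "PracticeRegister",
    "SyntheticStudy",
    "simulate_population_panel",
    "simulate_referrals",
    "simulate_stcar_panel",
    "simulate_study",
    "write_study",
    "default_gamma",
]

#: stage-two truth on the log-rate-ratio scale, per design column; year and
#: interaction effects follow the published point estimates, the intercept
#: is set so the implied rate at typical covariate values is ~4.5 referrals
#: per 100 patients.
_YEAR_RR = {2013: 0.965, 2014: 0.991, 2015: 1.030, 2016: 1.091,
            2017: 1.049, 2018: 0.975, 2019: 0.961}
_MBRN_YEAR_RR = {2013: 0.998, 2014: 0.999, 2015: 0.998, 2016: 0.999,
                 2017: 0.999, 2018: 0.996, 2019: 0.995}


def default_gamma(years: tuple = tuple(range(2012, 2020))) -> dict:
    """Default stage-two coefficients keyed by design-column name."""
    g = {
        "intercept": -4.29,
        "age65_74": np.log(1.017),
        "age75plus": np.log(1.009),
        "male": np.log(1.016),
        "distance_km": np.log(1.005),
        "imd": np.log(0.998),
        "mbrn": np.log(1.001),
    }
    for y in years[1:]:
        g[f"year_{y}"] = np.log(_YEAR_RR.get(y, 1.0))
        g[f"mbrn_{y}"] = np.log(_MBRN_YEAR_RR.get(y, 1.0))
    return g


@dataclass
class SyntheticTruth:
    """Every generating value of a synthetic study."""

    # lattice and scale
    rows: int = 10
    cols: int = 10
    contiguity: str = "queen"
    n_practices: int = 12
    study_years: tuple = tuple(range(2012, 2020))
    n_extra_years: int = 1  # trailing years used only by stage one
    n_missing_years: int = 2  # leading years with no official estimate

    # population structure
    base_pop_median: float = 1150.0  # adults per area, median
    base_pop_log_sd: float = 0.18
    pop_growth_mean: float = 0.005  # annual growth rate
    pop_growth_sd: float = 0.004
    catchment_decay: float = 1.2  # grid cells; practice catchment scale
    quarter_noise_sd: float = 0.01  # log-scale noise on quarterly counts
    frac_noise_sd: float = 0.005  # noise on the quarterly 25+ fraction

    # register error processes
    n_nonsharing: int = 2  # practices outside the sharing agreement
    attrition_rate: float = 0.02  # median register loss per retrospective year
    attrition_sd: float = 0.04  # log-sd of the error per sqrt(year back)
    relocation_rate: float = 0.03  # fraction misassigned to a neighbour

    # disease prevalence
    prevalence_mean: float = 0.085
    prevalence_sd: float = 0.01
    prevalence_growth: float = 0.045  # annual relative growth

    # stage-one model truth (used by the model-faithful generator)
    beta: tuple = (0.5, 0.9, 0.01, -0.3)
    sigma2: float = 0.005
    tau2: float = 0.02
    rho_s: float = 0.8
    rho_t: float = 0.7

    # stage-two truth
    gamma: dict = field(default_factory=default_gamma)
    kappa2: float = 0.023
    mbrn_target_share: float = 0.5  # population share reached by the network

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("attrition_rate", "relocation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_practices < 2:
            raise ValueError("need at least 2 practices")
        if len(self.study_years) + self.n_extra_years < 3:
            raise ValueError("need at least 3 time points")
        if not 0.0 < self.prevalence_mean < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")

    @property
    def panel_years(self) -> tuple:
        extra = tuple(
            self.study_years[-1] + k for k in range(1, self.n_extra_years + 1)
        )
        return tuple(self.study_years) + extra


@dataclass
class PracticeRegister:
    """One practice's quarterly register releases.

    ``quarterly`` has columns (year, quarter, area_id, count, frac_25plus):
    the all-ages patient count registered from each area and the
    practice-level fraction aged 25 or over for that release.
    """

    practice_id: str
    quarterly: pd.DataFrame
    in_cdw: bool = True
    joined_mbrn_2017: bool = False

    def __post_init__(self) -> None:
        f = self.quarterly["frac_25plus"]
        if (f < 0).any() or (f > 1).any():
            raise ValueError("25+ fraction must lie in [0, 1]")
        if (self.quarterly["count"] < 0).any():
            raise ValueError("register counts must be nonnegative")

    def register_size(self, year: int, quarter: int) -> float:
        q = self.quarterly
        sel = (q["year"] == year) & (q["quarter"] == quarter)
        return float(q.loc[sel, "count"].sum())


@dataclass
class SyntheticStudy:
    """A complete generated study plus its ground truth."""

    truth: SyntheticTruth
    lattice: AreaLattice
    registers: list
    panel: PopulationPanel
    referrals: ReferralPanel
    adult_true: np.ndarray  # (N, Tp) true adult population
    r_true: np.ndarray  # (N, Tp) true CRD patient counts
    prevalence: np.ndarray  # (N, Tp)
    covariates: pd.DataFrame  # stage-two covariate table (area-year rows)
    gamma_true: np.ndarray  # aligned with the design columns
    Z_true: np.ndarray  # (N,) true area intercepts
    p_nhs_full: np.ndarray  # (N, Tp) official estimates incl. masked years


def _practice_shares(
    rng: np.random.Generator, coords: np.ndarray, truth: SyntheticTruth
) -> tuple[np.ndarray, np.ndarray]:
    """Area-by-practice registration shares from distance-decay catchments."""
    centers = rng.uniform(
        low=[0, 0], high=[truth.rows - 1, truth.cols - 1],
        size=(truth.n_practices, 2),
    )
    sizes = rng.lognormal(mean=0.0, sigma=0.4, size=truth.n_practices)
    dist = np.linalg.norm(coords[:, None, :] - centers[None, :, :], axis=2)
    w = sizes[None, :] * np.exp(-dist / truth.catchment_decay)
    w[w < 0.02 * w.max(axis=1, keepdims=True)] = 0.0  # practices are local
    return w / w.sum(axis=1, keepdims=True), centers


def simulate_population_panel(
    lattice: AreaLattice,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> tuple[list, PopulationPanel, dict]:
    """Generate practice registers and the distorted area-year panel.

    Returns the practice-register collection, the analysis-ready
    :class:`~refrate.population.PopulationPanel` (official estimates
    masked for the first ``n_missing_years``), and a dict of ground-truth
    arrays (true adult population, prevalence, true patient counts, the
    unmasked official estimates, practice shares, MBRN coverage).
    """
    rng = rng or np.random.default_rng(truth.seed)
    n = lattice.n_areas
    years = truth.panel_years
    tp = len(years)
    coords = np.array(
        [(k // truth.cols, k % truth.cols) for k in range(n)], dtype=float
    )

    # 1. practice catchments
    shares, centers = _practice_shares(rng, coords, truth)

    # 2. true adult population trajectories
    base = truth.base_pop_median * rng.lognormal(
        0.0, truth.base_pop_log_sd, size=n
    )
    base = np.clip(base, 650.0, None)
    growth = rng.normal(truth.pop_growth_mean, truth.pop_growth_sd, size=n)
    adult_true = base[:, None] * (1.0 + growth[:, None]) ** np.arange(tp)[None, :]
    adult_by_practice = shares[:, :, None] * adult_true[:, None, :]  # (N, P, Tp)

    # 3. flags: non-sharing practices and 2017 network joiners (clustered)
    non_sharing = rng.choice(truth.n_practices, size=truth.n_nonsharing, replace=False)
    # network joiners: practices clustered around a hub, added nearest-first
    # until they reach the target share of the registered population
    hub = rng.integers(truth.n_practices)
    d_hub = np.linalg.norm(centers - centers[hub], axis=1)
    pop_share = (shares * adult_true[:, None, 0]).sum(axis=0) / adult_true[:, 0].sum()
    order = np.argsort(d_hub)
    cum = np.cumsum(pop_share[order])
    n_join = int(np.searchsorted(cum, truth.mbrn_target_share) + 1)
    joiners = order[: min(n_join, truth.n_practices)]

    # 4. quarterly register releases
    frac25 = rng.uniform(0.65, 0.85, size=truth.n_practices)
    registers = []
    for p in range(truth.n_practices):
        active = np.flatnonzero(shares[:, p] > 0)
        rows = []
        for ti, year in enumerate(years):
            for quarter in (1, 2, 3, 4):
                noise = rng.lognormal(0.0, truth.quarter_noise_sd, size=len(active))
                f = float(
                    np.clip(frac25[p] + rng.normal(0.0, truth.frac_noise_sd), 0.5, 0.95)
                )
                counts = adult_by_practice[active, p, ti] / f * noise
                rows.append(
                    pd.DataFrame(
                        {
                            "year": year,
                            "quarter": quarter,
                            "area_id": np.asarray(lattice.area_ids)[active],
                            "count": counts,
                            "frac_25plus": f,
                        }
                    )
                )
        registers.append(
            PracticeRegister(
                practice_id=f"P{p:02d}",
                quarterly=pd.concat(rows, ignore_index=True),
                in_cdw=p not in non_sharing,
                joined_mbrn_2017=p in joiners,
            )
        )

    # 5. official estimates from the registers (then mask the early years)
    est = nhs_population_estimate(registers, lattice.area_ids)
    p_nhs_full = est[list(years)].to_numpy(dtype=float)

    # 6. routine extract: drop non-sharing practices ...
    sharing = np.array([p not in non_sharing for p in range(truth.n_practices)])
    shared_adult = adult_by_practice[:, sharing, :].sum(axis=1)
    nonsharing_prop = 1.0 - shared_adult / adult_true

    # ... apply retrospective attrition (compounding per year back); the
    # stochastic part mixes a persistent, spatially correlated area
    # propensity (areas are consistently over- or under-counted, and
    # neighbouring areas alike) with independent year-to-year noise
    years_back = (tp - 1) - np.arange(tp)
    med = (1.0 - truth.attrition_rate) ** years_back
    Qa = leroux_precision(0.9, lattice).Q
    lam_a, V_a = np.linalg.eigh(Qa)
    u = V_a @ (rng.standard_normal(n) / np.sqrt(lam_a))
    u = (u - u.mean()) / u.std()
    e = rng.standard_normal((n, tp))
    mix = 0.9 * u[:, None] + 0.436 * e  # ~unit variance, persistence dominant
    noise = np.exp(truth.attrition_sd * np.sqrt(years_back)[None, :] * mix)
    cdw = shared_adult * med[None, :] * noise

    # ... and misassign a fraction of each register to a neighbouring area;
    # a wrong address persists for the whole registration spell, so the
    # destination and moved fraction are constant per area over time
    if truth.relocation_rate > 0:
        neigh = [np.flatnonzero(lattice.W[i]) for i in range(n)]
        dest = np.array([rng.choice(neigh[i]) for i in range(n)])
        frac = truth.relocation_rate * rng.uniform(0.5, 1.5, size=n)
        moved = frac[:, None] * cdw
        received = np.zeros_like(cdw)
        for t in range(tp):
            np.add.at(received[:, t], dest, moved[:, t])
        cdw = cdw - moved + received

    p_cdw = np.round(cdw)
    if (p_cdw <= 0).any():
        raise RuntimeError("generated a non-positive routine population count")

    # 7. prevalence and patient counts (register prevalence is the truth)
    base_prev = np.clip(
        rng.normal(truth.prevalence_mean, truth.prevalence_sd, size=n), 0.02, 0.25
    )
    prevalence = np.clip(
        base_prev[:, None] * (1.0 + truth.prevalence_growth) ** np.arange(tp)[None, :],
        0.0,
        0.95,
    )
    r_cdw = np.minimum(np.round(prevalence * p_cdw), p_cdw)
    r_true = prevalence * adult_true

    p_nhs_masked = np.round(p_nhs_full).astype(float)
    p_nhs_masked[:, : truth.n_missing_years] = np.nan
    panel = PopulationPanel(
        area_ids=lattice.area_ids,
        years=years,
        p_cdw=p_cdw,
        p_nhs=p_nhs_masked,
        r_cdw=r_cdw,
        nonsharing_prop=nonsharing_prop,
    )

    mbrn_share = shares[:, joiners].sum(axis=1)  # time-constant coverage
    extras = {
        "adult_true": adult_true,
        "prevalence": prevalence,
        "r_true": r_true,
        "p_nhs_full": p_nhs_full,
        "shares": shares,
        "mbrn_coverage_pct": 100.0 * mbrn_share,
        "non_sharing": non_sharing,
        "joiners": joiners,
        "centers": centers,
    }
    return registers, panel, extras


def _area_covariates(
    rng: np.random.Generator,
    lattice: AreaLattice,
    truth: SyntheticTruth,
    mbrn_coverage_pct: np.ndarray,
) -> pd.DataFrame:
    """Stage-two covariate table over the study years.

    Demographic percentages drift slightly year to year; distance and
    deprivation are time-constant, as in the source data.
    """
    n = lattice.n_areas
    coords = np.array(
        [(k // truth.cols, k % truth.cols) for k in range(n)], dtype=float
    )
    age65 = np.clip(rng.normal(17.0, 3.0, size=n), 5.0, 35.0)
    age75 = np.clip(rng.normal(13.0, 3.0, size=n), 3.0, 30.0)
    male = np.clip(rng.normal(48.0, 1.2, size=n), 42.0, 54.0)
    hospitals = rng.uniform(
        low=[0, 0], high=[truth.rows - 1, truth.cols - 1], size=(3, 2)
    )
    dist = np.linalg.norm(coords[:, None, :] - hospitals[None, :, :], axis=2).min(axis=1)
    distance_km = 2.0 * dist + rng.lognormal(0.0, 0.3, size=n)
    imd = np.clip(rng.gamma(3.2, 5.6, size=n), 1.0, 80.0)

    rows = []
    for i, a in enumerate(lattice.area_ids):
        for t, year in enumerate(truth.study_years):
            rows.append(
                {
                    "area_id": a,
                    "year": year,
                    "age65_74": float(
                        np.clip(age65[i] + rng.normal(0, 0.3), 0.0, 100.0)
                    ),
                    "age75plus": float(
                        np.clip(age75[i] + rng.normal(0, 0.3), 0.0, 100.0)
                    ),
                    "male": float(np.clip(male[i] + rng.normal(0, 0.2), 0.0, 100.0)),
                    "distance_km": float(distance_km[i]),
                    "imd": float(imd[i]),
                    "mbrn_pct": float(np.clip(mbrn_coverage_pct[i], 0.0, 100.0)),
                }
            )
    return pd.DataFrame(rows)


def simulate_referrals(
    r_true: np.ndarray,
    covariates: pd.DataFrame,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> tuple[ReferralPanel, np.ndarray]:
    """Draw referral counts from the stage-two model at the true patient counts.

    ``r_true`` is (N, T) over the study years (undistorted counts), and
    ``covariates`` the matching area-year table.  Returns the referral
    panel and the realised area intercepts Z.
    """
    rng = rng or np.random.default_rng(truth.seed)
    if (r_true <= 0).any():
        raise ValueError("true patient counts must be positive")
    design = build_design(covariates, baseline_year=truth.study_years[0])
    gamma = np.array([truth.gamma[c] for c in design.columns])
    n, t = r_true.shape
    Z = rng.normal(0.0, np.sqrt(truth.kappa2), size=n)
    eta = (design.to_numpy() @ gamma).reshape(n, t) + Z[:, None]
    mean = r_true * np.exp(eta)
    if not np.all(np.isfinite(mean)) or mean.max() > 1e12:
        raise OverflowError("referral mean overflow; check gamma scale")
    y = rng.poisson(mean)
    data = covariates.copy()
    data["y"] = y.reshape(-1)
    return ReferralPanel(data, baseline_year=truth.study_years[0]), Z


def simulate_stcar_panel(
    lattice: AreaLattice,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> tuple[PopulationPanel, np.ndarray, np.ndarray]:
    """Model-faithful stage-one data for parameter-recovery studies.

    Draws the random-effect field S exactly from its reverse-order
    autoregressive prior (marginal at the last time point, each earlier
    slice conditioned on its successor) and the official log-counts from
    the Gaussian observation model at the truth's (beta, sigma2, tau2,
    rho_s, rho_t).  Returns the panel (early years masked), the true S,
    and the complete log official counts.
    """
    rng = rng or np.random.default_rng(truth.seed)
    n = lattice.n_areas
    years = truth.panel_years
    tp = len(years)
    Q = leroux_precision(truth.rho_s, lattice).Q
    lam, V = np.linalg.eigh(Q)

    def draw_field() -> np.ndarray:
        return V @ (rng.standard_normal(n) * np.sqrt(truth.tau2 / lam))

    S = np.empty((n, tp))
    S[:, -1] = draw_field()
    for t in range(tp - 2, -1, -1):
        S[:, t] = truth.rho_t * S[:, t + 1] + draw_field()

    p_cdw = np.round(rng.lognormal(np.log(1100.0), 0.2, size=(n, tp)))
    nonshare = rng.beta(1.0, 12.0, size=n)[:, None] * np.ones((1, tp))
    X = np.empty((n, tp, 4))
    X[:, :, 0] = 1.0
    X[:, :, 1] = np.log(p_cdw)
    X[:, :, 2] = np.arange(1, tp + 1)[None, :]
    X[:, :, 3] = nonshare
    log_p_nhs = X @ np.asarray(truth.beta) + S + rng.normal(
        0.0, np.sqrt(truth.sigma2), size=(n, tp)
    )
    p_nhs = np.exp(log_p_nhs)
    p_nhs_masked = p_nhs.copy()
    p_nhs_masked[:, : truth.n_missing_years] = np.nan
    panel = PopulationPanel(
        area_ids=lattice.area_ids,
        years=years,
        p_cdw=p_cdw,
        p_nhs=p_nhs_masked,
        r_cdw=np.round(0.09 * p_cdw),
        nonsharing_prop=nonshare,
    )
    return panel, S, log_p_nhs


def simulate_study(truth: SyntheticTruth | None = None) -> SyntheticStudy:
    """Generate a complete study: lattice, registers, panels and referrals."""
    truth = truth or SyntheticTruth()
    rng = np.random.default_rng(truth.seed)
    lattice = build_grid_lattice(truth.rows, truth.cols, truth.contiguity)
    registers, panel, extras = simulate_population_panel(lattice, truth, rng)
    covariates = _area_covariates(rng, lattice, truth, extras["mbrn_coverage_pct"])
    t_study = len(truth.study_years)
    referrals, Z_true = simulate_referrals(
        extras["r_true"][:, :t_study], covariates, truth, rng
    )
    design_cols = build_design(covariates, truth.study_years[0]).columns
    gamma_true = np.array([truth.gamma[c] for c in design_cols])
    return SyntheticStudy(
        truth=truth,
        lattice=lattice,
        registers=registers,
        panel=panel,
        referrals=referrals,
        adult_true=extras["adult_true"],
        r_true=extras["r_true"],
        prevalence=extras["prevalence"],
        covariates=covariates,
        gamma_true=gamma_true,
        Z_true=Z_true,
        p_nhs_full=extras["p_nhs_full"],
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict:
    """Write a study to CSV panels plus a YAML ground-truth record.

    Returns a manifest mapping logical names to file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "adjacency": outdir / "adjacency_edges.csv",
        "area_ids": outdir / "area_ids.csv",
        "population_panel": outdir / "population_panel.csv",
        "referral_panel": outdir / "referral_panel.csv",
        "truth": outdir / "truth.yaml",
    }
    write_edge_list(study.lattice, paths["adjacency"])
    pd.DataFrame({"area_id": study.lattice.area_ids}).to_csv(
        paths["area_ids"], index=False
    )
    study.panel.to_csv(paths["population_panel"])
    study.referrals.to_csv(paths["referral_panel"])
    truth_dict = asdict(study.truth)
    truth_dict["gamma"] = {k: float(v) for k, v in truth_dict["gamma"].items()}
    truth_dict["Z_true"] = [float(z) for z in study.Z_true]
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth_dict, fh, sort_keys=False)
    return {k: str(v) for k, v in paths.items()}
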