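"""Stage one: official-population estimation, diagnostics, ST-CAR fit and
denominator adjustment."""

import numpy as np
import pandas as pd
import pytest

from refrate import (
    MCMCConfig,
    PopulationPanel,
    STCARPosterior,
    SyntheticTruth,
    adjust_denominator,
    build_grid_lattice,
    fit_stcar,
    glm_residual_diagnostics,
    nhs_population_estimate,
    simulate_stcar_panel,
)
from refrate.synthetic import PracticeRegister


def _register(practice_id, rows, **flags):
    return PracticeRegister(
        practice_id=practice_id, quarterly=pd.DataFrame(rows), **flags
    )


class TestNhsPopulationEstimate:
    def test_single_practice_identity(self):
        rows = [
            {"year": 2014, "quarter": q, "area_id": "a", "count": 100, "frac_25plus": 1.0}
            for q in (1, 2, 3, 4)
        ]
        est = nhs_population_estimate([_register("P0", rows)], ["a"])
        assert est.loc["a", 2014] == pytest.approx(100.0)

    def test_two_practices_weighted_sum(self):
        r1 = [{"year": 2014, "quarter": 1, "area_id": "a", "count": 100, "frac_25plus": 0.8}]
        r2 = [{"year": 2014, "quarter": 1, "area_id": "a", "count": 50, "frac_25plus": 0.6}]
        est = nhs_population_estimate([_register("P0", r1), _register("P1", r2)], ["a"])
        assert est.loc["a", 2014] == pytest.approx(110.0)

    def test_annual_mean_over_quarters(self):
        rows = [
            {"year": 2014, "quarter": q, "area_id": "a", "count": c, "frac_25plus": 1.0}
            for q, c in zip((1, 2, 3, 4), (100, 102, 104, 106))
        ]
        est = nhs_population_estimate([_register("P0", rows)], ["a"])
        assert est.loc["a", 2014] == pytest.approx(103.0)


class TestPopulationPanel:
    @staticmethod
    def _panel(**overrides):
        kw = dict(
            area_ids=("a", "b"),
            years=(2012, 2013, 2014),
            p_cdw=np.full((2, 3), 100.0),
            p_nhs=np.full((2, 3), 110.0),
            r_cdw=np.full((2, 3), 10.0),
            nonsharing_prop=np.zeros((2, 3)),
        )
        kw.update(overrides)
        return PopulationPanel(**kw)

    def test_validation(self):
        with pytest.raises(ValueError, match="nonnegative"):
            self._panel(r_cdw=np.full((2, 3), -1.0))
        with pytest.raises(ValueError, match="exceed"):
            self._panel(r_cdw=np.full((2, 3), 200.0))
        bad = np.full((2, 3), 100.0)
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="p_nhs"):
            self._panel(p_cdw=bad)

    def test_design_columns(self):
        panel = self._panel()
        X = panel.design()
        assert X.shape == (2, 3, 4)
        assert np.allclose(X[:, :, 0], 1.0)
        assert np.allclose(X[:, :, 1], np.log(100.0))
        assert np.allclose(X[0, :, 2], [1, 2, 3])

    def test_csv_roundtrip_preserves_missing(self, tmp_path):
        p_nhs = np.full((2, 3), 110.0)
        p_nhs[:, 0] = np.nan
        panel = self._panel(p_nhs=p_nhs)
        path = tmp_path / "panel.csv"
        panel.to_csv(path)
        back = PopulationPanel.from_csv(path)
        assert np.array_equal(back.missing_mask, panel.missing_mask)
        assert np.array_equal(back.p_cdw, panel.p_cdw)


class TestGlmResidualDiagnostics:
    def test_independent_noise_is_uncorrelated(self):
        # tau2 ~ 0 removes the spatio-temporal field: residuals are i.i.d.
        lat = build_grid_lattice(5, 5, "queen")
        truth = SyntheticTruth(
            rows=5, cols=5, tau2=1e-8, sigma2=0.01, rho_s=0.0, rho_t=0.0, seed=21
        )
        panel, _, _ = simulate_stcar_panel(lat, truth)
        diag = glm_residual_diagnostics(panel, lat, n_perm=499, seed=0)
        tab = diag["morans_by_year"]
        assert (tab["p_value"] > 0.05).sum() >= len(tab) - 1
        assert abs(tab["morans_i"].mean() + 1 / 24) < 0.06

    def test_strong_spatial_field_detected(self):
        lat = build_grid_lattice(10, 10, "queen")
        truth = SyntheticTruth(
            rows=10, cols=10, tau2=1.0, sigma2=0.001, rho_s=0.99, rho_t=0.9, seed=22
        )
        panel, _, _ = simulate_stcar_panel(lat, truth)
        diag = glm_residual_diagnostics(panel, lat, n_perm=499, seed=0)
        tab = diag["morans_by_year"]
        assert (tab["morans_i"] > 0).all()
        assert (tab["p_value"] < 0.05).all()
        # centring each short series at its own mean absorbs much of the
        # persistence, so the mean lag-1 ACF is positive but modest
        assert diag["lag1_acf_mean"] > 0.0

    def test_singular_design_rejected(self):
        lat = build_grid_lattice(2, 2, "queen")
        panel = PopulationPanel(
            area_ids=lat.area_ids,
            years=(2012, 2013, 2014),
            p_cdw=np.full((4, 3), 100.0),  # log p_cdw collinear with intercept
            p_nhs=np.full((4, 3), 110.0),
            r_cdw=np.full((4, 3), 10.0),
            nonsharing_prop=np.ones((4, 3)),
        )
        with pytest.raises(np.linalg.LinAlgError):
            glm_residual_diagnostics(panel, lat, n_perm=9, seed=0)


class TestFitStcar:
    def test_same_seed_identical_draws(self):
        lat = build_grid_lattice(4, 4, "queen")
        truth = SyntheticTruth(rows=4, cols=4, seed=31)
        panel, _, _ = simulate_stcar_panel(lat, truth)
        cfg = MCMCConfig(iterations=400, burn_in=200, thinning=2, seed=5)
        a = fit_stcar(panel, lat, cfg)
        b = fit_stcar(panel, lat, cfg)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.log_p_nhs_pred, b.log_p_nhs_pred)

    def test_fixed_parameters_are_clamped(self):
        lat = build_grid_lattice(4, 4, "queen")
        truth = SyntheticTruth(rows=4, cols=4, seed=32)
        panel, _, _ = simulate_stcar_panel(lat, truth)
        post = fit_stcar(
            panel,
            lat,
            MCMCConfig(iterations=300, burn_in=100, thinning=2, seed=5),
            fixed={"rho_t": 0.0, "sigma2": 0.01},
        )
        assert np.all(post.rho_t == 0.0)
        assert np.all(post.sigma2 == 0.01)

    def test_acceptance_rates_after_adaptation(self, stcar_fit):
        assert 0.2 <= stcar_fit.acceptance["rho_s"] <= 0.6
        assert 0.2 <= stcar_fit.acceptance["rho_t"] <= 0.6

    def test_imputed_totals_track_truth(self, study, stcar_fit):
        # posterior-predictive imputation of the masked early years should
        # recover the true adult population totals closely
        miss = study.panel.missing_mask
        pred_cells = np.median(np.exp(stcar_fit.log_p_nhs_pred), axis=0)
        true_cells = study.p_nhs_full[miss]
        rel_err = abs(pred_cells.sum() - true_cells.sum()) / true_cells.sum()
        assert rel_err < 0.05

    def test_mismatched_lattice_rejected(self, study):
        other = build_grid_lattice(3, 3, "queen")
        with pytest.raises(ValueError, match="areas"):
            fit_stcar(study.panel, other, MCMCConfig(iterations=20, burn_in=10))


class TestAdjustDenominator:
    @staticmethod
    def _posterior_for(panel, pred):
        n_draws = pred.shape[0]
        zeros = np.zeros(n_draws)
        return STCARPosterior(
            beta=np.zeros((n_draws, 4)),
            sigma2=zeros + 1,
            tau2=zeros + 1,
            rho_s=zeros,
            rho_t=zeros,
            S=np.zeros((n_draws, panel.n_areas, panel.n_years)),
            log_p_nhs_pred=pred,
            missing_mask=panel.missing_mask,
            area_ids=panel.area_ids,
            years=panel.years,
        )

    def _panel(self, p_nhs):
        return PopulationPanel(
            area_ids=("a",),
            years=(2012, 2013),
            p_cdw=np.array([[1000.0, 1000.0]]),
            p_nhs=p_nhs,
            r_cdw=np.array([[100.0, 100.0]]),
            nonsharing_prop=np.zeros((1, 2)),
        )

    def test_deterministic_equation(self):
        panel = self._panel(np.array([[1100.0, 1000.0]]))
        post = self._posterior_for(panel, np.zeros((5, 0)))
        adj = adjust_denominator(post, panel)
        assert np.allclose(adj.draws[:, 0, 0], 110.0)  # 100/1000 * 1100
        assert np.allclose(adj.draws[:, 0, 1], 100.0)  # identity when equal

    def test_linearity_in_official_count(self):
        a = adjust_denominator(
            self._posterior_for(self._panel(np.array([[1100.0, 1000.0]])), np.zeros((3, 0))),
            self._panel(np.array([[1100.0, 1000.0]])),
        )
        b = adjust_denominator(
            self._posterior_for(self._panel(np.array([[2200.0, 2000.0]])), np.zeros((3, 0))),
            self._panel(np.array([[2200.0, 2000.0]])),
        )
        assert np.allclose(b.draws, 2 * a.draws)

    def test_missing_cells_use_predictive_draws(self):
        panel = self._panel(np.array([[np.nan, 1000.0]]))
        pred = np.log(np.array([[1200.0], [1300.0]]))
        adj = adjust_denominator(self._posterior_for(panel, pred), panel)
        assert adj.draws[0, 0, 0] == pytest.approx(120.0)
        assert adj.draws[1, 0, 0] == pytest.approx(130.0)
        assert np.allclose(adj.draws[:, 0, 1], 100.0)

    def test_zero_register_count_rejected(self):
        panel = PopulationPanel(
            area_ids=("a",),
            years=(2012, 2013),
            p_cdw=np.array([[0.0, 1000.0]]),
            p_nhs=np.array([[1000.0, 1000.0]]),
            r_cdw=np.array([[0.0, 100.0]]),
            nonsharing_prop=np.zeros((1, 2)),
        )
        post = self._posterior_for(panel, np.zeros((2, 0)))
        with pytest.raises(ValueError, match="P_cdw"):
            adjust_denominator(post, panel)

    def test_adjustment_recovers_undercount(self, study, adjusted):
        # the register under-counts early years, so adjusted totals exceed
        # raw totals and the gap narrows toward the final year
        raw = study.panel.r_cdw.sum(axis=0)
        med = adjusted.median.sum(axis=0)
        gap = (med - raw) / raw * 100
        assert gap[0] > gap[-1] > 0
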