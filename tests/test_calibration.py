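"""Site classification, grid-search calibration, maps and scenarios."""

import numpy as np
import pytest
from scipy.stats import beta as beta_dist

from ripacal.calibration import (
    CellState,
    VegetationClass,
    calibrate_class,
    classify_eta,
    classify_pi,
    empirical_pdf,
    impact_scenario,
    mean_biomass_map,
    percentage_absolute_difference,
)
from ripacal.hydrology import ClimateScenario, StageStatistics
from ripacal.stochastic import SteadyStatePdf


def _stats(p_i, tau_days=5.0, cell_id=0, n_bins=20):
    """Uniform stage density on [-1, 1] with eta placed so that the mass
    above it equals p_i exactly."""
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    eta = 1.0 - 2.0 * p_i
    return StageStatistics(
        cell_id=cell_id, eta=eta, bin_edges=edges,
        masses=np.full(n_bins, 1.0 / n_bins), dry_mass=0.0, p_i=p_i,
        tau_e_days=tau_days / p_i, tau_i_days=tau_days / (1 - p_i),
        tau_days=tau_days, h_bar_star=1.0, omega=1.0,
    )


def _cells(nus, p_i=0.3, eta=None):
    st = _stats(p_i)
    eta = st.eta if eta is None else eta
    return [
        CellState(i, 0.0, 0.0, eta, st, float(nu)) for i, nu in enumerate(nus)
    ]


class TestClassification:
    def test_single_bin_collects_everything(self):
        cells = _cells(np.zeros(10))
        classes = classify_eta(cells, [cells[0].eta - 1, cells[0].eta + 1])
        assert len(classes) == 1 and classes[0].n_cells == 10

    def test_eta_boundary_goes_to_upper_bin(self):
        cells = _cells([0.0], eta=1.0)
        classes = classify_eta(cells, [0.0, 1.0, 2.0])
        assert classes[0].lo == 1.0  # half-open convention [1, 2)

    def test_cells_outside_edges_rejected(self):
        cells = _cells([0.0], eta=5.0)
        with pytest.raises(ValueError, match="outside"):
            classify_eta(cells, [0.0, 1.0])

    def test_eta_partition_covers_all_cells(self, rng):
        etas = rng.uniform(-1, 1, 200)
        cells = [
            CellState(i, 0, 0, float(e), _stats(0.3, cell_id=i), 0.0)
            for i, e in enumerate(etas)
        ]
        classes = classify_eta(cells, np.linspace(-1, 1.0001, 9))
        assert sum(c.n_cells for c in classes) == 200
        labels = [c.class_label for c in cells]
        assert all(l is not None for l in labels)

    def test_pi_boundaries(self):
        cells = [
            CellState(0, 0, 0, 0.0, _stats(0.9999), 0.0),
            CellState(1, 0, 0, 0.0, _stats(0.05), 0.0),
        ]
        classes = classify_pi(cells, delta=0.1)
        by_label = {c.class_label for c in cells}
        assert cells[0].class_label.startswith("pi[0.9")  # closed top bin
        assert cells[1].class_label.startswith("pi[0,")
        assert sum(c.n_cells for c in classes) == 2
        assert len(by_label) == 2

    def test_pi_delta_validated(self):
        with pytest.raises(ValueError):
            classify_pi([], delta=0.0)


class TestEmpiricalPdf:
    def test_point_mass_occupies_single_bin(self):
        vc = VegetationClass("pi", 0.0, 1.0, _cells(np.full(50, 0.5)))
        edges, dens = empirical_pdf(vc, n_bins=10, min_cells=30)
        assert np.count_nonzero(dens) == 1

    def test_unit_area(self, rng):
        vc = VegetationClass("pi", 0.0, 1.0, _cells(rng.uniform(0, 1, 200)))
        edges, dens = empirical_pdf(vc, n_bins=25, min_cells=30)
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0, abs=1e-9)

    def test_approaches_known_beta_density(self, rng):
        sample = beta_dist(2.0, 5.0).rvs(10000, random_state=rng)
        vc = VegetationClass("pi", 0.0, 1.0, _cells(sample))
        edges, dens = empirical_pdf(vc, n_bins=20, min_cells=30)
        expected_masses = np.diff(beta_dist(2.0, 5.0).cdf(edges))
        got_masses = dens * np.diff(edges)
        assert np.max(np.abs(np.cumsum(got_masses) - np.cumsum(expected_masses))) < 0.05

    def test_too_few_members_flagged_unfit(self):
        vc = VegetationClass("pi", 0.0, 1.0, _cells(np.zeros(5)))
        with pytest.raises(ValueError, match="unfit"):
            empirical_pdf(vc, min_cells=30)


def _synthetic_class(k_star, beta_star, p_i=0.3, tau_days=5.0, n=5000,
                     seed=0, omega=0.06):
    st = _stats(p_i, tau_days=tau_days)
    vc_probe = VegetationClass("pi", 0.0, 1.0,
                               [CellState(0, 0, 0, st.eta, st, 0.0)])
    alpha = vc_probe.decay_rate(k_star)
    pdf = SteadyStatePdf(beta_star, alpha, tau_days * omega, p_i)
    nus = pdf.rvs(n, seed=seed)
    cells = [CellState(i, 0, 0, st.eta, st, float(v))
             for i, v in enumerate(nus)]
    return VegetationClass("pi", 0.0, 1.0, cells), alpha


class TestCalibrateClass:
    def test_on_grid_truth_recovered_exactly(self):
        vc, alpha = _synthetic_class(1.2, 0.6, seed=21)
        res = calibrate_class(vc, omega=0.06)
        assert res.k_hat == pytest.approx(1.2)
        assert res.beta_hat == pytest.approx(0.6)
        assert res.alpha_hat == pytest.approx(alpha, rel=1e-9)
        assert res.viable

    def test_theoretical_pdf_is_its_own_argmin(self):
        # empirical histogram replaced by the exact binned law at a grid
        # point: that point must win with ~zero residual
        vc, alpha = _synthetic_class(0.8, 0.5, n=40, seed=3)
        pdf = SteadyStatePdf(0.5, alpha, 5.0 * 0.06, 0.3)
        edges = np.linspace(0, 1, 41)
        target = pdf.binned_masses(edges) / np.diff(edges)
        # hand the calibrator a class whose members reproduce the law
        # exactly by sampling the inverse CDF at midpoints of a fine grid
        u = (np.arange(20000) + 0.5) / 20000
        from scipy.optimize import brentq
        qs = np.array([
            brentq(lambda x: float(pdf.cdf(x)) - ui, 1e-12, 0.5 - 1e-12)
            for ui in u[:: 500]
        ])
        assert np.all(np.diff(qs) > 0)  # sanity of the inversion
        nus = np.interp(u, u[::500], qs)
        cells = [CellState(i, 0, 0, vc.cells[0].eta, vc.cells[0].stats,
                           float(np.clip(v, 0, 1))) for i, v in enumerate(nus)]
        vc2 = VegetationClass("pi", 0.0, 1.0, cells)
        res = calibrate_class(vc2, omega=0.06)
        assert (res.k_hat, res.beta_hat) == (pytest.approx(0.8), pytest.approx(0.5))

    def test_off_grid_truth_recovered_at_grid_resolution(self):
        # beta = 0.575 sits exactly between grid points, the worst case:
        # the support-endpoint error couples into k, so the joint error is
        # bounded by two grid steps in k and one in beta
        vc, alpha = _synthetic_class(1.24, 0.575, seed=5)
        res = calibrate_class(vc, omega=0.06)
        assert abs(res.beta_hat - 0.575) <= 0.05 + 1e-9
        assert abs(res.k_hat - 1.24) <= 0.2 + 1e-9
        assert res.alpha_hat == pytest.approx(alpha, rel=0.2)

    def test_mildly_off_grid_truth_recovered_within_one_step(self):
        vc, _ = _synthetic_class(1.23, 0.59, seed=5)
        res = calibrate_class(vc, omega=0.06)
        assert abs(res.k_hat - 1.23) <= 0.1 + 1e-9
        assert abs(res.beta_hat - 0.59) <= 0.05 + 1e-9

    def test_infeasible_class_flagged(self):
        # P_I so high that no (k, beta) on the grid is viable
        st = _stats(0.99, tau_days=5.0)
        cells = [CellState(i, 0, 0, st.eta, st, 0.0) for i in range(50)]
        vc = VegetationClass("pi", 0.9, 1.0, cells)
        res = calibrate_class(vc, omega=1.0,
                              grid_k=np.array([5.0, 8.0]),
                              grid_beta=np.array([0.05, 0.1]))
        assert not res.feasible and not res.viable


class TestMapsAndPad:
    def test_identical_maps_give_zero(self):
        m = np.array([0.1, 0.5, 0.3])
        assert percentage_absolute_difference(m, m) == 0.0

    def test_uniform_ten_percent_inflation(self):
        m = np.array([0.1, 0.5, 0.3])
        assert percentage_absolute_difference(m, 1.1 * m) == pytest.approx(10.0)

    def test_sign_symmetric(self):
        m = np.array([0.2, 0.4])
        up = percentage_absolute_difference(m, m + 0.05)
        down = percentage_absolute_difference(m, m - 0.05)
        assert up == pytest.approx(down)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            percentage_absolute_difference(np.zeros(3), np.ones(3))

    def test_mean_cell_pct_variant(self):
        m = np.array([0.1, 0.2])
        assert percentage_absolute_difference(
            m, np.array([0.11, 0.24]), method="mean_cell_pct"
        ) == pytest.approx(15.0)

    def test_map_mean_is_class_weighted_mean(self, small_site,
                                             small_site_results):
        mu = mean_biomass_map(small_site_results, small_site.cells)
        by_label = {r.vclass.label: r.mean_biomass()
                    for r in small_site_results}
        sizes = {r.vclass.label: r.vclass.n_cells for r in small_site_results}
        expect = sum(by_label[l] * sizes[l] for l in by_label) / sum(
            sizes.values()
        )
        assert mu.mean() == pytest.approx(expect, rel=1e-9)

    def test_atom_only_class_maps_to_zero(self):
        st = _stats(0.99)
        cells = [CellState(i, 0, 0, st.eta, st, 0.0) for i in range(40)]
        vc = VegetationClass("pi", 0.9, 1.0, cells)
        res = calibrate_class(vc, omega=1.0, grid_k=np.array([5.0]),
                              grid_beta=np.array([0.05]))
        np.testing.assert_array_equal(mean_biomass_map([res], cells), 0.0)


class TestImpactScenario:
    def test_identity_scenario_reproduces_baseline(self, small_site,
                                                   small_site_results):
        base = mean_biomass_map(small_site_results, small_site.cells)
        same = {c.cell_id: c.stats for c in small_site.cells}
        out = impact_scenario(small_site_results, small_site.cells, same,
                              ClimateScenario(1.0, 1.0, 1.0),
                              omega=small_site.config.omega)
        np.testing.assert_allclose(out.mu1, base, atol=1e-12)
        np.testing.assert_allclose(out.delta_pi_pct, 0.0, atol=1e-12)

    def test_beta_adaptation_never_reduces_biomass(self, small_site,
                                                   small_site_results):
        same = {c.cell_id: c.stats for c in small_site.cells}
        kw = dict(omega=small_site.config.omega)
        plain = impact_scenario(small_site_results, small_site.cells, same,
                                ClimateScenario(1.0, 1.0, 1.0), **kw)
        adapted = impact_scenario(small_site_results, small_site.cells, same,
                                  ClimateScenario(1.0, 1.0, 1.25), **kw)
        assert np.all(adapted.mu1 >= plain.mu1 - 1e-12)

    def test_pi_keying_borrows_nearest_calibrated_bin(self, small_site,
                                                      small_site_results):
        same = {c.cell_id: c.stats for c in small_site.cells}
        out = impact_scenario(small_site_results, small_site.cells, same,
                              ClimateScenario(1.0, 1.0, 1.0),
                              omega=small_site.config.omega, keying="pi")
        assert np.all(np.isfinite(out.mu1))
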