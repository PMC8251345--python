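"""Debye forward model and one-dimensional SAXS analyses."""

import numpy as np
import pytest

from torusfit import saxs_core as sx, synthetic_data as sd
from torusfit.errors import (
    InvalidArgumentError,
    InvalidDataError,
    MethodInapplicableError,
    NoGuinierRegionError,
)

from conftest import sphere_form_factor


@pytest.fixture(scope="module")
def q_grid():
    return np.linspace(0.01, 0.5, 101)


class TestDebye:
    def test_two_bead_closed_form(self, q_grid):
        d = 7.3
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        curve = sx.debye_intensity(coords, q_grid, bin_width=0.01)
        expect = 2.0 * (1.0 + np.sin(q_grid * d) / (q_grid * d))
        assert np.allclose(curve.I, expect, rtol=1e-6)

    def test_forward_intensity_is_total_weight_squared(self, dimer):
        w = np.linspace(0.5, 2.0, dimer.n_beads)
        curve = sx.debye_intensity(dimer.coords, np.array([0.0]), weights=w)
        assert curve.I[0] == pytest.approx(np.sum(w) ** 2, rel=1e-12)

    def test_histogram_matches_brute_force(self, dimer, q_grid):
        hist = sx.debye_intensity(dimer.coords, q_grid, bin_width=0.1)
        direct = sx.debye_intensity_direct(dimer.coords, q_grid)
        assert np.max(np.abs(hist.I - direct.I) / np.abs(direct.I)) < 1e-3

    def test_histogram_matches_brute_force_weighted(self, dimer, q_grid):
        w = np.linspace(0.5, 2.0, dimer.n_beads)
        hist = sx.debye_intensity(dimer.coords, q_grid, weights=w,
                                  bin_width=0.1)
        direct = sx.debye_intensity_direct(dimer.coords, q_grid, weights=w)
        assert np.max(np.abs(hist.I - direct.I) / np.abs(direct.I)) < 1e-3

    def test_sphere_form_factor_analytic_limit(self, sphere, sphere_curve):
        coords, r_eff = sphere
        F = sphere_form_factor(sphere_curve.q, r_eff)
        I0 = float(len(coords)) ** 2
        mask = (sphere_curve.q <= 0.3) & (F >= 1e-4)  # away from the nodes
        rel = np.abs(sphere_curve.I[mask] / (I0 * F[mask]) - 1.0)
        assert rel.max() < 0.02

    def test_intensity_bounded_by_forward_value(self, sphere_curve, sphere):
        coords, _ = sphere
        assert np.all(sphere_curve.I <= len(coords) ** 2)

    def test_empty_model_rejected(self, q_grid):
        with pytest.raises(InvalidArgumentError):
            sx.debye_intensity(np.zeros((0, 3)), q_grid)


class TestEnsembleAverage:
    def test_single_and_identical(self, q_grid):
        c = sx.SAXSCurve(q=q_grid, I=np.exp(-q_grid))
        assert np.array_equal(sx.ensemble_average([c]).I, c.I)
        assert np.allclose(sx.ensemble_average([c, c, c]).I, c.I, rtol=1e-14)

    def test_midpoint_of_two(self, q_grid):
        a = sx.SAXSCurve(q=q_grid, I=np.ones_like(q_grid))
        b = sx.SAXSCurve(q=q_grid, I=3.0 * np.ones_like(q_grid))
        avg = sx.ensemble_average([a, b])
        assert np.allclose(avg.I, 2.0)

    def test_grid_mismatch(self, q_grid):
        a = sx.SAXSCurve(q=q_grid, I=np.ones_like(q_grid))
        b = sx.SAXSCurve(q=q_grid + 0.001, I=np.ones_like(q_grid))
        with pytest.raises(InvalidArgumentError):
            sx.ensemble_average([a, b])


class TestGuinier:
    def test_exact_guinier_curve_recovered(self):
        q = np.linspace(0.001, 0.2, 300)
        curve = sx.SAXSCurve(q=q, I=7.0 * np.exp(-q**2 * 33.0**2 / 3.0))
        g = sx.guinier_fit(curve)
        assert g.Rg == pytest.approx(33.0, abs=1e-6)
        assert g.I0 == pytest.approx(7.0, abs=1e-6)
        assert g.q_range_used[1] * g.Rg <= 1.3 + 1e-9

    def test_sphere_rg_within_one_percent(self, sphere, sphere_curve):
        _, r_eff = sphere
        g = sx.guinier_fit(sphere_curve)
        assert g.Rg == pytest.approx(np.sqrt(3.0 / 5.0) * r_eff, rel=0.01)

    def test_linear_fit_overestimates_sphere_rg(self, sphere, sphere_curve):
        """The classic linear fit at qRg <= 1.3 carries the known positive
        truncation bias on sharp-edged particles; the quadratic default
        removes it."""
        _, r_eff = sphere
        true = np.sqrt(3.0 / 5.0) * r_eff
        g1 = sx.guinier_fit(sphere_curve, order=1)
        g2 = sx.guinier_fit(sphere_curve, order=2)
        assert g1.Rg > true * 1.005
        assert abs(g2.Rg - true) < abs(g1.Rg - true)

    def test_noisy_recovery_within_reported_errors(self):
        q = np.linspace(0.005, 0.3, 200)
        truth = sx.SAXSCurve(q=q, I=50.0 * np.exp(-q**2 * 30.0**2 / 3.0))
        noise = sd.NoiseModel.relative(0.01, 50.0)
        misses = 0
        for seed in range(20):
            obs = sd.simulate_saxs_observation(truth, noise, seed=seed)
            g = sx.guinier_fit(obs)
            if abs(g.Rg - 30.0) > 3.0 * g.Rg_err:
                misses += 1
        assert misses <= 1  # 3-sigma coverage over 20 derandomized seeds

    def test_error_paths(self):
        q = np.linspace(0.01, 0.2, 50)
        rising = sx.SAXSCurve(q=q, I=1.0 + q**2)
        with pytest.raises(NoGuinierRegionError):
            sx.guinier_fit(rising)
        dipping = np.exp(-q**2 * 100.0)
        dipping[5] = 0.0  # dead detector point inside the fit window
        with pytest.raises(InvalidDataError):
            sx.guinier_fit(sx.SAXSCurve(q=q, I=dipping))
        with pytest.raises(InvalidArgumentError):
            sx.guinier_fit(sx.SAXSCurve(q=q[:3], I=np.ones(3)))


class TestKratky:
    def test_exact_guinier_curve_peaks_at_analytic_point(self):
        q = np.linspace(0.001, 0.25, 1000)
        curve = sx.SAXSCurve(q=q, I=np.exp(-q**2 * 30.0**2 / 3.0))
        g = sx.guinier_fit(curve)
        k = sx.dimensionless_kratky(curve, g)
        assert k.peak_x == pytest.approx(np.sqrt(3.0), abs=2e-3)
        assert k.peak_y == pytest.approx(3.0 / np.e, abs=2e-3)

    def test_rigid_rod_peaks_right_of_globule(self):
        rod = np.column_stack([np.zeros(200), np.zeros(200),
                               1.5 * np.arange(200.0)])
        q = np.linspace(0.002, 0.5, 400)
        curve = sx.debye_intensity(rod, q, bin_width=0.2)
        k = sx.dimensionless_kratky(curve, sx.guinier_fit(curve))
        assert k.peak_x > 2.2

    def test_insufficient_coverage(self):
        q = np.linspace(0.001, 0.02, 50)
        curve = sx.SAXSCurve(q=q, I=np.exp(-q**2 * 30.0**2 / 3.0))
        g = sx.guinier_fit(curve)
        with pytest.raises(InvalidArgumentError):
            sx.dimensionless_kratky(curve, g)


class TestModelPr:
    def test_two_beads_single_bin(self):
        coords = np.array([[0.0, 0, 0], [8.2, 0, 0]])
        pr = sx.model_pr(coords, bin_width=0.5)
        assert pr.dmax == pytest.approx(8.2)
        occupied = pr.bin_mass > 0
        assert occupied.sum() == 1
        assert pr.r_eff[occupied][0] == pytest.approx(8.2)

    def test_rg_agrees_with_coordinate_space(self, ring12):
        coords = ring12.coords
        com = coords.mean(axis=0)
        rg_coord = np.sqrt(np.mean(np.sum((coords - com) ** 2, axis=1)))
        pr = sx.model_pr(coords, bin_width=0.5)
        assert pr.Rg_pr == pytest.approx(rg_coord, rel=5e-3)

    def test_fourier_pair_with_debye(self, dimer, q_grid):
        pr = sx.model_pr(dimer.coords, bin_width=0.5)
        back = sx.pr_to_intensity(pr, q_grid)
        direct = sx.debye_intensity_direct(dimer.coords, q_grid)
        assert np.max(np.abs(back.I - direct.I) / np.abs(direct.I)) < 5e-3


class TestIndirectTransform:
    def test_sphere_pr_recovered(self, sphere, sphere_curve):
        _, r_eff = sphere
        pr = sx.pr_indirect_transform(sphere_curve, dmax=2 * r_eff)
        r = pr.r
        analytic = r**2 * (1 - 0.75 * r / r_eff + r**3 / (16 * r_eff**3))
        analytic = np.clip(analytic, 0.0, None)
        analytic *= np.trapezoid(pr.P, r) / np.trapezoid(analytic, r)
        assert np.max(np.abs(pr.P - analytic)) / analytic.max() < 0.05

    def test_consistency_with_guinier(self, sphere, sphere_curve):
        _, r_eff = sphere
        g = sx.guinier_fit(sphere_curve)
        pr = sx.pr_indirect_transform(sphere_curve, dmax=2 * r_eff)
        assert pr.I0_pr == pytest.approx(g.I0, rel=0.02)
        assert pr.Rg_pr == pytest.approx(g.Rg, rel=0.02)

    def test_regularization_monotonicity(self, sphere_curve):
        resid = []
        for alpha in (1e-3, 1e0, 1e3, 1e6):
            pr = sx.pr_indirect_transform(sphere_curve, dmax=60.0,
                                          alpha=alpha)
            back = sx.pr_to_intensity(pr, sphere_curve.q)
            resid.append(float(np.sum((back.I - sphere_curve.I) ** 2)))
        assert all(a <= b for a, b in zip(resid, resid[1:]))

    def test_invalid_arguments(self, sphere_curve):
        with pytest.raises(InvalidArgumentError):
            sx.pr_indirect_transform(sphere_curve, dmax=60.0, alpha=-1.0)
        with pytest.raises(InvalidArgumentError):
            sx.pr_indirect_transform(sphere_curve, dmax=60.0, n_basis=3)
        with pytest.raises(InvalidArgumentError):
            sx.pr_indirect_transform(sphere_curve, dmax=-5.0)


class TestMolecularWeight:
    def test_porod_volume_matches_envelope(self, sphere, sphere_curve):
        _, r_eff = sphere
        mw = sx.mw_estimate(sphere_curve, sx.guinier_fit(sphere_curve),
                            method="porod")
        v_true = 4.0 / 3.0 * np.pi * r_eff**3
        assert mw.porod_volume == pytest.approx(v_true, rel=0.15)

    def test_double_volume_doubles_mass(self, sphere_curve):
        coords2, _ = sd.make_sphere_model(30.0 * 2 ** (1 / 3), 1.5)
        curve2 = sx.debye_intensity(coords2, sphere_curve.q, bin_width=0.5)
        m1 = sx.mw_estimate(sphere_curve, sx.guinier_fit(sphere_curve),
                            method="porod").mass
        m2 = sx.mw_estimate(curve2, sx.guinier_fit(curve2),
                            method="porod").mass
        assert 1.8 <= m2 / m1 <= 2.2

    def test_vc_scales_with_size(self, sphere_curve):
        coords2, _ = sd.make_sphere_model(30.0 * 2 ** (1 / 3), 1.5)
        curve2 = sx.debye_intensity(coords2, sphere_curve.q, bin_width=0.5)
        m1 = sx.mw_estimate(sphere_curve, sx.guinier_fit(sphere_curve),
                            method="vc").mass
        m2 = sx.mw_estimate(curve2, sx.guinier_fit(curve2), method="vc").mass
        assert m2 > m1

    def test_no_plateau_raises(self):
        q = np.linspace(0.005, 0.5, 200)
        gaussian = sx.SAXSCurve(q=q, I=np.exp(-q**2 * 25.0**2 / 3.0))
        g = sx.guinier_fit(gaussian)
        with pytest.raises(MethodInapplicableError):
            sx.mw_estimate(gaussian, g, method="porod")

    def test_unknown_method(self, sphere_curve):
        with pytest.raises(InvalidArgumentError):
            sx.mw_estimate(sphere_curve, sx.guinier_fit(sphere_curve),
                           method="bayes")
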