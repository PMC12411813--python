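"""Standard ellipse areas, Bayesian SEAb and ellipse overlap geometry."""

import numpy as np
import pytest
from scipy import stats

from isofoodweb.niche import (
    EllipseFit,
    ellipse_overlap,
    ellipse_polygon,
    sea_from_cov,
    seab,
    seac,
)


def _random_psd(rng):
    a = rng.normal(size=(2, 2))
    return a @ a.T + 0.1 * np.eye(2)


class TestSEA:
    def test_identity_covariance_gives_pi(self):
        assert sea_from_cov(np.eye(2)) == pytest.approx(np.pi)

    def test_diagonal_closed_form(self):
        assert sea_from_cov(np.diag([4.0, 9.0])) == pytest.approx(6 * np.pi)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            sea_from_cov(np.array([[1.0, 0.5], [0.0, 1.0]]))

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(ValueError, match="eigenvalue"):
            sea_from_cov(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_singular_covariance_warns_area_zero(self):
        with pytest.warns(UserWarning, match="singular"):
            assert sea_from_cov(np.outer([1.0, 2.0], [1.0, 2.0])) == 0.0

    def test_monte_carlo_geometric_oracle(self):
        """SEA equals the area of the ellipse holding the chi2(2) 1-sigma mass
        (~39.35%), estimated by rejection sampling in a bounding box."""
        rng = np.random.default_rng(42)
        cov = _random_psd(rng)
        r2 = stats.chi2.ppf(1 - np.exp(-0.5), df=2)  # = 1.0: the standard ellipse
        prec = np.linalg.inv(cov)
        half = np.sqrt(np.diag(cov) * r2) * 1.5
        box_area = 4 * half[0] * half[1]
        pts = rng.uniform(-half, half, size=(200_000, 2))
        inside = np.einsum("ij,jk,ik->i", pts, prec, pts) <= r2
        mc_area = box_area * inside.mean()
        assert sea_from_cov(cov) == pytest.approx(mc_area, rel=0.02)

    def test_rotation_translation_invariance_and_scaling(self):
        rng = np.random.default_rng(7)
        pts = rng.multivariate_normal([3, -2], [[2.0, 0.7], [0.7, 1.0]], 200)
        base = seac(pts).sea
        th = 0.83
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert seac(pts @ rot.T + [5, 5]).sea == pytest.approx(base, rel=1e-9)
        assert seac(3.0 * pts).sea == pytest.approx(9.0 * base, rel=1e-9)


class TestSEAc:
    def test_three_points_doubles_sea(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.2], [0.3, 1.0]])
        f = seac(pts)
        assert f.seac == pytest.approx(2 * f.sea)

    def test_correction_vanishes_asymptotically(self):
        rng = np.random.default_rng(1)
        cov = np.array([[1.5, 0.4], [0.4, 0.8]])
        f = seac(rng.multivariate_normal([0, 0], cov, 10_000))
        assert f.seac == pytest.approx(sea_from_cov(cov), rel=0.05)
        assert f.seac / f.sea == pytest.approx(1.0, abs=1e-3)

    def test_seac_never_below_sea(self):
        rng = np.random.default_rng(2)
        for n in (3, 5, 20, 200):
            f = seac(rng.standard_normal((n, 2)))
            assert f.seac >= f.sea

    def test_collinear_points_warn_area_zero(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.warns(UserWarning, match="singular"):
            assert seac(pts).seac == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            seac(np.zeros((2, 2)))


class TestSEAb:
    def test_area_draws_positive(self):
        rng = np.random.default_rng(3)
        f = seab(rng.standard_normal((30, 2)), seed=0)
        assert np.all(f.seab_draws > 0)
        assert f.ci50[0] <= f.seab_mode or f.seab_mode <= f.ci50[1]

    def test_calibration_interval_contains_truth(self):
        rng = np.random.default_rng(4)
        f = seab(rng.multivariate_normal([0, 0], np.eye(2), 500), seed=1)
        assert f.ci95[0] < np.pi < f.ci95[1]

    def test_doubling_coordinates_quadruples_area_draws(self):
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((50, 2))
        a = seab(pts, seed=2)
        b = seab(2 * pts, seed=2)
        np.testing.assert_allclose(b.seab_draws / a.seab_draws, 4.0, rtol=1e-3)

    def test_overwhelming_prior_reproduces_prior_scale(self):
        """With a massive prior df the data stop mattering: the posterior area
        concentrates on the prior's implied covariance."""
        rng = np.random.default_rng(6)
        pts = rng.standard_normal((5, 2))
        nu0 = 1e6
        sigma0 = np.array([[2.0, 0.0], [0.0, 2.0]])
        f = seab(pts, seed=3, nu0=nu0, psi0_scale=2.0 * (nu0 - 3) / 1.0)
        # psi0 = psi0_scale*I, prior mean of Sigma = psi0/(nu0-3) = 2I
        assert f.seab_mean == pytest.approx(sea_from_cov(sigma0), rel=0.01)

    def test_determinism_by_seed(self):
        rng = np.random.default_rng(8)
        pts = rng.standard_normal((40, 2))
        assert np.array_equal(seab(pts, seed=9).seab_draws, seab(pts, seed=9).seab_draws)


def _unit_circle_fit(cx):
    return EllipseFit(group="x", invaded=None, n=1000, mean_vec=np.array([cx, 0.0]),
                      cov=np.eye(2), sea=np.pi, seac=np.pi)


class TestOverlap:
    def test_identical_ellipses_fully_overlap(self):
        a, b = _unit_circle_fit(0.0), _unit_circle_fit(0.0)
        area, pa, pb = ellipse_overlap(a, b)
        assert pa == pytest.approx(1.0, abs=1e-6)
        assert pb == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_circles_zero_overlap(self):
        area, pa, pb = ellipse_overlap(_unit_circle_fit(0.0), _unit_circle_fit(10.0))
        assert area == 0.0

    def test_circle_lens_closed_form(self):
        # unit circles centred 1 apart: lens area 2*acos(1/2) - sqrt(3)/2
        want = 2 * np.arccos(0.5) - 0.5 * np.sqrt(3.0)
        area, _, _ = ellipse_overlap(_unit_circle_fit(0.0), _unit_circle_fit(1.0))
        assert area == pytest.approx(want, rel=0.01)

    def test_overlap_bounded_by_smaller_ellipse(self):
        rng = np.random.default_rng(10)
        a = seac(rng.multivariate_normal([0, 0], _random_psd(rng), 40))
        b = seac(rng.multivariate_normal([0.5, 0.5], _random_psd(rng), 40))
        area, pa, pb = ellipse_overlap(a, b)
        assert area <= min(a.seac, b.seac) + 1e-9
        assert 0.0 <= pa <= 1.0 and 0.0 <= pb <= 1.0

    def test_polygon_area_matches_requested_scaling(self):
        cov = np.array([[2.0, 0.3], [0.3, 1.0]])
        poly = ellipse_polygon(np.zeros(2), cov, area_scale=1.5, n_vertices=512)
        assert poly.area == pytest.approx(1.5 * sea_from_cov(cov), rel=1e-3)
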