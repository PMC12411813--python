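"""Isotopic niche ellipses in (δ13C, δ15N) space: SEA, SEAc, SEAb, overlap.

The standard ellipse of a bivariate normal cloud (the isotopic analogue of a
standard deviation) has area SEA = π·sqrt(det Σ) and encloses ≈ 39.35% of
the distribution (the chi-square(2) 1-sigma mass, loosely "40% of the data").
SEAc = SEA·(n−1)/(n−2) corrects the small-sample bias of the plug-in
covariance.  SEAb is the posterior distribution of the ellipse area under a
Bayesian bivariate-normal model with a vague conjugate normal–inverse-Wishart
prior, summarized by its posterior mode (kernel density estimate) and 50/95%
credible intervals.

Overlap between two groups' ellipses is the polygon-intersection area of
their SEAc-scaled standard ellipses; the proportion of each group's own
ellipse that is shared measures potential resource competition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from shapely.geometry import Polygon

__all__ = ["EllipseFit", "sea_from_cov", "seac", "seab", "ellipse_overlap"]

_PSD_TOL = 1e-10


@dataclass
class EllipseFit:
    """Point and (optionally) posterior summary of one stratum's ellipse."""

    group: str
    invaded: bool | None
    n: int
    mean_vec: np.ndarray  # (d13C, d15N)
    cov: np.ndarray  # 2x2
    sea: float
    seac: float
    seab_draws: np.ndarray | None = None
    seab_mode: float | None = None
    seab_mean: float | None = None
    ci50: tuple[float, float] | None = None
    ci95: tuple[float, float] | None = None


def sea_from_cov(cov: np.ndarray) -> float:
    """Standard ellipse area π·sqrt(det Σ) for a 2×2 covariance."""
    cov = np.asarray(cov, float)
    if cov.shape != (2, 2):
        raise ValueError("cov must be 2x2")
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("cov must be symmetric")
    eig = np.linalg.eigvalsh(cov)
    scale = max(abs(eig).max(), 1.0)
    if eig[0] < -_PSD_TOL * scale:
        raise ValueError(f"cov has a negative eigenvalue ({eig[0]:.3g})")
    det = float(np.prod(np.clip(eig, 0.0, None)))
    if det <= _PSD_TOL * scale**2:
        warnings.warn("singular covariance: standard ellipse area is 0")
        return 0.0
    return float(np.pi * np.sqrt(det))


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (d13C, d15N)")
    return pts


def seac(points, group: str = "", invaded: bool | None = None) -> EllipseFit:
    """Sample-size-corrected standard ellipse: SEAc = SEA·(n−1)/(n−2)."""
    pts = _as_points(points)
    n = len(pts)
    if n < 3:
        raise ValueError(f"SEAc needs at least 3 observations, got {n}")
    mean = pts.mean(axis=0)
    cov = np.cov(pts.T, ddof=1)
    sea = sea_from_cov(cov)
    return EllipseFit(
        group=group,
        invaded=invaded,
        n=n,
        mean_vec=mean,
        cov=cov,
        sea=sea,
        seac=sea * (n - 1) / (n - 2),
    )


def seab(
    points,
    group: str = "",
    invaded: bool | None = None,
    n_draws: int = 4000,
    seed: int = 0,
    kappa0: float = 1e-3,
    nu0: float = 3.0,
    psi0_scale: float = 1e-3,
) -> EllipseFit:
    """Bayesian standard ellipse area via the conjugate NIW posterior.

    Prior: mu | Σ ~ N(0, Σ/kappa0), Σ ~ InvWishart(nu0, psi0_scale·I) — a
    minimally proper, vague prior whose influence vanishes for n ≳ 10.  The
    posterior over Σ is again inverse-Wishart, so area draws π·sqrt(det Σ)
    need no MCMC.  The point estimate is the posterior mode of the area
    (Gaussian KDE, Silverman bandwidth), mirroring how SEAb is customarily
    plotted; the posterior mean is also kept.
    """
    fit_ = seac(points, group=group, invaded=invaded)
    pts = _as_points(points)
    n = len(pts)
    xbar = pts.mean(axis=0)
    S = (pts - xbar).T @ (pts - xbar)
    kn = kappa0 + n
    nun = nu0 + n
    psi_n = psi0_scale * np.eye(2) + S + (kappa0 * n / kn) * np.outer(xbar, xbar)
    rng = np.random.default_rng(seed)
    sigmas = stats.invwishart.rvs(df=nun, scale=psi_n, size=n_draws, random_state=rng)
    dets = np.linalg.det(sigmas)
    areas = np.pi * np.sqrt(np.clip(dets, 0.0, None))

    kde = stats.gaussian_kde(areas, bw_method="silverman")
    grid = np.linspace(areas.min(), areas.max(), 512)
    mode = float(grid[np.argmax(kde(grid))])

    fit_.seab_draws = areas
    fit_.seab_mode = mode
    fit_.seab_mean = float(areas.mean())
    fit_.ci50 = (float(np.quantile(areas, 0.25)), float(np.quantile(areas, 0.75)))
    fit_.ci95 = (float(np.quantile(areas, 0.025)), float(np.quantile(areas, 0.975)))
    return fit_


def ellipse_polygon(
    mean_vec: np.ndarray, cov: np.ndarray, area_scale: float = 1.0, n_vertices: int = 256
) -> Polygon:
    """Polygonal approximation of the standard ellipse, axes scaled so the
    ellipse area is multiplied by ``area_scale`` (e.g. (n−1)/(n−2) for SEAc)."""
    eigval, eigvec = np.linalg.eigh(np.asarray(cov, float))
    eigval = np.clip(eigval, 0.0, None)
    radii = np.sqrt(eigval) * np.sqrt(area_scale)
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    circle = np.stack([np.cos(theta), np.sin(theta)])
    boundary = (eigvec @ (radii[:, None] * circle)).T + np.asarray(mean_vec, float)
    return Polygon(boundary)


def ellipse_overlap(
    fit_a: EllipseFit, fit_b: EllipseFit, n_vertices: int = 256
) -> tuple[float, float, float]:
    """Intersection area of two SEAc-scaled standard ellipses.

    Returns (overlap area ‰², proportion of A's ellipse, proportion of B's).
    Polygonal approximation with ``n_vertices`` vertices; the inscribed-
    polygon area error is O(1/n_vertices²), well under 0.1% at the default.
    """
    if fit_a.seac == 0 or fit_b.seac == 0:
        warnings.warn("singular ellipse: overlap reported as 0")
        return 0.0, 0.0, 0.0
    polys = []
    for f in (fit_a, fit_b):
        scale = f.seac / f.sea if f.sea > 0 else 1.0
        polys.append(ellipse_polygon(f.mean_vec, f.cov, area_scale=scale, n_vertices=n_vertices))
    inter = polys[0].intersection(polys[1]).area
    return float(inter), float(inter / polys[0].area), float(inter / polys[1].area)
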