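"""Layman niche-structure metrics and invaded-vs-non-invaded percent change.

Six point-cloud statistics of a group's (δ13C, δ15N) observations summarize
niche breadth and internal structure: convex-hull total area (overall niche
width), δ13C range (diversity of basal carbon sources), δ15N range (vertical
trophic structure), mean distance to centroid (average trophic diversity),
mean nearest-neighbour distance (packing density) and its SD (evenness).
Here the points are individual organisms within a group × invasion-status
stratum, pooled across sites, so each group's niche can be compared between
invaded and non-invaded reaches of the river.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "LaymanMetrics",
    "MetricChange",
    "layman_metrics",
    "percent_change",
    "average_percent_change",
    "layman_table",
    "METRIC_NAMES",
]

METRIC_NAMES = ("cd", "mnnd", "sdnnd", "total_area", "cr", "nr")

METRIC_LABELS = {
    "cd": "Mean distance to centroid",
    "mnnd": "Mean nearest neighbor distance",
    "sdnnd": "SD of nearest neighbor distance",
    "total_area": "Total area",
    "cr": "d13C range",
    "nr": "d15N range",
}


@dataclass
class LaymanMetrics:
    group: str
    invaded: bool | None
    n: int
    total_area: float | None  # ‰²; None when n < 3
    cr: float
    nr: float
    cd: float
    mnnd: float | None
    sdnnd: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass
class MetricChange:
    group: str
    metric: str
    value_noninvaded: float
    value_invaded: float
    percent_change: float | None


def _hull_area(pts: np.ndarray) -> float:
    try:
        return float(ConvexHull(pts).volume)  # "volume" is area in 2D
    except QhullError:
        # collinear / coincident points: degenerate hull has zero area
        return 0.0


def layman_metrics(points, group: str = "", invaded: bool | None = None) -> LaymanMetrics:
    """All six metrics for one stratum; sub-minimum metrics come back None.

    total_area needs n ≥ 3 (degenerate collinear clouds get area 0); the
    nearest-neighbour metrics need n ≥ 2.  Ranges use max − min; cd is the
    mean Euclidean distance to the coordinate-wise centroid; sdnnd uses the
    n−1 denominator.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (d13C, d15N)")
    n = len(pts)
    if n < 2:
        raise ValueError("Layman metrics need at least 2 observations")
    cr = float(pts[:, 0].max() - pts[:, 0].min())
    nr = float(pts[:, 1].max() - pts[:, 1].min())
    centroid = pts.mean(axis=0)
    cd = float(np.mean(np.linalg.norm(pts - centroid, axis=1)))
    dm = squareform(pdist(pts))
    np.fill_diagonal(dm, np.inf)
    nnd = dm.min(axis=1)
    mnnd = float(nnd.mean())
    sdnnd = float(np.std(nnd, ddof=1)) if n >= 2 else None
    total_area = _hull_area(pts) if n >= 3 else None
    return LaymanMetrics(
        group=group, invaded=invaded, n=n, total_area=total_area,
        cr=cr, nr=nr, cd=cd, mnnd=mnnd, sdnnd=sdnnd,
    )


def percent_change(value_noninvaded: float, value_invaded: float) -> float | None:
    """Signed 100·(invaded − non-invaded)/non-invaded; None when undefined."""
    if value_noninvaded == 0:
        return None
    return 100.0 * (value_invaded - value_noninvaded) / value_noninvaded


def average_percent_change(changes: dict[str, float | None]) -> tuple[int | None, list[str]]:
    """Mean of the six signed percent changes, rounded to the nearest integer.

    Returns (average, missing-metric names); the average is None if any of
    the six metrics is missing.
    """
    missing = [m for m in METRIC_NAMES if changes.get(m) is None]
    if missing:
        return None, missing
    mean = float(np.mean([changes[m] for m in METRIC_NAMES]))
    return int(round(mean)), []


def layman_table(
    data: pd.DataFrame,
    d15n_column: str = "d15n_adjusted",
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group metric table with non-invaded, invaded and % change columns.

    Uses baseline-adjusted δ15N by default so strata pooled over sites are
    comparable; pass ``d15n_column="d15n_permil"`` for raw values.  Groups
    present at only one invasion level are reported without a change column.
    """
    if groups is None:
        groups = sorted(data["group"].unique())
    rows = []
    for g in groups:
        per_status: dict[bool, LaymanMetrics | None] = {}
        for inv in (False, True):
            sub = data[(data["group"] == g) & (data["invaded"] == inv)]
            pts = sub[["d13c_permil", d15n_column]].to_numpy(float)
            per_status[inv] = layman_metrics(pts, group=g, invaded=inv) if len(pts) >= 2 else None
        changes: dict[str, float | None] = {}
        for m in METRIC_NAMES:
            v_non = per_status[False].as_dict()[m] if per_status[False] else None
            v_inv = per_status[True].as_dict()[m] if per_status[True] else None
            pc = (
                percent_change(v_non, v_inv)
                if v_non is not None and v_inv is not None
                else None
            )
            changes[m] = pc
            rows.append(
                {
                    "group": g,
                    "metric": METRIC_LABELS[m],
                    "metric_key": m,
                    "noninvaded": None if v_non is None else round(v_non, 2),
                    "invaded": None if v_inv is None else round(v_inv, 2),
                    "percent_change": None if pc is None else round(pc, 2),
                }
            )
        avg, missing = average_percent_change(changes)
        rows.append(
            {
                "group": g,
                "metric": "Average percent change",
                "metric_key": "average",
                "noninvaded": None,
                "invaded": None,
                "percent_change": avg,
            }
        )
    return pd.DataFrame(rows)
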