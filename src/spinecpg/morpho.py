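"""Zebrafish axial-curvature morphometrics.

The severity of body curvature is summarized by a single θ angle computed
from the ordered midline of a fish: the vertex is the midline point farthest
from the head-tail chord, and θ is 180° minus the interior angle at that
vertex between the vertex→head and vertex→tail vectors. A straight body
gives θ = 0; for a circular-arc midline with central angle 2θ the statistic
returns θ exactly (inscribed-angle geometry), which is the closed-form
oracle used in the tests. Fish with θ ≥ 10° (boundary inclusive) are
classified as curved; penetrance is the percentage of curved fish.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import cross2, round_sigfigs
from .errors import DegenerateInputError, ParameterError

CURVED_THRESHOLD_DEG = 10.0


@dataclass
class BodyAxis:
    """Ordered 2D midline of one fish, head first."""

    points: np.ndarray  # (n, 2) in mm or pixels
    fish_id: str | None = None
    genotype: str | None = None
    treatment: str | None = None
    age_dpf: float | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ParameterError("points must be an (n, 2) array")
        if pts.shape[0] < 3:
            raise ParameterError("a body axis needs at least 3 points")
        if not np.all(np.isfinite(pts)):
            raise ParameterError("points contain non-finite values")
        if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise ParameterError("duplicate consecutive points")
        self.points = pts


@dataclass
class CurvatureRecord:
    theta_deg: float
    curved: bool
    threshold_deg: float = CURVED_THRESHOLD_DEG


@dataclass
class PenetranceSummary:
    n_total: int
    n_curved: int
    penetrance_pct: float  # exact 100*n_curved/n_total; round for display
    thetas: np.ndarray     # severity distribution

    @property
    def penetrance_pct_3sf(self) -> float:
        return round_sigfigs(self.penetrance_pct, 3)


def _smooth_midline(pts: np.ndarray, window: int) -> np.ndarray:
    """Moving-average smoothing of interior points; endpoints kept.

    Applied only when the polyline is long enough (>= 2*window + 1 points)
    that smoothing suppresses coordinate noise without displacing the vertex
    of a short polyline.
    """
    n = len(pts)
    if window <= 1 or n < 2 * window + 1:
        return pts
    kernel = np.ones(window) / window
    sm = pts.copy()
    for d in range(2):
        sm[:, d] = np.convolve(pts[:, d], kernel, mode="same")
    half = window // 2
    sm[:half + 1] = pts[:half + 1]
    sm[-(half + 1):] = pts[-(half + 1):]
    return sm


def theta_angle(axis: BodyAxis, smooth_window: int = 3) -> float:
    """Curvature angle θ in degrees, in [0, 180).

    Invariant under rotation, translation, reflection, uniform scaling, and
    head-tail reversal of the point set; 0 for collinear points.
    """
    pts = _smooth_midline(axis.points, smooth_window)
    head, tail = pts[0], pts[-1]
    chord = tail - head
    chord_len = np.hypot(*chord)
    span = np.ptp(pts, axis=0).max()
    if span == 0:
        raise DegenerateInputError("all midline points coincide")
    if chord_len < 1e-12 * span:
        raise DegenerateInputError("head and tail coincide; θ undefined")
    # perpendicular distance of interior points from the head-tail chord
    dist = np.abs(cross2(chord, pts - head)) / chord_len
    interior = slice(1, len(pts) - 1)
    rel = dist[interior] / chord_len
    if rel.max() < 1e-9:
        return 0.0
    vertex = pts[1 + int(np.argmax(dist[interior]))]
    v1, v2 = head - vertex, tail - vertex
    inner = np.degrees(np.arctan2(np.abs(cross2(v1, v2)), np.dot(v1, v2)))
    theta = 180.0 - inner
    return float(min(max(theta, 0.0), np.nextafter(180.0, 0.0)))


def classify_curved(theta_deg: float,
                    threshold_deg: float = CURVED_THRESHOLD_DEG) -> bool:
    """Curved phenotype iff θ ≥ threshold (boundary inclusive)."""
    if not np.isfinite(theta_deg):
        raise ParameterError("θ must be finite")
    return bool(theta_deg >= threshold_deg)


def curvature_record(axis: BodyAxis, threshold_deg: float = CURVED_THRESHOLD_DEG,
                     smooth_window: int = 3) -> CurvatureRecord:
    th = theta_angle(axis, smooth_window)
    return CurvatureRecord(theta_deg=th, curved=classify_curved(th, threshold_deg),
                           threshold_deg=threshold_deg)


def penetrance(thetas: Sequence[float],
               threshold_deg: float = CURVED_THRESHOLD_DEG) -> PenetranceSummary:
    """Fraction of fish with θ ≥ threshold, as a percentage."""
    th = np.asarray(list(thetas), dtype=float)
    if th.size == 0:
        raise ParameterError("penetrance of an empty group is undefined")
    n_curved = int(np.sum(th >= threshold_deg))
    return PenetranceSummary(
        n_total=int(th.size),
        n_curved=n_curved,
        penetrance_pct=100.0 * n_curved / th.size,
        thetas=th,
    )


def dose_response(groups: Mapping[float, Sequence[float]],
                  threshold_deg: float = CURVED_THRESHOLD_DEG) -> pd.DataFrame:
    """Per-dose penetrance and severity table, sorted by dose.

    The returned frame carries ``attrs["penetrance_monotone"]``, a flag for
    whether estimated penetrance is nondecreasing in dose.
    """
    if not groups:
        raise ParameterError("dose_response needs at least one group")
    rows = []
    for dose in sorted(groups):
        summ = penetrance(groups[dose], threshold_deg)
        rows.append({
            "dose": dose,
            "n": summ.n_total,
            "n_curved": summ.n_curved,
            "penetrance_pct": summ.penetrance_pct,
            "mean_theta_deg": float(np.mean(summ.thetas)),
        })
    df = pd.DataFrame(rows)
    df.attrs["penetrance_monotone"] = bool(
        np.all(np.diff(df["penetrance_pct"].to_numpy()) >= 0))
    return df


@dataclass
class GroupComparison:
    test_name: str           # "t_unpaired" or "anova_oneway"
    statistic: float
    df: tuple
    p_value: float


def compare_groups(theta_groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Two groups → unpaired Student's t test; more → one-way ANOVA."""
    groups = {k: np.asarray(list(v), dtype=float) for k, v in theta_groups.items()}
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    if any(g.size < 2 for g in groups.values()):
        raise ParameterError("each group needs at least 2 observations")
    arrays = list(groups.values())
    if len(arrays) == 2:
        res = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
        dof = arrays[0].size + arrays[1].size - 2
        return GroupComparison("t_unpaired", float(res.statistic), (dof,),
                               float(res.pvalue))
    res = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    return GroupComparison("anova_oneway", float(res.statistic), (k - 1, n - k),
                           float(res.pvalue))
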