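"""Contour-accuracy metrics: HSC, Dice, and simplified surface-DSC/APL.

The central metric is the *boundary-point untouched fraction* (HSC)::

    HSC = N_U / N_T

where ``N_T`` is the total number of boundary points of the **final**
(clinically accepted) contour and ``N_U`` the number of those points that
also appear — within a matching tolerance — in the initial contour, i.e.
that were left untouched during contour adjustment.  The metric is
deliberately asymmetric: the denominator is always the final contour, so
extra points of an oversized initial contour never inflate the score.

Matching is 3D Euclidean but restricted to paired slices (contour editing
is per-slice): z planes of the two structures pair when within half the
smaller slice thickness.  Within a paired slice, matching is one-to-one by
default — candidate pairs are processed in ascending distance order and
each initial point may certify at most one final point — so a single
stationary initial point cannot certify many final points.  A permissive
``many_to_one`` discipline is available for sensitivity checks.

The volumetric Dice coefficient and slice-wise simplified surface-DSC /
added-path-length comparators are provided for benchmarking the HSC
against overlap-based metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import cKDTree

from .contour_io import RasterGrid, rasterize
from .contour_model import SliceContour, Structure
from .errors import GeometryError

#: default matching tolerance (mm) operationalizing "unchanged coordinates"
DEFAULT_MATCH_TOL = 1e-6
#: default clinical tolerance (mm) for the adapted HSC
DEFAULT_CLINICAL_TOL = 0.5


@dataclass(frozen=True)
class MetricResult:
    """A metric value together with its provenance."""

    metric_name: str
    value: float
    n_untouched: int | None = None
    n_total_final: int | None = None
    match_tol: float | None = None
    grid: RasterGrid | None = None

    def to_dict(self) -> dict:
        d = {
            "metric": self.metric_name,
            "value": self.value,
            "n_untouched": self.n_untouched,
            "n_total_final": self.n_total_final,
            "match_tol": self.match_tol,
        }
        if self.grid is not None:
            d["pixel_size"] = self.grid.pixel_size
            d["n_planes"] = len(self.grid.z_planes)
        return d


def _pair_slices(a: Structure, b: Structure):
    """Yield (slice_of_a, matching slice_of_b or None) pairs.

    Slices pair when their z values agree within half the smaller slice
    thickness; each b-slice pairs with at most one a-slice (nearest z).
    """
    tol = 0.5 * min(a.slice_thickness, b.slice_thickness)
    bz = b.z_values
    used = set()
    for sa in a.slices:
        if len(bz) == 0:
            yield sa, None
            continue
        d = np.abs(bz - sa.z)
        k = int(np.argmin(d))
        if d[k] <= tol and k not in used:
            used.add(k)
            yield sa, b.slices[k]
        else:
            yield sa, None


def _count_untouched(final_pts, initial_pts, tol, matching):
    """Count final points certified by an initial point within ``tol``."""
    if len(initial_pts) == 0:
        return 0
    tree = cKDTree(initial_pts)
    if matching == "many_to_one":
        d, _ = tree.query(final_pts, k=1)
        return int(np.sum(d <= tol))
    # one-to-one greedy by ascending pair distance; deterministic
    # tie-break on (distance, final index, initial index)
    pairs = []
    for fi, cands in enumerate(tree.query_ball_point(final_pts, tol)):
        for ij in cands:
            d = float(np.linalg.norm(final_pts[fi] - initial_pts[ij]))
            pairs.append((d, fi, ij))
    pairs.sort()
    used_f, used_i = set(), set()
    n = 0
    for _, fi, ij in pairs:
        if fi in used_f or ij in used_i:
            continue
        used_f.add(fi)
        used_i.add(ij)
        n += 1
    return n


def hsc(
    initial: Structure,
    final: Structure,
    match_tol: float = DEFAULT_MATCH_TOL,
    matching: str = "one_to_one",
) -> MetricResult:
    """Untouched fraction of final-contour boundary points (N_U / N_T).

    Parameters
    ----------
    initial : Structure
        The contour before adjustment (e.g. auto-generated).
    final : Structure
        The clinically accepted contour after adjustment; its point count
        is the denominator.
    match_tol : float
        Maximum 3D Euclidean distance (mm) at which a final point counts
        as untouched.  The default (1e-6 mm) means "unchanged coordinates"
        while being robust to I/O round-trip float noise.
    matching : {"one_to_one", "many_to_one"}
        Matching discipline within a paired slice.

    Returns
    -------
    MetricResult
        ``value`` in [0, 1] with ``n_untouched``/``n_total_final`` filled.
    """
    if match_tol < 0:
        raise ValueError("match_tol must be >= 0")
    if matching not in ("one_to_one", "many_to_one"):
        raise ValueError(f"unknown matching discipline {matching!r}")
    if not final.slices:
        raise ValueError("final structure is empty; HSC undefined")
    n_total = final.total_points
    n_untouched = 0
    for f_slice, i_slice in _pair_slices(final, initial):
        if i_slice is None:
            continue
        n_untouched += _count_untouched(
            f_slice.points, i_slice.points, match_tol, matching
        )
    return MetricResult(
        "HSC",
        n_untouched / n_total,
        n_untouched=n_untouched,
        n_total_final=n_total,
        match_tol=match_tol,
    )


def adapted_hsc(
    initial: Structure,
    final: Structure,
    clinical_tol: float = DEFAULT_CLINICAL_TOL,
    matching: str = "one_to_one",
) -> MetricResult:
    """HSC with a clinical geometric-deviation tolerance.

    A final boundary point whose nearest initial point lies within
    ``clinical_tol`` (default 0.5 mm) is clinically indistinguishable from
    unchanged and is counted as untouched.  This is the tolerance-adapted
    variant suitable e.g. for scoring auto-contours whose points are all
    offset by a sub-resolution amount.
    """
    if clinical_tol <= 0:
        raise ValueError("clinical_tol must be > 0")
    r = hsc(initial, final, match_tol=clinical_tol, matching=matching)
    return MetricResult(
        "adapted_HSC",
        r.value,
        n_untouched=r.n_untouched,
        n_total_final=r.n_total_final,
        match_tol=clinical_tol,
    )


def dsc(a: Structure, b: Structure, grid: RasterGrid | None = None) -> MetricResult:
    """Volumetric Dice coefficient 2|A∩B| / (|A| + |B|) on rasterized masks.

    The two structures are rasterized on a common grid (default: a 1 mm
    grid covering both with a 2 mm margin).  Symmetric in its arguments.
    """
    if grid is None:
        grid = RasterGrid.cover([a, b])
    ma = rasterize(a, grid)
    mb = rasterize(b, grid)
    na, nb = int(ma.sum()), int(mb.sum())
    if na + nb == 0:
        raise ValueError("both masks are empty; DSC undefined")
    inter = int(np.logical_and(ma, mb).sum())
    return MetricResult("DSC", 2.0 * inter / (na + nb), grid=grid)


def _boundary_samples(c: SliceContour, n: int) -> np.ndarray:
    """``n`` equally spaced in-plane points along the closed boundary."""
    closed = np.vstack([c.xy, c.xy[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    t = (np.arange(n) + 0.5) * (cum[-1] / n)
    return np.column_stack(
        [np.interp(t, cum, closed[:, 0]), np.interp(t, cum, closed[:, 1])]
    )


def _within_length(c: SliceContour, other: SliceContour | None, tau, n_samples):
    """(boundary length of c within tau of other's boundary, perimeter)."""
    perim = c.perimeter
    if other is None:
        return 0.0, perim
    pts = shapely.points(_boundary_samples(c, n_samples))
    d = shapely.distance(pts, other.polygon.exterior)
    return perim * float(np.mean(d <= tau)), perim


def surface_dsc(
    a: Structure,
    b: Structure,
    tau: float,
    n_samples: int = 512,
) -> float:
    """Simplified slice-wise surface Dice at distance tolerance ``tau``.

    The fraction of each contour's boundary length lying within ``tau`` of
    the other contour's boundary, combined with perimeter weights:
    (L_a_within + L_b_within) / (L_a + L_b).  This is a 2D slice-wise
    comparator, not a full 3D surface implementation.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if not a.slices or not b.slices:
        raise ValueError("surface_dsc needs two non-empty structures")
    num = den = 0.0
    for sa, sb in _pair_slices(a, b):
        w, p = _within_length(sa, sb, tau, n_samples)
        num += w
        den += p
    for sb, sa in _pair_slices(b, a):
        w, p = _within_length(sb, sa, tau, n_samples)
        num += w
        den += p
    return num / den


def apl(
    initial: Structure,
    final: Structure,
    tau: float,
    n_samples: int = 1024,
) -> float:
    """Simplified slice-wise added path length in mm.

    Total arc length of the final contour's boundary lying farther than
    ``tau`` from the initial contour's boundary — the boundary that had to
    be drawn anew during adjustment.  2D slice-wise comparator.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if not final.slices:
        raise ValueError("final structure is empty; APL undefined")
    total = 0.0
    for f_slice, i_slice in _pair_slices(final, initial):
        w, p = _within_length(f_slice, i_slice, tau, n_samples)
        total += p - w
    return total
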