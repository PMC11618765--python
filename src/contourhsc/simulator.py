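"""Synthetic phantom generation and constrained contour-set construction.

The phantom emulates a filled bladder on a pelvic CT: a stack of smooth,
convex-ish superellipse slices at 3 mm spacing, with a rounded inferior
dome, a flat-radius body, and optional seeded low-frequency radial noise.

Two families of degraded contours are constructed from a ground-truth
phantom by the same primitive — keep a contiguous band of slices untouched
and radially shrink every other slice about its centroid by one global
factor:

* **fixed-DSC mode** — for each target untouched-point fraction (HSC), the
  shrink factor is solved so the volumetric Dice against ground truth hits
  one common value (e.g. 0.850);
* **fixed-HSC mode** — one untouched band is fixed (e.g. 46.4% of points)
  and the factor is solved per Dice target (e.g. 0.640 … 0.953).

Because Dice is continuous and monotone in the shrink factor, the original
trial-and-error construction is replaced by deterministic bisection.  The
untouched band is anchored at the inferior pole and grows superiorly: on a
tapered organ an equatorial band would hold a larger volume fraction than
its point fraction, putting the reachable-DSC floor 2·V_u/(V_u+V_gt) above
the low end of the fixed-HSC Dice schedule.  Untouched slices are copied
verbatim, so the HSC numerator is exactly the untouched band's point count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import metrics
from .contour_io import RasterGrid, rasterize_slice
from .contour_model import SliceContour, Structure, centroid
from .errors import GeometryError, InfeasibleTargetError

#: fraction of the stack occupied by the inferior dome of the bladder profile
_DOME_FRACTION = 0.3
#: lower bisection bound for the shrink factor
_FACTOR_FLOOR = 1e-3

#: the two simulated-set schedules used in the validation study
SET1_HSC_TARGETS = (0.0, 0.111, 0.295, 0.507, 0.704)
SET1_DSC = 0.850
SET2_DSC_TARGETS = (0.640, 0.730, 0.765, 0.805, 0.849, 0.899, 0.953)
SET2_HSC = 0.464


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic organ phantom.

    Defaults describe a bladder-like organ: 28 axial slices at 3 mm
    (≈84 mm extent), 40 mm maximal radius, 64 boundary points per slice
    (≈4 mm in-plane point spacing), a mildly squarish superellipse cross
    section, and 1 mm of low-frequency radial noise.
    """

    n_slices: int = 28
    slice_thickness: float = 3.0
    max_radius: float = 40.0
    points_per_slice: int = 64
    superellipse_exponent: float = 2.2
    noise_amp: float = 1.0
    seed: int = 2024
    profile: str = "bladder"  # "bladder" | "cylinder" | "sphere"

    def __post_init__(self):
        if self.n_slices < 3:
            raise ValueError("n_slices must be >= 3")
        if self.max_radius <= 0:
            raise ValueError("max_radius must be > 0")
        if self.points_per_slice < 8:
            raise ValueError("points_per_slice must be >= 8")
        if self.noise_amp < 0:
            raise ValueError("noise_amp must be >= 0")
        if self.profile not in ("bladder", "cylinder", "sphere"):
            raise ValueError(f"unknown profile {self.profile!r}")


@dataclass(frozen=True)
class SimTarget:
    """A constrained-simulation request.

    ``mode="fixed_dsc"``: ``fixed_value`` is the common Dice, and
    ``sweep_values`` are untouched-fraction (HSC) targets.
    ``mode="fixed_hsc"``: ``fixed_value`` is the common untouched fraction,
    and ``sweep_values`` are Dice targets.  ``tol`` bounds the achieved
    deviation of every solved Dice from its target.
    """

    mode: str
    fixed_value: float
    sweep_values: tuple[float, ...]
    tol: float = 0.005

    def __post_init__(self):
        if self.mode not in ("fixed_dsc", "fixed_hsc"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.fixed_value <= 1:
            raise ValueError("fixed_value must be in (0, 1]")
        vals = tuple(self.sweep_values)
        if any(not 0 <= v <= 1 for v in vals):
            raise ValueError("sweep values must be in [0, 1]")
        if list(vals) != sorted(vals):
            raise ValueError("sweep_values must be sorted ascending")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        object.__setattr__(self, "sweep_values", vals)

    @classmethod
    def set1(cls) -> "SimTarget":
        """Fixed-DSC schedule: common DSC 0.850, five HSC targets."""
        return cls("fixed_dsc", SET1_DSC, SET1_HSC_TARGETS)

    @classmethod
    def set2(cls) -> "SimTarget":
        """Fixed-HSC schedule: common HSC 0.464, seven DSC targets."""
        return cls("fixed_hsc", SET2_HSC, SET2_DSC_TARGETS)


@dataclass(frozen=True)
class SimCase:
    """One simulated contour with its construction provenance."""

    index: int
    mode: str
    structure: Structure
    untouched: tuple[int, ...]
    factor: float
    target_hsc: float
    target_dsc: float
    hsc: float
    dsc: float


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------
def _axial_radii(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """(z positions, slice radii) for the requested axial profile."""
    n, dz, R = spec.n_slices, spec.slice_thickness, spec.max_radius
    if spec.profile == "sphere":
        # z centered on the equator; slices outside the sphere are dropped
        z = (np.arange(n) - (n - 1) / 2.0) * dz
        r = np.sqrt(np.maximum(R**2 - z**2, 0.0))
        keep = r > max(0.05 * R, 2.0 * spec.noise_amp)
        return z[keep], r[keep]
    z = np.arange(n) * dz
    t = (np.arange(n) + 0.5) / n
    if spec.profile == "cylinder":
        frac = np.ones(n)
    else:  # bladder: inferior dome, then flat body
        d = _DOME_FRACTION
        frac = np.where(
            t < d, np.sqrt(np.clip(1.0 - ((d - t) / d) ** 2, 0.0, 1.0)), 1.0
        )
    return z, R * frac


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> Structure:
    """Generate the synthetic organ phantom (deterministic given seed).

    Each slice is a superellipse of the profile radius, perturbed by
    low-frequency radial noise (harmonics k=2,3 with seeded amplitudes
    summing to at most ``noise_amp`` mm).
    """
    zs, radii = _axial_radii(spec)
    rng = np.random.default_rng(spec.seed)
    p = spec.superellipse_exponent
    theta = np.arange(spec.points_per_slice) * (2 * np.pi / spec.points_per_slice)
    c, s = np.cos(theta), np.sin(theta)
    ux = np.sign(c) * np.abs(c) ** (2.0 / p)
    uy = np.sign(s) * np.abs(s) ** (2.0 / p)
    slices = []
    for z, r in zip(zs, radii):
        delta = np.zeros_like(theta)
        if spec.noise_amp > 0:
            amps = rng.uniform(0, spec.noise_amp / 2.0, size=2)
            phases = rng.uniform(0, 2 * np.pi, size=2)
            for k, a, ph in zip((2, 3), amps, phases):
                delta += a * np.cos(k * theta + ph)
        x, y = r * ux, r * uy
        rho = np.hypot(x, y)
        scale = 1.0 + delta / rho
        pts = np.column_stack([x * scale, y * scale, np.full_like(theta, z)])
        slices.append(SliceContour(pts))
    return Structure("phantom", slices, spec.slice_thickness)


def default_grid(gt: Structure, pixel_size: float = 1.0) -> RasterGrid:
    """The evaluation grid: 1 mm in-plane pixels covering the phantom."""
    return RasterGrid.cover([gt], pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# Shrink construction
# ---------------------------------------------------------------------------
def shrink_slice(c: SliceContour, factor: float) -> SliceContour:
    """Move every boundary point radially toward the slice centroid.

    ``factor=1`` returns an identical contour; ``factor<1`` displaces every
    point by ``(1-factor)·|p-centroid| > 0``, so the slice contributes zero
    to the HSC numerator at exact matching tolerance.
    """
    if not 0 < factor <= 1:
        raise ValueError(f"shrink factor must be in (0, 1], got {factor}")
    if factor == 1.0:
        return SliceContour(c.points.copy())
    return c.scaled(factor)


def build_shrunk(gt: Structure, untouched: set[int], factor: float,
                 name: str = "simulated") -> Structure:
    """Copy ``untouched`` slices verbatim, shrink the rest by ``factor``."""
    slices = [
        SliceContour(sl.points.copy()) if i in untouched else shrink_slice(sl, factor)
        for i, sl in enumerate(gt.slices)
    ]
    return Structure(name, slices, gt.slice_thickness)


def hsc_from_untouched(gt: Structure, untouched_slices) -> float:
    """Predicted HSC of any contour built by shrinking the complement.

    Untouched slices keep their points exactly, shrunk slices (factor < 1)
    contribute nothing at exact tolerance, so the HSC is the untouched
    point count over the total point count.
    """
    untouched = set(untouched_slices)
    if untouched and (min(untouched) < 0 or max(untouched) >= gt.n_slices):
        raise IndexError("untouched slice index out of range")
    total = gt.total_points
    kept = sum(gt.slices[i].n_points for i in untouched)
    return kept / total


def select_untouched_band(gt: Structure, hsc_target: float) -> tuple[int, ...]:
    """Choose the untouched band whose point fraction is closest to target.

    The band is contiguous, anchored at the inferior (lowest-z) slice, and
    grows superiorly; ties go to the smaller band.
    """
    counts = np.array([s.n_points for s in gt.slices], dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(counts)]) / counts.sum()
    best_k = int(np.argmin(np.abs(cum - hsc_target)))  # argmin takes first tie
    return tuple(range(best_k))


# ---------------------------------------------------------------------------
# Dice-targeted shrink solving
# ---------------------------------------------------------------------------
class _DiceEvaluator:
    """Cached Dice-vs-ground-truth as a function of the shrink factor."""

    def __init__(self, gt: Structure, untouched: set[int], grid: RasterGrid):
        self.gt = gt
        self.untouched = set(untouched)
        self.grid = grid
        self.gt_masks = [rasterize_slice(sl, grid) for sl in gt.slices]
        self.gt_count = int(sum(m.sum() for m in self.gt_masks))
        self.untouched_count = int(
            sum(self.gt_masks[i].sum() for i in self.untouched)
        )

    def __call__(self, factor: float) -> float:
        b_count = self.untouched_count
        inter = self.untouched_count
        for i, sl in enumerate(self.gt.slices):
            if i in self.untouched:
                continue
            m = rasterize_slice(shrink_slice(sl, factor), self.grid)
            b_count += int(m.sum())
            inter += int(np.logical_and(m, self.gt_masks[i]).sum())
        return 2.0 * inter / (self.gt_count + b_count)


def solve_shrink_for_dsc(
    gt: Structure,
    untouched,
    dsc_target: float,
    grid: RasterGrid | None = None,
    tol: float = 0.0025,
    max_iter: int = 60,
) -> tuple[float, float]:
    """Find the shrink factor whose Dice against ground truth hits a target.

    Dice is monotone non-decreasing in the factor, so plain bisection on
    [1e-3, 1] converges; iteration stops as soon as the achieved Dice is
    within ``tol`` of the target.

    Returns
    -------
    (factor, achieved_dsc)

    Raises
    ------
    InfeasibleTargetError
        If the target lies below the reachable floor — the Dice obtained
        as the factor approaches zero with only the untouched band left —
        or if the untouched band covers every slice but the target is < 1.
    """
    untouched = set(untouched)
    if grid is None:
        grid = default_grid(gt)
    if not 0 < dsc_target <= 1:
        raise ValueError("dsc_target must be in (0, 1]")
    if len(untouched) == gt.n_slices:
        if dsc_target >= 1.0 - tol:
            return 1.0, 1.0
        raise InfeasibleTargetError(
            "every slice is untouched, so DSC is pinned at 1.0 "
            f"and the target {dsc_target} is unreachable",
            floor=1.0,
        )
    if dsc_target == 1.0:
        return 1.0, 1.0
    evaluate = _DiceEvaluator(gt, untouched, grid)
    floor = evaluate(_FACTOR_FLOOR)
    if dsc_target < floor - tol:
        raise InfeasibleTargetError(
            f"DSC target {dsc_target:.3f} is below the reachable floor "
            f"{floor:.3f} for this untouched band",
            floor=floor,
        )
    lo, hi = _FACTOR_FLOOR, 1.0
    best = (hi, 1.0)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        d = evaluate(mid)
        if abs(d - dsc_target) < abs(best[1] - dsc_target):
            best = (mid, d)
        if abs(d - dsc_target) <= tol:
            return mid, d
        if d < dsc_target:
            lo = mid
        else:
            hi = mid
    if abs(best[1] - dsc_target) <= tol:
        return best
    raise GeometryError(
        f"bisection did not reach DSC {dsc_target:.3f} within tol {tol:g} "
        f"(best achieved {best[1]:.4f}); the grid may be too coarse"
    )


# ---------------------------------------------------------------------------
# Set construction
# ---------------------------------------------------------------------------
def _make_case(gt, grid, index, mode, untouched, factor, t_hsc, t_dsc) -> SimCase:
    s = build_shrunk(gt, set(untouched), factor, name=f"{mode}_case{index}")
    measured_hsc = metrics.hsc(s, gt).value
    measured_dsc = metrics.dsc(s, gt, grid).value
    return SimCase(
        index=index,
        mode=mode,
        structure=s,
        untouched=tuple(sorted(untouched)),
        factor=factor,
        target_hsc=t_hsc,
        target_dsc=t_dsc,
        hsc=measured_hsc,
        dsc=measured_dsc,
    )


def build_fixed_dsc_set(
    gt: Structure,
    target: SimTarget,
    grid: RasterGrid | None = None,
) -> list[SimCase]:
    """Contours sharing one Dice value but sweeping the untouched fraction.

    For each HSC target, the untouched band closest in point mass is
    selected and the shrink factor solved so the Dice equals
    ``target.fixed_value`` within ``target.tol``.  Achieved values are
    measured with the metrics module, not assumed.
    """
    if target.mode != "fixed_dsc":
        raise ValueError("target.mode must be 'fixed_dsc'")
    if grid is None:
        grid = default_grid(gt)
    cases = []
    for i, h in enumerate(target.sweep_values, start=1):
        untouched = select_untouched_band(gt, h)
        factor, _ = solve_shrink_for_dsc(
            gt, untouched, target.fixed_value, grid, tol=target.tol / 2
        )
        cases.append(
            _make_case(gt, grid, i, "fixed_dsc", untouched, factor,
                       h, target.fixed_value)
        )
    return cases


def build_fixed_hsc_set(
    gt: Structure,
    target: SimTarget,
    grid: RasterGrid | None = None,
) -> list[SimCase]:
    """Contours sharing one untouched fraction but sweeping the Dice.

    One untouched band (closest achievable to ``target.fixed_value``) is
    fixed for all cases, so every member has the identical measured HSC;
    the shrink factor is solved per Dice target.
    """
    if target.mode != "fixed_hsc":
        raise ValueError("target.mode must be 'fixed_hsc'")
    if grid is None:
        grid = default_grid(gt)
    untouched = select_untouched_band(gt, target.fixed_value)
    cases = []
    for i, d in enumerate(target.sweep_values, start=1):
        factor, _ = solve_shrink_for_dsc(
            gt, untouched, d, grid, tol=target.tol / 2
        )
        cases.append(
            _make_case(gt, grid, i, "fixed_hsc", untouched, factor,
                       target.fixed_value, d)
        )
    return cases
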