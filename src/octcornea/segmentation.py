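"""Corneal interface segmentation by gradient cost + shortest-path search.

Each of the four interfaces (air-epithelium, epithelium-Bowman,
Bowman-stroma, stroma-posterior) is extracted as the left-to-right path of
minimal total gradient-derived cost through the B-scan, with the vertical
step between neighbouring columns bounded.  The Bowman-stroma interface —
the low-contrast one — is searched inside a band around a spline through a
few operator seed points (or around the epithelium-Bowman trace plus a
nominal Bowman thickness when no seeds are given), and a manual-correction
hook lets stated column ranges be shifted by stated row offsets.

The path problem is solved exactly by column-wise dynamic programming:
for this graph class (one node per (row, column), edges only between
adjacent columns with |row change| <= max_step) DP is the shortest-path
algorithm, in linear time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter

from .synthetic import BScan

INTERFACES = ("air_epithelium", "epithelium_bowman", "bowman_stroma", "stroma_posterior")

COST_EPS = 1e-6


@dataclass
class SegmentationConfig:
    """Tunables of the boundary search.

    Bands are expressed as geometric tissue depths (um) and converted to
    axial pixels through the scan geometry, so they track the physical
    layer thicknesses rather than the sampling.
    """

    max_step: int = 2                      # px, vertical step bound between columns
    smooth_sigma: float = 1.0              # px, Gaussian pre-smoothing of the image
    spline_band_halfwidth_px: float = 10.0 # band half-width around the seed spline
    epithelium_band_um: tuple[float, float] = (25.0, 95.0)
    bowman_band_um: tuple[float, float] = (6.0, 40.0)
    # generous upper bound: the vertical (A-scan) gap between the stromal
    # interfaces grows ~1/cos of the surface tilt near the Bowman edge
    stroma_band_um: tuple[float, float] = (280.0, 800.0)
    #: validity threshold on the signed gradient at the trace.  Must sit
    #: well above the column-wise *maximum* noise gradient (the path is a
    #: per-column near-maximum, an extreme value, ~10 at the default
    #: noise level), and below the weakest true edge response (~30).
    min_edge_gradient: float = 15.0
    #: Bowman's-layer validity uses band contrast rather than the point
    #: gradient: the mean intensity between the two Bowman traces must
    #: differ from the stroma below by at least this much.  Band means
    #: average out spatially correlated (speckle-like) noise that can
    #: suppress the point gradient over long column runs.
    bowman_min_band_contrast: float = 15.0
    edge_offset_px: float = 0.0            # calibration offset added to reported rows
    polarity: dict = field(
        default_factory=lambda: {
            "air_epithelium": "dark_to_bright",
            "epithelium_bowman": "bright_to_dark",
            "bowman_stroma": "dark_to_bright",
            "stroma_posterior": "bright_to_dark",
        }
    )


@dataclass
class BoundaryTrace:
    """One interface trace: sub-pixel axial position per column + validity."""

    interface: str
    rows: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.rows.shape != self.valid.shape:
            raise ValueError("rows and valid must have the same length")


@dataclass
class BoundarySet:
    """The four interface traces of one B-scan, ordering-enforced."""

    air_epithelium: BoundaryTrace
    epithelium_bowman: BoundaryTrace
    bowman_stroma: BoundaryTrace
    stroma_posterior: BoundaryTrace
    geometry: object = None
    region: str | None = None
    clipped: np.ndarray | None = None  # columns where ordering was enforced

    def trace(self, interface: str) -> BoundaryTrace:
        return getattr(self, interface)

    def traces(self):
        return [self.trace(i) for i in INTERFACES]


def gradient_cost(image, polarity: str) -> np.ndarray:
    """Positive cost grid from the signed vertical intensity gradient.

    ``cost = max(signed_gradient) - signed_gradient + eps`` where the signed
    gradient is +dI/drow for ``dark_to_bright`` and -dI/drow for
    ``bright_to_dark`` — a monotone decreasing transform, so the minimal
    cost row is the strongest matching transition, and strictly positive so
    path length is well defined.
    """
    if polarity not in ("dark_to_bright", "bright_to_dark"):
        raise ValueError(f"unknown polarity {polarity!r}")
    a = image.intensity if isinstance(image, BScan) else image
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("need a 2-D image with at least 2 rows")
    # backward difference: the transition is attributed to the first row of
    # the new medium, so the cost minimum sits on the interface row itself
    g = np.diff(a, axis=0, prepend=a[:1])
    if polarity == "bright_to_dark":
        g = -g
    return (g.max() - g) + COST_EPS


#: transition preference order: smaller |row change| first, then the upper
#: (smaller) predecessor row — deterministic tie-breaking
def _shift_order(max_step: int) -> list[int]:
    order = [0]
    for m in range(1, max_step + 1):
        order.extend([-m, m])
    return order


def shortest_path_boundary(
    cost: np.ndarray,
    band: tuple[np.ndarray, np.ndarray] | None = None,
    max_step: int = 2,
) -> BoundaryTrace:
    """Exact minimal-cost left-to-right path with bounded vertical step.

    ``band`` restricts each column to an inclusive [lo, hi] row interval.
    Raises ValueError when the band admits no feasible path under
    ``max_step``.  Returns integer rows (sub-pixel refinement is applied
    separately by :func:`segment_cornea`).
    """
    cost = np.asarray(cost, dtype=float)
    H, W = cost.shape
    if max_step < 0:
        raise ValueError("max_step must be >= 0")
    if band is None:
        lo = np.zeros(W, dtype=int)
        hi = np.full(W, H - 1, dtype=int)
    else:
        lo = np.clip(np.asarray(band[0], dtype=int), 0, H - 1)
        hi = np.clip(np.asarray(band[1], dtype=int), 0, H - 1)
        if np.any(lo > hi):
            raise ValueError("infeasible band: empty column interval")

    INF = np.inf
    dp = np.full(H, INF)
    dp[lo[0] : hi[0] + 1] = cost[lo[0] : hi[0] + 1, 0]
    ptr = np.zeros((H, W), dtype=np.int8)
    shifts = _shift_order(max_step)
    for j in range(1, W):
        best = np.full(H, INF)
        choice = np.zeros(H, dtype=np.int8)
        for s in shifts:  # predecessor row = r + s
            cand = np.full(H, INF)
            if s == 0:
                cand = dp
            elif s > 0:
                cand[:-s] = dp[s:]
            else:
                cand[-s:] = dp[:s]
            better = cand < best
            best[better] = cand[better]
            choice[better] = s
        col = np.full(H, INF)
        sl = slice(lo[j], hi[j] + 1)
        col[sl] = best[sl] + cost[sl, j]
        if not np.any(np.isfinite(col)):
            raise ValueError(f"infeasible band: column {j} unreachable under max_step={max_step}")
        ptr[:, j] = choice
        dp = col

    rows = np.empty(W, dtype=int)
    rows[-1] = int(np.argmin(dp))  # ties -> upper row (first minimum)
    for j in range(W - 1, 0, -1):
        rows[j - 1] = rows[j] + ptr[rows[j], j]
    return BoundaryTrace("path", rows.astype(float), np.ones(W, dtype=bool))


def refine_subpixel(cost: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Parabolic refinement of the cost minimum across the 3 rows around the
    path; shifts are confined to +/-0.5 px."""
    H = cost.shape[0]
    r = np.round(rows).astype(int)
    out = rows.astype(float).copy()
    interior = (r >= 1) & (r <= H - 2)
    cols = np.nonzero(interior)[0]
    cm = cost[r[cols] - 1, cols]
    c0 = cost[r[cols], cols]
    cp = cost[r[cols] + 1, cols]
    denom = cm - 2 * c0 + cp
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 0.5 * (cm - cp) / denom
    delta = np.where(np.isfinite(delta), np.clip(delta, -0.5, 0.5), 0.0)
    out[cols] = r[cols] + delta
    return out


def spline_init_boundary(seed_points, n_columns: int) -> BoundaryTrace:
    """Initial boundary estimate from sparse operator seed points.

    A (not-a-knot) cubic spline through the points, evaluated at every
    column; beyond the outer seeds the end slopes are extended linearly.
    """
    pts = sorted((float(c), float(r)) for c, r in seed_points)
    if len(pts) < 2:
        raise ValueError("need at least 2 seed points")
    cols = np.array([p[0] for p in pts])
    vals = np.array([p[1] for p in pts])
    if np.any(np.diff(cols) == 0):
        raise ValueError("duplicate seed-point columns")
    x = np.arange(n_columns, dtype=float)
    if len(pts) == 2:
        rows = np.interp(x, cols, vals)
        slope = (vals[1] - vals[0]) / (cols[1] - cols[0])
        rows = np.where(x < cols[0], vals[0] + slope * (x - cols[0]), rows)
        rows = np.where(x > cols[-1], vals[-1] + slope * (x - cols[-1]), rows)
    else:
        cs = CubicSpline(cols, vals)
        rows = cs(x)
        dl, dr = float(cs(cols[0], 1)), float(cs(cols[-1], 1))
        left = x < cols[0]
        right = x > cols[-1]
        rows[left] = vals[0] + dl * (x[left] - cols[0])
        rows[right] = vals[-1] + dr * (x[right] - cols[-1])
    return BoundaryTrace("spline_init", rows, np.ones(n_columns, dtype=bool))


def _edge_gradient(smoothed: np.ndarray, rows: np.ndarray, polarity: str) -> np.ndarray:
    """Signed smoothed gradient sampled at the (rounded) trace rows."""
    H = smoothed.shape[0]
    g = np.diff(smoothed, axis=0, prepend=smoothed[:1])
    if polarity == "bright_to_dark":
        g = -g
    r = np.clip(np.round(rows).astype(int), 0, H - 1)
    return g[r, np.arange(smoothed.shape[1])]


def _filled(rows: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Interpolate invalid columns from the valid ones (nearest/linear)."""
    if valid.all():
        return rows
    if not valid.any():
        return rows
    x = np.arange(rows.size)
    return np.interp(x, x[valid], rows[valid])


def segment_cornea(
    image: BScan,
    config: SegmentationConfig | None = None,
    seeds=None,
    corrections=None,
) -> BoundarySet:
    """Segment the four corneal interfaces of one B-scan.

    ``seeds`` (optional) are (column, row) points on the Bowman-stroma
    interface; when given, that interface is searched in a band around the
    seed spline, otherwise below the epithelium-Bowman trace at a nominal
    Bowman thickness.  ``corrections`` is a list of
    ``(interface, col_lo, col_hi, row_offset)`` manual fixes applied to the
    stated inclusive column range.  The interface ordering invariant is
    enforced afterwards: violating columns are clipped and flagged.
    """
    cfg = config or SegmentationConfig()
    geom = image.geometry
    a = np.asarray(image.intensity, dtype=float)
    H, W = a.shape
    smoothed = gaussian_filter(a, cfg.smooth_sigma) if cfg.smooth_sigma > 0 else a
    # validity is checked on a vertically-smoothed image only: lateral
    # smoothing dilutes the vertical gradient of steeply tilted interfaces
    vert_smoothed = gaussian_filter(a, (cfg.smooth_sigma, 0.0)) if cfg.smooth_sigma > 0 else a

    def band_from(rows: np.ndarray, um_lo: float, um_hi: float):
        lo = rows + geom.um_to_axial_px(um_lo)
        hi = rows + geom.um_to_axial_px(um_hi)
        return np.floor(lo).astype(int), np.ceil(hi).astype(int)

    def run(interface: str, band):
        cost = gradient_cost(smoothed, cfg.polarity[interface])
        path = shortest_path_boundary(cost, band=band, max_step=cfg.max_step)
        rows = refine_subpixel(cost, path.rows) + cfg.edge_offset_px
        grad = _edge_gradient(vert_smoothed, rows, cfg.polarity[interface])
        valid = grad >= cfg.min_edge_gradient
        return BoundaryTrace(interface, rows, valid)

    t0 = run("air_epithelium", None)
    if not t0.valid.any():
        raise ValueError("image without detectable anterior surface")
    base = _filled(t0.rows, t0.valid)

    t1 = run("epithelium_bowman", band_from(base, *cfg.epithelium_band_um))
    t1.valid &= t0.valid

    if seeds is not None:
        init = spline_init_boundary(seeds, W).rows
        b2lo = np.floor(init - cfg.spline_band_halfwidth_px).astype(int)
        b2hi = np.ceil(init + cfg.spline_band_halfwidth_px).astype(int)
        t2 = run("bowman_stroma", (b2lo, b2hi))
    else:
        t2 = run("bowman_stroma", band_from(_filled(t1.rows, t1.valid), *cfg.bowman_band_um))
    # Bowman's layer is present where the band between the two traces is
    # darker than the stroma just below (beyond the Bowman edge the two
    # interfaces merge and the contrast vanishes)
    cols = np.arange(W)
    csum = np.cumsum(np.vstack([np.zeros((1, W)), vert_smoothed]), axis=0)

    def band_mean(lo, hi):
        lo = np.clip(np.round(lo).astype(int), 0, H - 1)
        hi = np.clip(np.round(hi).astype(int), 1, H)
        hi = np.maximum(hi, lo + 1)
        return (csum[hi, cols] - csum[lo, cols]) / (hi - lo)

    bowman_band = band_mean(t1.rows + 1, t2.rows)
    stroma_band = band_mean(t2.rows + 2, t2.rows + 12)
    t2.valid = (
        t1.valid
        & (stroma_band - bowman_band >= cfg.bowman_min_band_contrast)
        & (t2.rows - t1.rows >= 3)
    )

    t3 = run("stroma_posterior", band_from(_filled(t2.rows, t2.valid), *cfg.stroma_band_um))
    t3.valid &= t2.valid

    traces = {t.interface: t for t in (t0, t1, t2, t3)}
    if corrections:
        for interface, col_lo, col_hi, offset in corrections:
            if interface not in traces:
                raise ValueError(f"unknown interface {interface!r} in correction")
            sl = slice(int(col_lo), int(col_hi) + 1)
            traces[interface].rows[sl] = traces[interface].rows[sl] + offset
            traces[interface].valid[sl] = True

    # enforce ordering: clip each trace to lie at or below the one above it
    clipped = np.zeros(W, dtype=bool)
    order = [traces[i] for i in INTERFACES]
    for upper, lower in zip(order[:-1], order[1:]):
        viol = lower.rows < upper.rows
        both = viol & upper.valid & lower.valid
        lower.rows = np.maximum(lower.rows, upper.rows)
        clipped |= both

    return BoundarySet(
        air_epithelium=traces["air_epithelium"],
        epithelium_bowman=traces["epithelium_bowman"],
        bowman_stroma=traces["bowman_stroma"],
        stroma_posterior=traces["stroma_posterior"],
        geometry=geom,
        region=image.region,
        clipped=clipped,
    )
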