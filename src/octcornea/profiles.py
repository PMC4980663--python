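"""Zonal averaging and entire-vertical-profile registration.

Each regional scan contributes one 1,000-A-scan analysis window: the
central window is centred on the corneal apex, the peripheral windows run
from the Bowman's-layer edge toward the centre.  A window is averaged
into 10 zones of 100 A-scans (0.42-mm chord each), ordered inferior to
superior, and the three regions are then registered onto one common
apex-anchored chord axis of fixed 0.423-mm bins — peripheral windows
anchored at their Bowman's edge, the central window at the apex — giving
an entire vertical profile of ~26 bins (~11 mm) per layer.  Overlapping
bins are averaged with equal region weights and the number of
contributing regions is recorded per bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import N_ZONES, WINDOW_ASCANS, ZONE_ASCANS, ScanGeometry
from .optics import AScanThicknessProfile
from .segmentation import BoundarySet
from .synthetic import N_HALF_BINS, default_semichord_mm

#: validity-mask gaps up to this many columns are bridged when locating
#: Bowman termini (robustness to single-column segmentation dropouts)
EDGE_GAP_TOLERANCE = 5

#: margin (columns) from the image border within which a validity
#: transition is taken as field-of-view truncation, not a true edge
EDGE_BORDER_MARGIN = 10

#: zones with fewer than this fraction of valid A-scans are flagged
#: partial and excluded from profile merging / index computation
MIN_ZONE_VALID_FRACTION = 0.6

#: merged validity runs shorter than this are noise islands, not tissue
MIN_EDGE_RUN_COLUMNS = 100


@dataclass
class ZonalProfile:
    """10 zone-mean thicknesses of one region/layer, inferior -> superior."""

    region: str
    layer: str
    zone_means_um: np.ndarray
    zone_valid_counts: np.ndarray
    partial: np.ndarray
    zone_chord_mm: float
    window_origin_mm: float  # chord of the window's inferior edge, apex = 0
    window_start_col: int


@dataclass
class VerticalProfile:
    """Entire vertical thickness profile of one layer on the common axis.

    ``bin_index`` counts 0.423-mm bins from the apex (bin b covers
    [b*w, (b+1)*w)); the apex bin has index 0.  ``n_regions`` is the
    number of regions contributing to each bin; flagged bins (no
    non-partial contributor) carry NaN thickness.
    """

    layer: str
    bin_index: np.ndarray
    thickness_um: np.ndarray
    n_regions: np.ndarray
    bin_width_mm: float
    apex_bin: int = 0

    @property
    def chord_mm(self) -> np.ndarray:
        return (self.bin_index + 0.5) * self.bin_width_mm

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.thickness_um) & (self.n_regions > 0)


def detect_bowman_edges(boundaries: BoundarySet, gap_tolerance: int = EDGE_GAP_TOLERANCE) -> dict:
    """Outermost columns where the Bowman's-layer trace terminates.

    Validity gaps of up to ``gap_tolerance`` columns inside the run are
    bridged.  A terminus closer than ``EDGE_BORDER_MARGIN`` columns to the
    image border is field-of-view truncation, not an edge, and is omitted;
    a central image therefore yields ``{}``.  Keys of the result are
    ``"inferior"`` (low-column terminus) and/or ``"superior"``.
    """
    valid = boundaries.epithelium_bowman.valid & boundaries.bowman_stroma.valid
    W = valid.size
    if not valid.any():
        return {}
    idx = np.nonzero(valid)[0]
    # merge runs separated by small gaps; short leftovers are noise
    # islands, and the termini are the outermost columns of the rest
    breaks = np.nonzero(np.diff(idx) > gap_tolerance + 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    lengths = idx[ends] - idx[starts] + 1
    keep = lengths >= MIN_EDGE_RUN_COLUMNS
    if not keep.any():
        keep = lengths == lengths.max()
    first = int(idx[starts[keep][0]])
    last = int(idx[ends[keep][-1]])
    edges = {}
    if first >= EDGE_BORDER_MARGIN:
        edges["inferior"] = first
    if last <= W - 1 - EDGE_BORDER_MARGIN:
        edges["superior"] = last
    return edges


def zonal_average(
    profile: AScanThicknessProfile,
    region: str,
    edges: dict | None = None,
    apex_col: int | None = None,
    geometry: ScanGeometry | None = None,
    bowman_semichord_mm: float | None = None,
) -> ZonalProfile:
    """Average one analysis window into 10 zones of 100 A-scans.

    central: the window is the 1,000 A-scans centred on ``apex_col``;
    peripheral: the 1,000 A-scans from the region's Bowman edge toward the
    centre.  Invalid A-scans are excluded from their block mean and
    counted; zones below ``MIN_ZONE_VALID_FRACTION`` are flagged partial.
    """
    t = profile.thickness_um
    v = profile.valid
    W = t.size
    w_mm = None
    if geometry is not None:
        w_mm = geometry.zone_chord_mm
        semichord = bowman_semichord_mm or default_semichord_mm(geometry)
    else:
        raise ValueError("geometry is required to place the window on the chord axis")

    if region == "central":
        if apex_col is None:
            raise ValueError("central region needs apex_col")
        start = apex_col - WINDOW_ASCANS // 2
        origin = -(N_ZONES // 2) * w_mm
    elif region in ("inferior", "superior"):
        if not edges or region not in edges:
            raise ValueError(
                f"{region} region requires its Bowman's-layer edge in view (protocol)"
            )
        e = edges[region]
        start = e if region == "inferior" else e - WINDOW_ASCANS + 1
        origin = -semichord if region == "inferior" else semichord - N_ZONES * w_mm
    else:
        raise ValueError(f"unknown region {region!r}")

    if start < 0 or start + WINDOW_ASCANS > W:
        raise ValueError(
            f"{region} window [{start}, {start + WINDOW_ASCANS}) truncated by the image border"
        )

    block_t = t[start : start + WINDOW_ASCANS].reshape(N_ZONES, ZONE_ASCANS)
    block_v = v[start : start + WINDOW_ASCANS].reshape(N_ZONES, ZONE_ASCANS)
    counts = block_v.sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(
            counts > 0, np.nansum(np.where(block_v, block_t, 0.0), axis=1) / np.maximum(counts, 1), np.nan
        )
    partial = counts < MIN_ZONE_VALID_FRACTION * ZONE_ASCANS
    return ZonalProfile(
        region=region,
        layer=profile.layer,
        zone_means_um=means,
        zone_valid_counts=counts,
        partial=partial,
        zone_chord_mm=w_mm,
        window_origin_mm=origin,
        window_start_col=int(start),
    )


def register_vertical_profile(
    inferior: ZonalProfile, central: ZonalProfile, superior: ZonalProfile
) -> VerticalProfile:
    """Merge the three regional zonal profiles onto the common chord axis.

    Each zone is placed on the apex-anchored bin grid via its region's
    window origin; overlapping bins are averaged with equal region
    weights.  Raises when a region is missing, the layers differ, or the
    anchors are inconsistent (negative overlap or a gap wider than one
    bin between adjacent regions).
    """
    regions = {"inferior": inferior, "central": central, "superior": superior}
    for name, zp in regions.items():
        if zp is None:
            raise ValueError(f"missing {name} region")
        if zp.region != name:
            raise ValueError(f"profile in {name} slot is labelled {zp.region!r}")
    layers = {zp.layer for zp in regions.values()}
    if len(layers) != 1:
        raise ValueError(f"regions mix layers: {sorted(layers)}")
    w = central.zone_chord_mm

    spans = {}
    for name, zp in regions.items():
        b0 = int(round(zp.window_origin_mm / w))
        spans[name] = (b0, b0 + N_ZONES - 1)

    for lo_name, hi_name in (("inferior", "central"), ("central", "superior")):
        gap = spans[hi_name][0] - spans[lo_name][1] - 1
        if gap > 1:
            raise ValueError(
                f"anchors inconsistent: {gap}-bin gap between {lo_name} and {hi_name} windows"
            )
        if spans[hi_name][1] < spans[lo_name][1]:
            raise ValueError(f"anchors inconsistent: {hi_name} window ends inside {lo_name}")

    b_min = min(s[0] for s in spans.values())
    b_max = max(s[1] for s in spans.values())
    n = b_max - b_min + 1
    total = np.zeros(n)
    count = np.zeros(n, dtype=int)
    for name, zp in regions.items():
        b0 = spans[name][0]
        for k in range(N_ZONES):
            if zp.partial[k] or not np.isfinite(zp.zone_means_um[k]):
                continue
            i = b0 + k - b_min
            total[i] += zp.zone_means_um[k]
            count[i] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return VerticalProfile(
        layer=central.layer,
        bin_index=np.arange(b_min, b_max + 1),
        thickness_um=mean,
        n_regions=count,
        bin_width_mm=w,
    )


def zonal_profiles_from_truth(gt, layer: str, geometry: ScanGeometry) -> dict[str, ZonalProfile]:
    """Ideal regional zonal profiles sampled from ground truth on the
    common axis (no rendering/segmentation), with exact window overlap."""
    w = geometry.zone_chord_mm
    origins = {
        "inferior": -N_HALF_BINS,
        "central": -(N_ZONES // 2),
        "superior": N_HALF_BINS - N_ZONES,
    }
    offs = (np.arange(33) + 0.5) / 33.0
    out = {}
    for region, b0 in origins.items():
        bins = np.arange(b0, b0 + N_ZONES)
        samples = (bins[:, None] + offs[None, :]) * w
        means = gt.layer_thickness(samples.ravel(), layer).reshape(N_ZONES, 33).mean(axis=1)
        out[region] = ZonalProfile(
            region=region,
            layer=layer,
            zone_means_um=means,
            zone_valid_counts=np.full(N_ZONES, ZONE_ASCANS),
            partial=np.zeros(N_ZONES, dtype=bool),
            zone_chord_mm=w,
            window_origin_mm=b0 * w,
            window_start_col=0,
        )
    return out


def truth_vertical_profile(gt, layer: str, geometry: ScanGeometry) -> VerticalProfile:
    """Ground-truth entire profile on the registered bin axis (oracle).

    Uses a finer quadrature than the sampled zonal profiles so the
    round-trip comparison is not trivially exact."""
    from .synthetic import truth_bin_means

    return VerticalProfile(
        layer=layer,
        bin_index=np.arange(-N_HALF_BINS, N_HALF_BINS),
        thickness_um=truth_bin_means(gt, layer, geometry, n_sub=257),
        n_regions=np.ones(2 * N_HALF_BINS, dtype=int),
        bin_width_mm=geometry.zone_chord_mm,
    )


def plot_profiles(profiles: list[VerticalProfile], labels=None, ax=None):
    """Thickness (um) vs chord (mm) panel for entire vertical profiles."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    for i, vp in enumerate(profiles):
        lab = labels[i] if labels else vp.layer
        ax.plot(vp.chord_mm, vp.thickness_um, marker="o", ms=3, label=lab)
    ax.set_xlabel("chord from apex (mm, inferior < 0)")
    ax.set_ylabel("thickness (µm)")
    ax.legend(fontsize=8)
    return ax
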