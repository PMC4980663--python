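"""Synthetic corneas and rendered UHR-OCT B-scans.

The generator produces ground-truth layered corneas with the group-wise
zonal thickness structure reported for normal, sub-clinical keratoconus
(the asymptomatic fellow eye of unilateral KC) and manifest KC eyes, and
renders the three overlapping regional B-scans (central / superior /
inferior) the acquisition protocol produces, so that every downstream
stage — segmentation, refraction correction, zonal profiling, indices,
statistics — can be tested end to end without patient data.

Model
-----
* The anterior surface is a circular arc of radius ``anterior_radius_mm``.
* Each layer's thickness, measured perpendicular to the anterior surface,
  is a smooth function of chord position built from per-bin baseline means
  on the registered 26-bin vertical axis (bin width = one 100-A-scan zone,
  ~0.423 mm; 13 bins inferior and 13 superior of the apex), plus one
  additive subject-level offset per layer, independent per-bin jitter, and
  a localized Gaussian cone thinning::

      t(x) = baseline(x) + offset - cone_depth * exp(-(x - c)^2 / (2 s^2))

* All layers terminate at the Bowman's-layer edge (default semichord
  13 bins ~ 5.50 mm, an 11-mm edge-to-edge vertical meridian).
* Peripheral scans are acquired with the eye rotated so the peripheral
  window sits at the scan pole, mirroring the ~30 degree fixation offsets
  of the acquisition protocol.  The renderer traces each A-scan through
  the refracting anterior surface (Snell, n = 1.389) so boundary pixel
  rows carry the optical distortion the correction stage must undo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from .geometry import N_ZONES, ScanGeometry, DEFAULT_GEOMETRY

LAYERS = ("epithelium", "bowman", "stroma")
REGIONS = ("central", "superior", "inferior")
GROUPS = ("normal", "subclinical_kc", "kc")

#: bins per side of the apex on the registered vertical axis
N_HALF_BINS = 13
N_BINS = 2 * N_HALF_BINS

#: regional mean +/- SD thicknesses (um) for (superior, central, inferior)
#: regions of each layer, per group — the study's group structure.
REGIONAL_THICKNESS_UM = {
    "normal": {
        "epithelium": ((50.91, 3.09), (53.48, 2.83), (54.94, 2.80)),
        "bowman": ((17.18, 1.96), (17.07, 1.51), (17.08, 1.35)),
        "stroma": ((525.27, 32.64), (460.32, 29.65), (533.30, 29.03)),
    },
    "subclinical_kc": {
        "epithelium": ((50.27, 3.02), (51.92, 2.57), (54.85, 3.36)),
        "bowman": ((16.58, 1.75), (16.02, 2.10), (15.70, 1.62)),
        "stroma": ((512.04, 40.82), (454.16, 36.25), (509.67, 38.32)),
    },
    "kc": {
        "epithelium": ((51.09, 4.29), (46.10, 5.31), (54.45, 5.03)),
        "bowman": ((16.23, 2.80), (12.06, 2.50), (15.23, 2.12)),
        "stroma": ((493.15, 32.85), (412.49, 39.19), (482.35, 38.54)),
    },
}

#: localized cone thinning depth (um) per layer; the sub-clinical group
#: carries a shallow cone ("localized central epithelial and inferior
#: Bowman's layer thinning"), manifest KC a deep one.
DEFAULT_CONE_DEPTH_UM = {
    "normal": {"epithelium": 0.0, "bowman": 0.0, "stroma": 0.0},
    "subclinical_kc": {"epithelium": 5.0, "bowman": 1.5, "stroma": 15.0},
    "kc": {"epithelium": 12.0, "bowman": 3.0, "stroma": 40.0},
}

DEFAULT_ANTERIOR_RADIUS_MM = {"normal": 7.8, "subclinical_kc": 7.6, "kc": 7.0}

#: independent per-zone jitter SD (um): small local anatomical variation
#: on top of the smooth profile.  The reported regional SDs are dominated
#: by between-eye variation; attributing them to per-zone noise would give
#: adjacent 0.42-mm zones non-physiological thickness swings.
DEFAULT_ZONAL_NOISE_SD_UM = {"epithelium": 1.0, "bowman": 0.8, "stroma": 5.0}

#: rendered 8-bit mean intensity per tissue class (chosen so every
#: interface has a distinct strongest gradient polarity in its search
#: domain; synthetic contrast, not a speckle model)
TISSUE_INTENSITY = {"background": 20.0, "epithelium": 150.0, "bowman": 60.0, "stroma": 105.0}

DEFAULT_NOISE_SD = 12.0

#: correlation lengths (rows, columns) of the rendered noise field.  OCT
#: speckle is spatially correlated and decorrelates between repeated
#: acquisitions; a correlated field (unlike white noise) moves boundary
#: estimates coherently over many A-scans and therefore carries through
#: 100-A-scan zone means, which is what measurement repeatability sees.
NOISE_CORRELATION_PX = (2.0, 40.0)

#: eye rotation (about the corneal centre of curvature) applied for each
#: regional acquisition is computed so the peripheral window is centred on
#: the scan pole; see `region_rotation_rad`.


def bin_centers_mm(geometry: ScanGeometry = DEFAULT_GEOMETRY) -> np.ndarray:
    """Centres of the 26 registered profile bins (mm from the apex)."""
    w = geometry.zone_chord_mm
    return (np.arange(-N_HALF_BINS, N_HALF_BINS) + 0.5) * w


def default_semichord_mm(geometry: ScanGeometry = DEFAULT_GEOMETRY) -> float:
    """Default Bowman's-edge semichord: 13 zone widths (~5.50 mm)."""
    return N_HALF_BINS * geometry.zone_chord_mm


def _regional_to_bins(values_sup_cen_inf, geometry: ScanGeometry) -> np.ndarray:
    """Evaluate the quadratic through the three regional window centres at
    the 26 bin centres (regions overlap; their centres sit at -8w, 0, +8w)."""
    w = geometry.zone_chord_mm
    sup, cen, inf = values_sup_cen_inf
    xs = np.array([-8.0 * w, 0.0, 8.0 * w])
    coeffs = np.polyfit(xs, [inf, cen, sup], deg=2)
    return np.polyval(coeffs, bin_centers_mm(geometry))


@dataclass
class SyntheticCorneaParams:
    """Population parameters for one study group.

    ``baseline_zonal_means``/``baseline_zonal_sds`` hold per-layer arrays of
    26 per-bin thickness means / SDs (um) on the registered vertical axis.
    ``cone_center_mm`` may be None, in which case each sampled eye draws its
    cone centre uniformly from [-2.5, 0] mm (central to inferior).
    """

    group: str
    baseline_zonal_means: dict[str, np.ndarray]
    baseline_zonal_sds: dict[str, np.ndarray]
    cone_center_mm: float | None
    cone_width_mm: float
    cone_depth_um: dict[str, float]
    anterior_radius_mm: float
    noise_sd: float
    between_eye_sd_um: dict[str, float]
    zonal_noise_sd_um: dict[str, float]
    bowman_semichord_mm: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        for layer in LAYERS:
            means = np.asarray(self.baseline_zonal_means[layer], dtype=float)
            if means.shape != (N_BINS,):
                raise ValueError(f"{layer}: expected {N_BINS} baseline zonal means")
            if np.any(means <= 0):
                raise ValueError(f"{layer}: baseline zonal means must be positive")
            if self.cone_depth_um[layer] < 0:
                raise ValueError(f"{layer}: cone_depth must be >= 0")
        if self.group == "normal" and any(self.cone_depth_um[l] != 0 for l in LAYERS):
            raise ValueError("normal group must have cone_depth = 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_group_params(
    group: str, geometry: ScanGeometry = DEFAULT_GEOMETRY
) -> SyntheticCorneaParams:
    """Study-condition defaults for one group, derived from the reported
    regional means/SDs and the localized-thinning pattern."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    regional = REGIONAL_THICKNESS_UM[group]
    means = {l: _regional_to_bins([m for m, _ in regional[l]], geometry) for l in LAYERS}
    sds = {l: _regional_to_bins([s for _, s in regional[l]], geometry) for l in LAYERS}
    zonal_noise = dict(DEFAULT_ZONAL_NOISE_SD_UM)
    # between-eye offset carries the rest of the reported regional SD
    between = {
        l: math.sqrt(max(float(np.median(sds[l])) ** 2 - zonal_noise[l] ** 2, 0.5**2))
        for l in LAYERS
    }
    return SyntheticCorneaParams(
        group=group,
        baseline_zonal_means=means,
        baseline_zonal_sds=sds,
        cone_center_mm=None,
        cone_width_mm=0.9,
        cone_depth_um=dict(DEFAULT_CONE_DEPTH_UM[group]),
        anterior_radius_mm=DEFAULT_ANTERIOR_RADIUS_MM[group],
        noise_sd=DEFAULT_NOISE_SD,
        between_eye_sd_um=between,
        zonal_noise_sd_um=zonal_noise,
        bowman_semichord_mm=default_semichord_mm(geometry),
    )


@dataclass
class GroundTruthCornea:
    """One eye's ground-truth geometry: smooth per-layer thickness functions
    of chord position plus the anterior-arc parameters."""

    group: str
    subject_id: str
    seed: int
    anterior_radius_mm: float
    semichord_mm: float
    cone_center_mm: float
    cone_width_mm: float
    cone_depth_um: dict[str, float]
    noise_sd: float
    _interpolants: dict[str, PchipInterpolator] = field(repr=False, default_factory=dict)

    def layer_thickness(self, chord_mm, layer: str) -> np.ndarray:
        """Thickness (um) of ``layer`` at chord position(s), perpendicular to
        the anterior surface."""
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
        x = np.asarray(chord_mm, dtype=float)
        base = self._interpolants[layer](x)
        d = self.cone_depth_um[layer]
        if d:
            base = base - d * np.exp(
                -((x - self.cone_center_mm) ** 2) / (2.0 * self.cone_width_mm**2)
            )
        return base

    def interface_depth_um(self, chord_mm, interface_index: int) -> np.ndarray:
        """Cumulative geometric depth (um) below the anterior surface of
        interface ``0..3`` (0 = anterior surface itself)."""
        x = np.asarray(chord_mm, dtype=float)
        depth = np.zeros_like(x, dtype=float)
        for layer in LAYERS[:interface_index]:
            depth = depth + self.layer_thickness(x, layer)
        return depth

    def check_ordering(self, n: int = 512) -> None:
        """Assert interface ordering / positivity across the whole cornea."""
        x = np.linspace(-self.semichord_mm, self.semichord_mm, n)
        for layer in LAYERS:
            t = self.layer_thickness(x, layer)
            if np.any(t <= 0):
                i = int(np.argmin(t))
                raise ValueError(
                    f"non-positive {layer} thickness ({t[i]:.2f} um) at "
                    f"chord {x[i]:+.2f} mm for subject {self.subject_id}"
                )


def sample_cornea_geometry(
    params: SyntheticCorneaParams,
    seed: int,
    subject_id: str | None = None,
    geometry: ScanGeometry = DEFAULT_GEOMETRY,
) -> GroundTruthCornea:
    """Draw one eye from the group distribution. Deterministic given seed."""
    rng = np.random.default_rng(seed)
    centers = bin_centers_mm(geometry)
    cone_center = (
        params.cone_center_mm
        if params.cone_center_mm is not None
        else float(rng.uniform(-2.5, 0.0))
    )
    interpolants = {}
    for layer in LAYERS:
        # draws truncated at +/-3 SD: keeps thin layers (Bowman's, ~12 um
        # centrally in KC after cone thinning) strictly positive
        off_sd = params.between_eye_sd_um[layer]
        jit_sd = params.zonal_noise_sd_um[layer]
        offset = float(np.clip(rng.normal(0.0, off_sd or 1.0), -3 * off_sd, 3 * off_sd)) if off_sd else 0.0
        jitter = np.clip(rng.normal(0.0, jit_sd or 1.0, size=N_BINS), -3 * jit_sd, 3 * jit_sd) if jit_sd else np.zeros(N_BINS)
        values = params.baseline_zonal_means[layer] + offset + jitter
        # monotone-cubic through the bin values, linear beyond the outer bins
        interpolants[layer] = PchipInterpolator(centers, values, extrapolate=True)
    gt = GroundTruthCornea(
        group=params.group,
        subject_id=subject_id or f"{params.group}-{seed}",
        seed=int(seed),
        anterior_radius_mm=params.anterior_radius_mm,
        semichord_mm=params.bowman_semichord_mm,
        cone_center_mm=cone_center,
        cone_width_mm=params.cone_width_mm,
        cone_depth_um=dict(params.cone_depth_um),
        noise_sd=params.noise_sd,
        _interpolants=interpolants,
    )
    gt.check_ordering()
    return gt


# ---------------------------------------------------------------------------
# B-scan rendering
# ---------------------------------------------------------------------------

#: air gap between the image top and the scan pole of the cornea (mm)
APEX_CLEARANCE_MM = 0.15

#: rendered tissue continues this far beyond the Bowman's-layer edge
#: (epithelium and stroma persist toward the limbus; only Bowman's layer
#: terminates, which is the contrast feature co-registration keys on)
EDGE_MARGIN_MM = 0.5


@dataclass
class BScan:
    """A rendered (or loaded) grayscale B-scan.

    ``intensity`` has rows = axial (optical depth in air), columns =
    lateral, with columns ordered inferior -> superior.  ``rotation_rad``
    records the eye rotation used during (synthetic) acquisition; it is
    metadata of the fixture, not an input to the analysis pipeline.
    """

    intensity: np.ndarray
    region: str
    geometry: ScanGeometry
    rotation_rad: float = 0.0
    truth_rows: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.intensity)
        if a.ndim != 2 or a.shape[0] < 3 or a.shape[1] < 3:
            raise ValueError("BScan intensity must be at least 3x3")
        if not np.all(np.isfinite(np.asarray(a, dtype=float))):
            raise ValueError("BScan intensity must be finite")


def region_rotation_rad(gt: GroundTruthCornea, region: str, geometry: ScanGeometry) -> float:
    """Eye rotation placing the region's analysis window at the scan pole.

    The peripheral rotation maps the Bowman's edge to half a window from
    the pole (~29-30 degrees with default geometry), mirroring the
    acquisition protocol's peripheral fixation targets.
    """
    if region == "central":
        return 0.0
    R = gt.anterior_radius_mm
    half_window = 500 * geometry.lateral_pitch_mm
    theta_edge = math.asin(gt.semichord_mm / R)
    rot = theta_edge - math.asin(half_window / R)
    return -rot if region == "inferior" else rot


def render_bscan(
    gt: GroundTruthCornea,
    region: str,
    geometry: ScanGeometry = DEFAULT_GEOMETRY,
    seed: int = 0,
    noise_sd: float | None = None,
    with_truth: bool = False,
) -> BScan:
    """Render the regional B-scan of a ground-truth cornea.

    Each column is traced as one A-scan: the vertical ray meets the
    anterior arc, refracts by Snell's law (n = geometry.refractive_index),
    and each deeper interface echo is placed at its cumulative *optical*
    path length.  Intensities are piecewise-constant per tissue class with
    additive Gaussian noise of SD ``noise_sd`` (default: the generator's),
    quantized to 8 bits; transitions fall at the rounded boundary rows.

    With ``with_truth=True`` the float ground-truth boundary rows are kept
    on the returned scan (fixture metadata for validation).
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    R = gt.anterior_radius_mm
    if gt.semichord_mm >= R:
        raise ValueError("cornea semichord exceeds anterior radius; geometry/gt mismatch")
    if 500 * geometry.lateral_pitch_mm >= R:
        raise ValueError("scan window wider than anterior arc; geometry/gt mismatch")
    if noise_sd is None:
        noise_sd = gt.noise_sd
    n_idx = geometry.refractive_index
    H, W = geometry.axial_pixels, geometry.lateral_pixels
    pitch_ax = geometry.axial_pitch_air_mm

    rot = region_rotation_rad(gt, region, geometry)
    u = geometry.column_to_chord_mm(np.arange(W))  # frame chord, inf -> sup
    theta_f = np.arcsin(np.clip(u / R, -1.0, 1.0))  # frame polar angle
    theta_g = theta_f + rot  # global polar angle
    theta_edge = math.asin(gt.semichord_mm / R)
    sc = gt.semichord_mm
    extent = min(sc + EDGE_MARGIN_MM, 0.999 * R)
    tissue = np.abs(theta_g) <= math.asin(extent / R)

    def depth_um(x, iface):
        """Interface depth; Bowman's layer vanishes beyond its edge, the
        other layers freeze at their edge values toward the limbus."""
        xc = np.clip(x, -sc, sc)
        d = np.zeros_like(xc)
        if iface >= 1:
            d = d + gt.layer_thickness(xc, "epithelium")
        if iface >= 2:
            d = d + gt.layer_thickness(xc, "bowman") * (np.abs(x) <= sc)
        if iface >= 3:
            d = d + gt.layer_thickness(xc, "stroma")
        return d

    # anterior surface in the frame (z down, geometric == optical in air)
    cz = APEX_CLEARANCE_MM + R  # arc centre depth
    z_surf = cz - R * np.cos(theta_f)

    # refract the vertical ray at the surface
    cos_i = np.cos(theta_f)
    sin_t_sq = (1.0 - cos_i**2) / n_idx**2
    cos_t = np.sqrt(1.0 - sin_t_sq)
    # inward normal (towards arc centre): (-sin(theta_f), cos(theta_f))
    k = cos_t - cos_i / n_idx
    dir_x = -k * np.sin(theta_f)
    dir_z = 1.0 / n_idx + k * cos_i
    # chord position of the entry point on the global axis
    x_entry = R * np.sin(theta_g)

    rows = [z_surf / pitch_ax]
    s_mm = None
    for iface in (1, 2, 3):
        depth_um_entry = depth_um(x_entry, iface)
        s = depth_um_entry / 1000.0 / np.maximum(cos_t, 0.3) if s_mm is None else s_mm.copy()
        # Newton iteration on the path length s along the refracted ray:
        # f(s) = |X(s) - C| - (R - D_iface(chord of X))
        for _ in range(12):
            Xx = u + s * dir_x
            Xz = z_surf + s * dir_z
            rx = Xx - 0.0
            rz = Xz - cz
            rho = np.sqrt(rx**2 + rz**2)
            phi_f = np.arctan2(rx, -rz)
            x_pt = R * np.sin(np.clip(phi_f + rot, -math.pi / 2, math.pi / 2))
            d_um = depth_um(x_pt, iface)
            f = rho - (R - d_um / 1000.0)
            fp = (dir_x * rx + dir_z * rz) / np.maximum(rho, 1e-9)
            fp = np.where(np.abs(fp) < 0.2, np.sign(fp) * 0.2 + (fp == 0) * 0.2, fp)
            s = s - f / fp
        s = np.maximum(s, 0.0)
        s_mm = s
        rows.append((z_surf + n_idx * s) / pitch_ax)

    rows_px = [np.where(tissue, r, np.nan) for r in rows]

    img = np.full((H, W), TISSUE_INTENSITY["background"], dtype=float)
    rr = [np.where(np.isfinite(r), np.round(r), -1).astype(int) for r in rows_px]
    grid = np.arange(H)[:, None]
    in_tissue = tissue[None, :]
    img = np.where(in_tissue & (grid >= rr[0]) & (grid < rr[1]), TISSUE_INTENSITY["epithelium"], img)
    img = np.where(in_tissue & (grid >= rr[1]) & (grid < rr[2]), TISSUE_INTENSITY["bowman"], img)
    img = np.where(in_tissue & (grid >= rr[2]) & (grid < rr[3]), TISSUE_INTENSITY["stroma"], img)

    if noise_sd > 0:
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(seed)
        white = rng.normal(size=img.shape)
        field = gaussian_filter(white, NOISE_CORRELATION_PX)
        field /= field.std()
        # equal-power split between speckle-like correlated structure and
        # uncorrelated detector noise
        mix = (field + rng.normal(size=img.shape)) / math.sqrt(2.0)
        img = img + noise_sd * mix
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    truth = None
    if with_truth:
        names = ("air_epithelium", "epithelium_bowman", "bowman_stroma", "stroma_posterior")
        truth = {name: rows_px[i] for i, name in enumerate(names)}
        truth["chord_mm"] = np.where(tissue, x_entry, np.nan)
    return BScan(intensity=img, region=region, geometry=geometry, rotation_rad=rot, truth_rows=truth)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class SyntheticEye:
    gt: GroundTruthCornea
    group: str
    subject_id: str
    bscans: dict[str, BScan] | None = None


def generate_cohort(
    design: dict[str, int],
    seed: int,
    params: dict[str, SyntheticCorneaParams] | None = None,
    geometry: ScanGeometry = DEFAULT_GEOMETRY,
    render: bool = True,
    with_truth: bool = False,
) -> list[SyntheticEye]:
    """Generate ``design[group]`` eyes per group, reproducibly from ``seed``.

    ``design`` maps group labels (any of normal / subclinical_kc / kc,
    possibly with suffixes like ``normal_I`` that reuse the base group's
    parameters) to counts.  With ``render=True`` each eye carries its three
    regional B-scans.
    """
    if not design:
        raise ValueError("empty cohort design")
    for label, n in design.items():
        if n < 1:
            raise ValueError(f"group {label!r} must have n >= 1")
    eyes: list[SyntheticEye] = []
    ss = np.random.SeedSequence(seed)
    for label, n in design.items():
        base = label
        for g in GROUPS:  # normal_I / normal_II reuse the normal parameters
            if label == g or label.startswith(g + "_"):
                base = g
        if base not in GROUPS:
            raise ValueError(f"cannot map cohort label {label!r} onto a study group")
        p = params[label] if params and label in params else default_group_params(base, geometry)
        for i in range(n):
            child = ss.spawn(1)[0]
            eye_seed = int(child.generate_state(1)[0] % (2**31))
            sid = f"{label}-{i:03d}"
            gt = sample_cornea_geometry(p, eye_seed, subject_id=sid, geometry=geometry)
            scans = None
            if render:
                scans = {
                    region: render_bscan(
                        gt, region, geometry, seed=eye_seed + j, with_truth=with_truth
                    )
                    for j, region in enumerate(REGIONS)
                }
            eyes.append(SyntheticEye(gt=gt, group=label, subject_id=sid, bscans=scans))
    return eyes


# ---------------------------------------------------------------------------
# ideal sampling of ground truth onto the registered profile axis
# ---------------------------------------------------------------------------


def truth_bin_means(
    gt: GroundTruthCornea, layer: str, geometry: ScanGeometry = DEFAULT_GEOMETRY, n_sub: int = 33
) -> np.ndarray:
    """Ground-truth mean thickness (um) of each of the 26 registered bins."""
    w = geometry.zone_chord_mm
    edges = np.arange(-N_HALF_BINS, N_HALF_BINS + 1) * w
    offs = (np.arange(n_sub) + 0.5) / n_sub
    samples = edges[:-1, None] + offs[None, :] * w
    return gt.layer_thickness(samples.ravel(), layer).reshape(N_BINS, n_sub).mean(axis=1)
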