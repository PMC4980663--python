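"""Refraction correction and perpendicular layer thickness.

A raw B-scan places every echo at its optical path length along the
A-scan column, so sub-surface boundaries are axially stretched by the
tissue index and laterally displaced by refraction at the anterior
surface.  `refraction_correct` undoes this by Snell ray tracing: the
incidence angle at each A-scan comes from the local tangent of the
anterior surface, the transmitted direction from Snell's law (n1 = 1 air,
n2 = the geometry's refractive index, 1.389 by default), and the optical
path below the surface is divided by the index and laid along the
refracted ray.  Refraction is applied at the anterior surface only, with
one index for all corneal layers.

`perpendicular_thickness` then measures each layer as the distance from
its upper interface to its lower interface along the local normal of the
anterior surface, in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ScanGeometry
from .segmentation import INTERFACES, BoundarySet

#: half-width (A-scans) of the smoothing window for the anterior tangent
TANGENT_HALFWIDTH = 25

LAYER_BOUNDS = {
    "epithelium": ("air_epithelium", "epithelium_bowman"),
    "bowman": ("epithelium_bowman", "bowman_stroma"),
    "stroma": ("bowman_stroma", "stroma_posterior"),
}


@dataclass
class CorrectedBoundarySet:
    """Per-interface geometric (refraction-corrected) coordinates.

    ``x_mm[i], z_mm[i]`` give the lateral / axial position of interface
    ``i`` at each A-scan, in mm, z increasing with depth.
    """

    x_mm: dict[str, np.ndarray]
    z_mm: dict[str, np.ndarray]
    valid: dict[str, np.ndarray]
    geometry: ScanGeometry
    region: str | None = None


@dataclass
class AScanThicknessProfile:
    """Per-A-scan thickness (um) of one layer along the scan."""

    layer: str
    thickness_um: np.ndarray
    valid: np.ndarray
    lateral_mm: np.ndarray
    region: str | None = None


def _smoothed(z: np.ndarray, valid: np.ndarray, halfwidth: int = TANGENT_HALFWIDTH) -> np.ndarray:
    """Moving-average smoothing over +/-halfwidth A-scans, gap-filled."""
    x = np.arange(z.size)
    zz = np.interp(x, x[valid], z[valid]) if valid.any() and not valid.all() else z.copy()
    k = 2 * halfwidth + 1
    kern = np.ones(k) / k
    pad = np.pad(zz, halfwidth, mode="edge")
    return np.convolve(pad, kern, mode="valid")


def anterior_slope(corrected_or_z, valid=None, geometry: ScanGeometry | None = None):
    """dz/dx of the (smoothed) anterior surface per A-scan."""
    if isinstance(corrected_or_z, CorrectedBoundarySet):
        c = corrected_or_z
        z = c.z_mm["air_epithelium"]
        valid = c.valid["air_epithelium"]
        return np.gradient(_smoothed(z, valid), c.x_mm["air_epithelium"])
    z = np.asarray(corrected_or_z, dtype=float)
    if valid is None:
        valid = np.ones(z.size, dtype=bool)
    return np.gradient(_smoothed(z, valid), geometry.lateral_pitch_mm)


def refraction_correct(boundaries: BoundarySet, geometry: ScanGeometry) -> CorrectedBoundarySet:
    """Snell ray tracing of all four interface traces into geometric space.

    With ``refractive_index == 1`` this is the identity on coordinates
    (only pixel -> mm unit conversion happens).
    """
    surf = boundaries.air_epithelium
    if not surf.valid.any():
        raise ValueError("anterior surface trace has no valid columns")
    W = surf.rows.size
    pitch_ax = geometry.axial_pitch_air_mm
    n2 = geometry.refractive_index
    u = geometry.column_to_chord_mm(np.arange(W))
    z0 = surf.rows * pitch_ax  # air path: optical == geometric

    m = anterior_slope(z0, surf.valid, geometry)  # dz/dx
    norm = np.sqrt(1.0 + m**2)
    # inward surface normal (z down): (-m, 1)/norm ; incident ray (0, 1)
    cos_i = 1.0 / norm
    sin_i2 = 1.0 - cos_i**2
    sin_t2 = sin_i2 / n2**2
    if np.any(sin_t2[surf.valid] >= 1.0):
        raise ValueError("total internal reflection encountered: malformed surface normals")
    cos_t = np.sqrt(1.0 - sin_t2)
    k = cos_t - cos_i / n2
    dir_x = -k * m / norm
    dir_z = 1.0 / n2 + k / norm

    x_mm = {"air_epithelium": u.copy()}
    z_mm = {"air_epithelium": z0.copy()}
    valid = {"air_epithelium": surf.valid.copy()}
    for name in INTERFACES[1:]:
        tr = boundaries.trace(name)
        d_opt = (tr.rows - surf.rows) * pitch_ax  # optical path below surface
        s = d_opt / n2  # geometric path along the refracted ray
        x_mm[name] = u + s * dir_x
        z_mm[name] = z0 + s * dir_z
        valid[name] = tr.valid & surf.valid & (d_opt >= 0)
    return CorrectedBoundarySet(
        x_mm=x_mm, z_mm=z_mm, valid=valid, geometry=geometry, region=boundaries.region
    )


def perpendicular_thickness(
    corrected: CorrectedBoundarySet, layer: str, normal_slope: np.ndarray | None = None
) -> AScanThicknessProfile:
    """Layer thickness per A-scan, measured along the anterior normal.

    At each A-scan the ray from the layer's upper interface point along
    the local anterior normal is intersected with the (interpolated) lower
    interface trace; columns whose normal never meets the lower trace
    inside the scan are marked invalid.
    """
    if layer not in LAYER_BOUNDS:
        raise ValueError(f"unknown layer {layer!r}")
    up_name, lo_name = LAYER_BOUNDS[layer]
    xu = corrected.x_mm[up_name]
    zu = corrected.z_mm[up_name]
    vu = corrected.valid[up_name]
    xl = corrected.x_mm[lo_name]
    zl = corrected.z_mm[lo_name]
    vl = corrected.valid[lo_name]
    if not (vu.any() and vl.any()):
        raise ValueError(f"{layer}: bounding interface traces have no valid columns")

    m = anterior_slope(corrected) if normal_slope is None else normal_slope
    norm = np.sqrt(1.0 + m**2)
    nx, nz = -m / norm, 1.0 / norm

    # lower trace as a function z_l(x) over its valid support
    order = np.argsort(xl[vl])
    xs = xl[vl][order]
    zs = zl[vl][order]

    t = np.maximum(np.interp(xu, xs, zs) - zu, 0.0) / np.maximum(nz, 1e-6)
    for _ in range(8):  # fixed point: move along the normal, re-look-up z_l
        xq = xu + t * nx
        t = (np.interp(xq, xs, zs) - zu) / np.maximum(nz, 1e-6)
    xq = xu + t * nx
    inside = (xq >= xs[0]) & (xq <= xs[-1])
    valid = vu & inside & (t > 0)
    return AScanThicknessProfile(
        layer=layer,
        thickness_um=t * 1000.0,
        valid=valid,
        lateral_mm=xu.copy(),
        region=corrected.region,
    )


def find_apex_column(corrected: CorrectedBoundarySet) -> int:
    """A-scan of maximal anterior-surface elevation (minimal depth) in the
    corrected image, on the smoothed surface."""
    z = corrected.z_mm["air_epithelium"]
    v = corrected.valid["air_epithelium"]
    zz = _smoothed(z, v)
    zz = np.where(v, zz, np.inf)
    return int(np.argmin(zz))
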