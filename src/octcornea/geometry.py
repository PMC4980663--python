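"""Physical calibration of a UHR-OCT corneal B-scan.

A B-scan is a lateral sequence of A-scans (columns); the axial axis (rows)
measures optical path length in air.  The default instrument geometry is
1,365 x 2,048 pixels covering 2.02 mm of depth and 8.66 mm of width in air,
with a corneal group refractive index of 1.389 used to convert optical to
geometric depth inside tissue.

Zone arithmetic is anchored here because every downstream stage uses it:
an analysis window is 1,000 A-scans (a 4.23-mm chord with the default
lateral sampling) divided into 10 zones of 100 A-scans (0.42 mm) each.
"""

from __future__ import annotations

from dataclasses import dataclass

WINDOW_ASCANS = 1000
ZONE_ASCANS = 100
N_ZONES = WINDOW_ASCANS // ZONE_ASCANS


@dataclass(frozen=True)
class ScanGeometry:
    """Pixel counts, physical extents (in air) and refractive index of a scan.

    Parameters
    ----------
    axial_pixels, lateral_pixels:
        Image dimensions (rows, columns).
    axial_extent_air_mm:
        Scan depth in air covered by ``axial_pixels`` rows.
    lateral_extent_mm:
        Scan width covered by ``lateral_pixels`` columns.
    refractive_index:
        Corneal group index used for optical -> geometric depth conversion.
    """

    axial_pixels: int = 1365
    lateral_pixels: int = 2048
    axial_extent_air_mm: float = 2.02
    lateral_extent_mm: float = 8.66
    refractive_index: float = 1.389

    def __post_init__(self) -> None:
        for name in (
            "axial_pixels",
            "lateral_pixels",
            "axial_extent_air_mm",
            "lateral_extent_mm",
            "refractive_index",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScanGeometry.{name} must be positive")

    # -- pixel pitches ----------------------------------------------------
    @property
    def lateral_pitch_mm(self) -> float:
        """Chord distance between neighbouring A-scans."""
        return self.lateral_extent_mm / self.lateral_pixels

    @property
    def axial_pitch_air_mm(self) -> float:
        """Axial pixel pitch in air (optical units)."""
        return self.axial_extent_air_mm / self.axial_pixels

    @property
    def axial_pitch_air_um(self) -> float:
        return self.axial_pitch_air_mm * 1000.0

    @property
    def axial_pitch_tissue_um(self) -> float:
        """Geometric depth per axial pixel inside tissue."""
        return self.axial_pitch_air_um / self.refractive_index

    # -- zone arithmetic --------------------------------------------------
    @property
    def window_chord_mm(self) -> float:
        """Chord spanned by one 1,000-A-scan analysis window."""
        return WINDOW_ASCANS * self.lateral_pitch_mm

    @property
    def zone_chord_mm(self) -> float:
        """Chord spanned by one 100-A-scan zone (= profile bin width)."""
        return ZONE_ASCANS * self.lateral_pitch_mm

    def zone_outer_boundary_mm(self, zone: int) -> int | float:
        """Chord distance from the window centre to the outer edge of the
        ``zone``-th zone counted outward (zone 1 adjacent to the centre)."""
        if not 1 <= zone <= N_ZONES:
            raise ValueError(f"zone must be in 1..{N_ZONES}, got {zone}")
        return zone * self.zone_chord_mm

    def column_to_chord_mm(self, column) -> float:
        """Lateral position (mm) of a column, centred on the image middle."""
        return (column - (self.lateral_pixels - 1) / 2.0) * self.lateral_pitch_mm

    def um_to_axial_px(self, geometric_um: float) -> float:
        """Axial pixels (optical) corresponding to a geometric tissue depth."""
        return geometric_um * self.refractive_index / self.axial_pitch_air_um


DEFAULT_GEOMETRY = ScanGeometry()
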