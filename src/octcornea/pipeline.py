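"""End-to-end orchestration: B-scans -> profiles -> indices -> cohort table.

Thin glue over the stage modules, so drivers (CLI, analysis scripts,
acceptance checks) all run the identical pipeline:

scan -> segment_cornea -> refraction_correct -> perpendicular_thickness
     -> zonal_average (per region) -> register_vertical_profile
     -> compute_index_set -> cohort table -> statistics.

Two cohort paths exist: ``profiles_from_scans`` runs the full image
pipeline; ``profiles_from_truth`` samples the generator's ground truth
directly onto the registered axis (no rendering), which isolates the
statistical machinery from segmentation error and runs in milliseconds
per eye.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import ScanGeometry
from .indices import build_normal_pattern, compute_index_set
from .optics import find_apex_column, perpendicular_thickness, refraction_correct
from .profiles import (
    VerticalProfile,
    detect_bowman_edges,
    register_vertical_profile,
    zonal_average,
    zonal_profiles_from_truth,
)
from .segmentation import SegmentationConfig, segment_cornea
from .synthetic import LAYERS, REGIONS, SyntheticEye, default_semichord_mm


def profiles_from_scans(
    bscans: dict,
    seg_config: SegmentationConfig | None = None,
    bowman_semichord_mm: float | None = None,
    seeds: dict | None = None,
) -> dict[str, VerticalProfile]:
    """Entire vertical profile per layer from one eye's three B-scans."""
    for region in REGIONS:
        if region not in bscans:
            raise ValueError(f"missing {region} B-scan")
    geometry: ScanGeometry = bscans["central"].geometry
    semichord = bowman_semichord_mm or default_semichord_mm(geometry)
    zonal: dict[str, dict[str, object]] = {layer: {} for layer in LAYERS}
    for region in REGIONS:
        scan = bscans[region]
        bset = segment_cornea(scan, seg_config, seeds=(seeds or {}).get(region))
        corrected = refraction_correct(bset, geometry)
        edges = detect_bowman_edges(bset)
        apex = find_apex_column(corrected) if region == "central" else None
        for layer in LAYERS:
            prof = perpendicular_thickness(corrected, layer)
            zonal[layer][region] = zonal_average(
                prof,
                region,
                edges=edges,
                apex_col=apex,
                geometry=geometry,
                bowman_semichord_mm=semichord,
            )
    return {
        layer: register_vertical_profile(
            zonal[layer]["inferior"], zonal[layer]["central"], zonal[layer]["superior"]
        )
        for layer in LAYERS
    }


def profiles_from_truth(eye: SyntheticEye, geometry: ScanGeometry) -> dict[str, VerticalProfile]:
    """Ideal-sampling profiles of one synthetic eye (no image stage)."""
    out = {}
    for layer in LAYERS:
        zp = zonal_profiles_from_truth(eye.gt, layer, geometry)
        out[layer] = register_vertical_profile(zp["inferior"], zp["central"], zp["superior"])
    return out


def cohort_table(
    eyes: list[SyntheticEye],
    geometry: ScanGeometry,
    reference_labels: tuple[str, ...] | None = None,
    use_images: bool = False,
    seg_config: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Per-eye table of the 12 indices over a cohort.

    The normal-pattern references are built from the eyes whose cohort
    label is in ``reference_labels`` (default: every label starting with
    ``"normal"``); PSD indices of those reference eyes are scored against
    the same pattern.
    """
    profs = []
    for eye in eyes:
        if use_images:
            p = profiles_from_scans(eye.bscans, seg_config, eye.gt.semichord_mm)
        else:
            p = profiles_from_truth(eye, geometry)
        profs.append(p)
    if reference_labels is None:
        reference_labels = tuple({e.group for e in eyes if e.group.startswith("normal")})
    ref = [i for i, e in enumerate(eyes) if e.group in reference_labels]
    if not ref:
        raise ValueError("no reference (normal) eyes to build the pattern from")
    patterns = {
        layer: build_normal_pattern([profs[i][layer] for i in ref]) for layer in LAYERS
    }
    rows = []
    for eye, p in zip(eyes, profs):
        iset = compute_index_set(
            p["epithelium"], p["bowman"], p["stroma"], patterns, subject_id=eye.subject_id
        )
        row = iset.as_row()
        row["group"] = eye.group
        rows.append(row)
    df = pd.DataFrame(rows)
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicated subject ids in cohort")
    return df
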