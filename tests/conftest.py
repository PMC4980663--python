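"""Shared fixtures: deterministic synthetic eyes and cohorts.

Everything is generated at test time from seeds; the expensive rendered
cohort is session-scoped so the image-pipeline tests share one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from octcornea.geometry import DEFAULT_GEOMETRY
from octcornea.pipeline import cohort_table, profiles_from_scans
from octcornea.synthetic import (
    REGIONS,
    default_group_params,
    generate_cohort,
    render_bscan,
    sample_cornea_geometry,
)


def noise_free_params(group: str = "normal"):
    p = default_group_params(group)
    p.between_eye_sd_um = {l: 0.0 for l in p.between_eye_sd_um}
    p.zonal_noise_sd_um = {l: 0.0 for l in p.zonal_noise_sd_um}
    p.noise_sd = 0.0
    return p


@pytest.fixture(scope="session")
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def noiseless_eye():
    """One deterministic normal eye with noise-free rendered scans + truth."""
    gt = sample_cornea_geometry(noise_free_params(), seed=3)
    scans = {
        r: render_bscan(gt, r, DEFAULT_GEOMETRY, seed=0, noise_sd=0.0, with_truth=True)
        for r in REGIONS
    }
    return gt, scans


@pytest.fixture(scope="session")
def noiseless_kc_eye():
    """A manifest-KC eye (deep inferior-central cone), noise-free."""
    p = noise_free_params("kc")
    p.cone_center_mm = -1.2
    gt = sample_cornea_geometry(p, seed=5)
    scans = {
        r: render_bscan(gt, r, DEFAULT_GEOMETRY, seed=0, noise_sd=0.0, with_truth=True)
        for r in REGIONS
    }
    return gt, scans


@pytest.fixture(scope="session")
def rendered_cohort():
    """15 noise-free rendered eyes (5 per group, subject variation kept)
    pushed through the full image pipeline."""
    params = {}
    for g in ("normal", "subclinical_kc", "kc"):
        p = default_group_params(g)
        p.noise_sd = 0.0
        params[g] = p
    eyes = generate_cohort(
        {"normal": 5, "subclinical_kc": 5, "kc": 5},
        seed=42,
        params=params,
        render=True,
        with_truth=True,
    )
    profiles = [
        profiles_from_scans(e.bscans, bowman_semichord_mm=e.gt.semichord_mm) for e in eyes
    ]
    return eyes, profiles


@pytest.fixture(scope="session")
def truth_cohort_table():
    """80-eye ideal-sampling cohort table (normal I/II, sub-clinical, KC)."""
    eyes = generate_cohort(
        {"normal_I": 20, "normal_II": 20, "subclinical_kc": 20, "kc": 20},
        seed=11,
        render=False,
    )
    df = cohort_table(eyes, DEFAULT_GEOMETRY, reference_labels=("normal_I",))
    return df
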