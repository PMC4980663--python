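# octcornea

Corneal sub-layer thickness profiling from UHR-OCT B-scans, built for
one scientific question: can thickness indices derived from *entire
vertical profiles* of the corneal epithelium and Bowman's layer detect
**sub-clinical keratoconus** — the topographically normal fellow eye of
a unilateral keratoconus patient — before the disease is visible to
standard examination?

The package implements the full measurement-and-statistics chain, plus a
synthetic-cornea generator so every stage is testable without patient
data:

1. **Segmentation** (`octcornea.segmentation`) — the four corneal
   interfaces (air–epithelium, epithelium–Bowman, Bowman–stroma,
   stroma–posterior) extracted as exact minimal-cost paths through a
   vertical-gradient cost grid (column-wise dynamic programming with a
   bounded vertical step), with spline initialisation from sparse seed
   points and a manual-correction hook for the low-contrast
   Bowman–stroma interface.
2. **Refraction correction** (`octcornea.optics`) — Snell ray tracing at
   the anterior surface (n = 1.389): optical depths divided by the index
   and laid along the refracted ray; thickness measured perpendicular to
   the anterior surface.
3. **Profile reconstruction** (`octcornea.profiles`) — per region, a
   1,000-A-scan window (4.23-mm chord) averaged into ten 0.42-mm zones;
   the central, superior and inferior regions co-registered at the
   Bowman's-layer edges into one ~11-mm entire vertical profile per
   layer.
4. **Diagnostic indices** (`octcornea.indices`) — for each layer
   L ∈ {E, B, S}:

   * ectasia index `LEI = 100·min(inferior half)/mean(superior half)` (%)
   * maximum ectasia index `LEI-MAX = 100·min(inf)/max(sup)` (%)
   * profile variation `LPV = RMS(zones − profile mean)` (µm)
   * pattern SD `LPSD = RMS(zones − normal pattern)` (µm)

   Low EI/EI-MAX flag localized inferior thinning; high PV/PSD flag
   profile irregularity and deviation from the normal cohort pattern.
5. **Statistics** (`octcornea.stats`) — three-group ANOVA, forward
   Wilks'-λ stepwise discriminant analysis (F-to-enter 3.84),
   discriminant scoring oriented so diseased eyes score higher, and
   empirical ROC/AUC with Youden cutoffs.

`octcornea.synthetic` generates ground-truth corneas with the group-wise
zonal thickness structure of the normal / sub-clinical / keratoconus
populations (localized central-to-inferior Gaussian cone thinning) and
renders physically consistent regional B-scans through the refracting
anterior surface, so segmentation and correction can be validated
against known truth.

## Worked example

```python
import numpy as np
from octcornea import (
    DEFAULT_GEOMETRY, default_group_params, sample_cornea_geometry,
    render_bscan, segment_cornea, refraction_correct,
    perpendicular_thickness,
)

params = default_group_params("kc")
params.noise_sd = 0.0
eye = sample_cornea_geometry(params, seed=5)

scan = render_bscan(eye, "central", DEFAULT_GEOMETRY, seed=0, with_truth=True)
bset = segment_cornea(scan)
corr = refraction_correct(bset, DEFAULT_GEOMETRY)
epi = perpendicular_thickness(corr, "epithelium")

mid = slice(524, 1524)
print(f"central-window epithelium: {np.nanmean(epi.thickness_um[mid]):.2f} um")
truth = eye.layer_thickness(scan.truth_rows["chord_mm"][mid], "epithelium")
err = epi.thickness_um[mid] - truth
print(f"recovery error vs ground truth: RMSE {np.sqrt(np.nanmean(err**2)):.2f} um")
```

prints

```
central-window epithelium: 34.00 um
recovery error vs ground truth: RMSE 0.28 um
```

— a keratoconic eye whose central epithelium (the ~46-µm KC group
baseline with this eye's subject offset and a localized cone thinning of
12 µm inside the window) is recovered from the rendered raw scan to
about a quarter micron.

The numbered drivers under `analysis/` run the whole study on a
rendered four-arm cohort (normal I/II, sub-clinical KC, KC; 12 eyes per
arm): `01_simulate_cohort.py` → `02_segment_profiles.py` →
`03_indices.py` → `04_group_stats.py`, writing tables under `results/`
(images and intermediate profiles go to `scratch/`).  An equivalent
`octcornea` command-line interface (`simulate`, `segment`, `profile`,
`pattern`, `indices`, `stats`, `roc`, `report`) composes the same
pipeline on files.

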