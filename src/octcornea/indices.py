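"""The twelve diagnostic thickness indices.

For each layer (E = epithelium, B = Bowman's layer, S = stroma) four
quantities are computed from the entire vertical thickness profile:

* ectasia index        ``EI  = 100 * min(inferior half) / mean(superior half)``
* maximum ectasia index ``EI_MAX = 100 * min(inferior half) / max(superior half)``
* profile variation    ``PV  = RMS of zonal thicknesses about the profile mean`` (um)
* pattern SD           ``PSD = RMS of zonal thicknesses about a normal-cohort
  pattern average`` (um)

Halves are taken on the registered entire profile, split at the apex bin
with the apex bin excluded.  Low EI / EI_MAX flag localized inferior
thinning; high PV flags profile irregularity; high PSD flags deviation
from the normal pattern.  EI_MAX <= EI always (mean <= max).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import VerticalProfile

LAYER_PREFIX = {"epithelium": "E", "bowman": "B", "stroma": "S"}

INDEX_NAMES = (
    "EEI", "EEI_MAX", "EPV", "EPSD",
    "BEI", "BEI_MAX", "BPV", "BPSD",
    "SEI", "SEI_MAX", "SPV", "SPSD",
)

PERCENT_INDICES = ("EEI", "EEI_MAX", "BEI", "BEI_MAX", "SEI", "SEI_MAX")


@dataclass
class NormalPattern:
    """Per-bin mean thickness of a reference (normal) cohort for one layer."""

    layer: str
    bin_index: np.ndarray
    mean_um: np.ndarray
    n_subjects: int
    bin_width_mm: float


@dataclass
class IndexSet:
    """The 12 indices of one eye; unset entries are None and flagged."""

    subject_id: str
    values: dict[str, float | None]
    excluded_bins: dict[str, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __getitem__(self, name: str) -> float | None:
        return self.values[name]

    def as_row(self) -> dict:
        row = {"subject_id": self.subject_id}
        row.update(self.values)
        row["flags"] = ";".join(self.flags)
        return row


def build_normal_pattern(profiles: list[VerticalProfile]) -> NormalPattern:
    """Per-bin arithmetic mean across a reference cohort; bins missing in
    some subjects are averaged over the subjects that have them."""
    if not profiles:
        raise ValueError("empty reference cohort")
    layer = profiles[0].layer
    w = profiles[0].bin_width_mm
    for p in profiles:
        if p.layer != layer:
            raise ValueError("mixed layers in reference cohort")
        if abs(p.bin_width_mm - w) > 1e-12:
            raise ValueError("mismatched bin axes in reference cohort")
    b_min = min(int(p.bin_index.min()) for p in profiles)
    b_max = max(int(p.bin_index.max()) for p in profiles)
    n = b_max - b_min + 1
    total = np.zeros(n)
    count = np.zeros(n, dtype=int)
    for p in profiles:
        ok = p.valid
        i = p.bin_index[ok] - b_min
        total[i] += p.thickness_um[ok]
        count[i] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    keep = count > 0
    return NormalPattern(
        layer=layer,
        bin_index=np.arange(b_min, b_max + 1)[keep],
        mean_um=mean[keep],
        n_subjects=len(profiles),
        bin_width_mm=w,
    )


def _halves(profile: VerticalProfile):
    ok = profile.valid
    inf = ok & (profile.bin_index < profile.apex_bin)
    sup = ok & (profile.bin_index > profile.apex_bin)
    return profile.thickness_um[inf], profile.thickness_um[sup]


def ectasia_indices(profile: VerticalProfile) -> tuple[float, float]:
    """(EI, EI_MAX) in percent for one layer profile."""
    inf, sup = _halves(profile)
    if inf.size < 2 or sup.size < 2:
        raise ValueError(
            f"{profile.layer}: need >= 2 valid bins on each side of the apex "
            f"(got {inf.size} inferior, {sup.size} superior)"
        )
    ei = 100.0 * inf.min() / sup.mean()
    ei_max = 100.0 * inf.min() / sup.max()
    return float(ei), float(ei_max)


def profile_variation(profile: VerticalProfile) -> float:
    """PV: RMS of the valid bins about the profile's own mean (um)."""
    t = profile.thickness_um[profile.valid]
    if t.size < 2:
        raise ValueError(f"{profile.layer}: need >= 2 valid bins for PV")
    return float(np.sqrt(np.mean((t - t.mean()) ** 2)))


def pattern_sd(profile: VerticalProfile, pattern: NormalPattern) -> float:
    """PSD: RMS difference from the normal pattern over shared valid bins (um)."""
    if abs(profile.bin_width_mm - pattern.bin_width_mm) > 1e-12:
        raise ValueError("profile and pattern bin axes do not match")
    pat = dict(zip(pattern.bin_index.tolist(), pattern.mean_um.tolist()))
    ok = profile.valid
    diffs = [
        profile.thickness_um[i] - pat[int(b)]
        for i, b in enumerate(profile.bin_index)
        if ok[i] and int(b) in pat and np.isfinite(pat[int(b)])
    ]
    if not diffs:
        raise ValueError(f"{profile.layer}: no shared valid bins with the pattern")
    d = np.asarray(diffs)
    return float(np.sqrt(np.mean(d**2)))


def compute_index_set(
    epithelium: VerticalProfile,
    bowman: VerticalProfile,
    stroma: VerticalProfile,
    patterns: dict[str, NormalPattern] | None = None,
    subject_id: str = "",
) -> IndexSet:
    """All twelve indices of one eye; a missing layer pattern leaves that
    PSD unset and flagged, the other indices are still computed."""
    patterns = patterns or {}
    values: dict[str, float | None] = {}
    excluded: dict[str, int] = {}
    flags: list[str] = []
    for layer, vp in (("epithelium", epithelium), ("bowman", bowman), ("stroma", stroma)):
        pre = LAYER_PREFIX[layer]
        if vp.layer != layer:
            raise ValueError(f"profile in {layer} slot is labelled {vp.layer!r}")
        excluded[layer] = int((~vp.valid).sum())
        try:
            ei, ei_max = ectasia_indices(vp)
            pv = profile_variation(vp)
        except ValueError as err:
            raise ValueError(f"{layer}: {err}") from err
        values[f"{pre}EI"] = ei
        values[f"{pre}EI_MAX"] = ei_max
        values[f"{pre}PV"] = pv
        if layer in patterns:
            values[f"{pre}PSD"] = pattern_sd(vp, patterns[layer])
        else:
            values[f"{pre}PSD"] = None
            flags.append(f"{pre}PSD_unset_no_pattern")
    return IndexSet(subject_id=subject_id, values=values, excluded_bins=excluded, flags=flags)
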