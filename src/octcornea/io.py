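"""File formats and pipeline configuration.

Conventions: tables are comma-separated UTF-8 CSV with a header row and
'.' decimals; models and seed/correction sets are JSON; images are
single-channel TIFF or PNG; configuration is YAML (or JSON) validated
against the defaults with unknown keys rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import ScanGeometry
from .indices import NormalPattern
from .profiles import VerticalProfile
from .segmentation import INTERFACES, BoundarySet, BoundaryTrace, SegmentationConfig
from .stats import DiscriminantModel, ROCResult


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ProfileConfig:
    bowman_semichord_mm: float | None = None  # None -> 13 zone widths
    edge_gap_tolerance: int = 5
    min_zone_valid_fraction: float = 0.6


@dataclass
class StatsConfig:
    f_enter: float = 3.84
    cutoff_rule: str = "youden"
    control_label: str = "normal_II"
    seed: int = 0


@dataclass
class PipelineConfig:
    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        blocks = {f.name: f for f in dataclasses.fields(cls)}
        for block_name, block_val in d.items():
            if block_name not in blocks:
                raise ValueError(f"unknown config block {block_name!r}")
            obj = getattr(cfg, block_name)
            known = {f.name for f in dataclasses.fields(obj)}
            for key, val in (block_val or {}).items():
                if key not in known:
                    raise ValueError(f"unknown config key {block_name}.{key}")
            merged = {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
            merged.update(block_val or {})
            setattr(cfg, block_name, type(obj)(**merged))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(repr(sorted(self.to_dict().items())).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def _require_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[i]!r} in row {i}, column {col!r}"
            )
        df[col] = coerced
    return df


def write_vertical_profiles(profiles: dict, path, subject_id: str = "") -> None:
    """``{layer: VerticalProfile}`` -> tidy CSV."""
    rows = []
    for layer, vp in profiles.items():
        for i in range(vp.bin_index.size):
            rows.append(
                {
                    "subject_id": subject_id,
                    "layer": layer,
                    "bin_index": int(vp.bin_index[i]),
                    "chord_mm": float(vp.chord_mm[i]),
                    "thickness_um": float(vp.thickness_um[i]),
                    "n_regions": int(vp.n_regions[i]),
                    "bin_width_mm": vp.bin_width_mm,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_vertical_profiles(path) -> dict[str, dict[str, VerticalProfile]]:
    """CSV -> ``{subject_id: {layer: VerticalProfile}}``."""
    df = pd.read_csv(path, dtype={"subject_id": str, "layer": str})
    df = _require_numeric(df, ["bin_index", "thickness_um", "n_regions", "bin_width_mm"], path)
    out: dict[str, dict[str, VerticalProfile]] = {}
    for (sid, layer), sub in df.groupby(["subject_id", "layer"], sort=False):
        sub = sub.sort_values("bin_index")
        out.setdefault(sid, {})[layer] = VerticalProfile(
            layer=layer,
            bin_index=sub["bin_index"].to_numpy(dtype=int),
            thickness_um=sub["thickness_um"].to_numpy(dtype=float),
            n_regions=sub["n_regions"].to_numpy(dtype=int),
            bin_width_mm=float(sub["bin_width_mm"].iloc[0]),
        )
    return out


def write_boundaries(bset: BoundarySet, path) -> None:
    rows = []
    for name in INTERFACES:
        tr = bset.trace(name)
        for col in range(tr.rows.size):
            rows.append(
                {
                    "column": col,
                    "interface": name,
                    "row": float(tr.rows[col]),
                    "valid": int(tr.valid[col]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_boundaries(path, geometry: ScanGeometry | None = None, region=None) -> BoundarySet:
    df = pd.read_csv(path, dtype={"interface": str})
    df = _require_numeric(df, ["column", "row", "valid"], path)
    traces = {}
    for name in INTERFACES:
        sub = df[df["interface"] == name].sort_values("column")
        if sub.empty:
            raise ValueError(f"{path}: missing interface {name!r}")
        traces[name] = BoundaryTrace(
            name, sub["row"].to_numpy(dtype=float), sub["valid"].to_numpy(dtype=bool)
        )
    return BoundarySet(geometry=geometry, region=region, **traces)


def write_pattern(pattern: NormalPattern, path) -> None:
    pd.DataFrame(
        {
            "layer": pattern.layer,
            "bin_index": pattern.bin_index,
            "mean_um": pattern.mean_um,
            "n_subjects": pattern.n_subjects,
            "bin_width_mm": pattern.bin_width_mm,
        }
    ).to_csv(path, index=False)


def read_patterns(path) -> dict[str, NormalPattern]:
    df = pd.read_csv(path, dtype={"layer": str})
    df = _require_numeric(df, ["bin_index", "mean_um", "n_subjects", "bin_width_mm"], path)
    out = {}
    for layer, sub in df.groupby("layer", sort=False):
        sub = sub.sort_values("bin_index")
        out[layer] = NormalPattern(
            layer=layer,
            bin_index=sub["bin_index"].to_numpy(dtype=int),
            mean_um=sub["mean_um"].to_numpy(dtype=float),
            n_subjects=int(sub["n_subjects"].iloc[0]),
            bin_width_mm=float(sub["bin_width_mm"].iloc[0]),
        )
    return out


def write_model(model: DiscriminantModel, path) -> None:
    Path(path).write_text(model.to_json())


def read_model(path) -> DiscriminantModel:
    return DiscriminantModel.from_json(Path(path).read_text())


def write_roc(roc: ROCResult, path) -> None:
    pd.DataFrame(
        {
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def write_image(array: np.ndarray, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.asarray(array, dtype=np.uint8))
    elif path.suffix.lower() == ".png":
        from PIL import Image

        Image.fromarray(np.asarray(array, dtype=np.uint8), mode="L").save(path)
    else:
        raise ValueError(f"unrecognized image format: {path.suffix!r}")


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path))
    if path.suffix.lower() == ".png":
        from PIL import Image

        return np.asarray(Image.open(path))
    raise ValueError(f"unrecognized image format: {path.suffix!r}")
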