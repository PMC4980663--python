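#!/usr/bin/env python
"""Compute the twelve diagnostic thickness indices per eye.

Builds the normal-pattern references (per-bin mean profiles) from normal
group I, scores every eye's entire vertical profiles against them, and
writes results/indices.csv (one row per eye: group + 12 indices) and
results/normal_pattern.csv.  Prints the group means of the key indices.

Run after 02:  python analysis/03_indices.py
"""

from pathlib import Path

import pandas as pd

from octcornea.indices import build_normal_pattern, compute_index_set
from octcornea.io import read_vertical_profiles, write_pattern
from octcornea.synthetic import LAYERS

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    profs = read_vertical_profiles(ROOT / "scratch" / "cohort" / "profiles.csv")
    manifest = pd.read_csv(ROOT / "scratch" / "cohort" / "manifest.csv")
    group_of = dict(manifest[["subject_id", "group"]].drop_duplicates().itertuples(index=False))

    ref_ids = [s for s, g in group_of.items() if g == "normal_I"]
    patterns = {
        layer: build_normal_pattern([profs[s][layer] for s in ref_ids]) for layer in LAYERS
    }
    for layer, pat in patterns.items():
        write_pattern(pat, ROOT / "results" / f"normal_pattern_{layer}.csv")

    rows = []
    for sid, layers in profs.items():
        iset = compute_index_set(
            layers["epithelium"], layers["bowman"], layers["stroma"], patterns, subject_id=sid
        )
        row = iset.as_row()
        row["group"] = group_of[sid]
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "results" / "indices.csv", index=False)
    print(f"wrote 12 indices for {len(df)} eyes -> results/indices.csv")
    print("group means of the headline indices:")
    print(
        df.groupby("group")[["EEI", "EEI_MAX", "BEI", "BEI_MAX", "EPV", "EPSD"]]
        .mean()
        .round(2)
    )


if __name__ == "__main__":
    main()
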