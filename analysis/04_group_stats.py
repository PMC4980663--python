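#!/usr/bin/env python
"""Group statistics: ANOVA, stepwise discriminant analysis and ROC.

Takes results/indices.csv, compares the sub-clinical KC and KC arms
against normal group II (one-way ANOVA with Dunnett-style post-hoc,
empirical ROC with Youden cutoffs), runs Wilks'-lambda stepwise LDA over
the twelve indices (F-to-enter 3.84) and a fixed two-feature discriminant
on (EEI_MAX, BEI_MAX), and writes results/table_report.csv,
results/discriminant_model.json and results/discriminant_scores.csv.

Run after 03:  python analysis/04_group_stats.py
"""

from pathlib import Path

import pandas as pd

from octcornea.indices import INDEX_NAMES
from octcornea.io import write_model
from octcornea.stats import (
    discriminant_score,
    fit_discriminant,
    index_direction,
    roc_analysis,
    stepwise_lda,
    table_report,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    df = pd.read_csv(ROOT / "results" / "indices.csv")
    roc_set = df[df.group.isin(["normal_II", "subclinical_kc", "kc"])]

    report = table_report(
        roc_set, INDEX_NAMES, control_label="normal_II", case_labels=["subclinical_kc", "kc"]
    )
    report.to_csv(ROOT / "results" / "table_report.csv", index=False)
    sub = report[report.comparison == "subclinical_kc_vs_normal_II"].set_index("index")
    print("sub-clinical KC vs normal II — AUC by index:")
    print(sub["auc"].sort_values(ascending=False).to_string())

    stepwise = stepwise_lda(
        roc_set[list(INDEX_NAMES)], roc_set["group"], f_enter=3.84, control_label="normal_II"
    )
    print(f"\nstepwise selection (F-to-enter 3.84): {stepwise.features}")
    print(f"Wilks' lambda trajectory: {[round(l, 3) for l in stepwise.wilks_trajectory]}")

    model = fit_discriminant(
        roc_set[["EEI_MAX", "BEI_MAX"]], roc_set["group"], ["EEI_MAX", "BEI_MAX"],
        control_label="normal_II",
    )
    write_model(model, ROOT / "results" / "discriminant_model.json")
    scores = discriminant_score(model, df)
    out = df[["subject_id", "group"]].copy()
    out["score"] = scores
    out.to_csv(ROOT / "results" / "discriminant_scores.csv", index=False)
    means = out.groupby("group")["score"].agg(["mean", "std"]).round(2)
    print("\ndiscriminant scores on (EEI_MAX, BEI_MAX), diseased oriented higher:")
    print(means)

    sel = out[out.group.isin(["normal_II", "subclinical_kc"])]
    roc = roc_analysis(sel["score"], sel.group == "subclinical_kc", "higher")
    print(
        f"\ncombined discriminant, sub-clinical KC vs normal II: AUC {roc.auc:.3f}, "
        f"cutoff {roc.cutoff:.2f}, sensitivity {100 * roc.sensitivity_at_cutoff:.0f}%, "
        f"specificity {100 * roc.specificity_at_cutoff:.0f}%"
    )


if __name__ == "__main__":
    main()
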