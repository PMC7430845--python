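#!/usr/bin/env python
"""Per-TSS differential expression for the two contrasts: differentiation
(control vs cAMP-treated primary cells) and factor loss (parental vs
knockout line). Counts are re-tallied per sample within the TSS intervals
defined in the previous step; each contrast is TMM-normalized and tested
with the common-dispersion NB exact test at FDR < 0.05. Also tabulates the
cross-model overlap of knockout-dependent TSSs with differentiation status.

Reads results/study/ and results/tss_records.tsv; writes de_camp.tsv,
de_sox10_loss.tsv and overlap_summary.tsv under results/."""

from pathlib import Path

import pandas as pd

from promscan.differential_expression import run_de
from promscan.io_formats import read_ctss
from promscan.report_stats import crosstab_percentages

RESULTS = Path(__file__).resolve().parent.parent / "results"

CONTRASTS = {
    "camp": ("primary_control", "primary_camp"),
    "sox10_loss": ("s16_parental", "s16_dsox10"),
}


def main() -> None:
    study = RESULTS / "study"
    records = pd.read_csv(RESULTS / "tss_records.tsv", sep="\t")
    tss_ids = records["tss_id"].tolist()
    count_cols = {
        c.replace("count_", ""): c for c in records.columns if c.startswith("count_")
    }

    de_tables = {}
    for cname, (prefix_a, prefix_b) in CONTRASTS.items():
        samples_a = sorted(s for s in count_cols if s.startswith(prefix_a))
        samples_b = sorted(s for s in count_cols if s.startswith(prefix_b))
        ordered = samples_a + samples_b
        counts = records[[count_cols[s] for s in ordered]].to_numpy()
        lib = [read_ctss(study / f"ctss_{s}.tsv").library_size for s in ordered]
        groups = ["A"] * len(samples_a) + ["B"] * len(samples_b)
        de = run_de(counts, groups, row_ids=tss_ids)
        de.to_csv(RESULTS / f"de_{cname}.tsv", sep="\t", index=False)
        de_tables[cname] = de.set_index("tss_id")
        n = de["status"].value_counts()
        print(f"contrast {cname} ({'+'.join(ordered)}; libs {lib}):")
        print(n.to_string(), "\n")

    # cross-model bookkeeping over the candidate (BOTH-class) TSSs
    both = records.loc[records["class_label"] == "BOTH", "tss_id"]
    ko = de_tables["sox10_loss"].loc[both]
    camp = de_tables["camp"].loc[both]
    dependent = ko.index[ko["status"] == "DOWN"]
    pairs = {
        "dependent_of_candidates": (len(dependent), len(both)),
        "dependent_up_with_differentiation": (
            int((camp.loc[dependent, "status"] == "UP").sum()), len(dependent)),
        "dependent_down_with_differentiation": (
            int((camp.loc[dependent, "status"] == "DOWN").sum()), len(dependent)),
        "dependent_unchanged_with_differentiation": (
            int((camp.loc[dependent, "status"] == "UNCHANGED").sum()),
            len(dependent)),
    }
    overlap = crosstab_percentages(pairs, decimals=1)
    overlap.to_csv(RESULTS / "overlap_summary.tsv", sep="\t", index=False)
    print("cross-model overlap:")
    print(overlap.to_string(index=False))


if __name__ == "__main__":
    main()
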