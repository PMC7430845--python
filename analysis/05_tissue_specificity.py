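#!/usr/bin/env python
"""Score each TSS's breadth of expression across the 11-tissue panel with
the Tau index (0 = ubiquitous, 1 = single-tissue) and compare
knockout-dependent (DOWN) against unchanged TSSs; also summarize the
normalized per-tissue expression components per status class.

Reads results/study/, results/tss_records.tsv and results/de_sox10_loss.tsv;
writes tau.tsv and tissue_components.tsv under results/."""

from pathlib import Path

import numpy as np
import pandas as pd

from promscan.report_stats import mann_whitney_u
from promscan.synthetic_data import GroundTruth, match_records_to_truth
from promscan.tissue_specificity import normalized_tissue_components, tau_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    study = RESULTS / "study"
    tissue = pd.read_csv(study / "tissue_counts.tsv", sep="\t", index_col=0)
    tau = tau_table(tissue)
    tau.to_csv(RESULTS / "tau.tsv", sep="\t")

    # tissue rows are keyed by promoter; map TSSs to promoters by proximity
    frame = pd.read_csv(RESULTS / "tss_records.tsv", sep="\t")
    truth = GroundTruth.load(study)
    prom = truth.promoters
    status = (
        pd.read_csv(RESULTS / "de_sox10_loss.tsv", sep="\t")
        .set_index("tss_id")["status"]
    )
    tss_to_prom = {}
    for row in frame.itertuples(index=False):
        sub = prom[(prom["chrom"] == row.chrom) & (prom["strand"] == row.strand)]
        d = (sub["tss_pos"] - row.anchor).abs()
        if len(d) and d.min() <= 500:
            tss_to_prom[row.tss_id] = sub.loc[d.idxmin(), "promoter_id"]

    merged = pd.DataFrame(
        {
            "tss_id": list(tss_to_prom),
            "promoter_id": list(tss_to_prom.values()),
        }
    )
    merged["status"] = merged["tss_id"].map(status)
    merged["tau"] = merged["promoter_id"].map(tau["tau"])
    groups = {
        s: merged.loc[merged["status"] == s, "tau"].dropna().tolist()
        for s in ("DOWN", "UNCHANGED")
    }
    _, p = mann_whitney_u(groups["DOWN"], groups["UNCHANGED"])
    print(
        f"Tau DOWN median {np.median(groups['DOWN']):.3f} vs "
        f"UNCHANGED median {np.median(groups['UNCHANGED']):.3f}; "
        f"Mann-Whitney p = {p:.2e}"
    )

    classes = merged.set_index("promoter_id")["status"]
    comp = normalized_tissue_components(tau, classes=classes)
    comp.to_csv(RESULTS / "tissue_components.tsv", sep="\t", index=False)
    top = (
        comp[comp["class"] == "DOWN"]
        .sort_values("median", ascending=False)
        .head(3)["tissue"]
        .tolist()
    )
    print(f"tissues with highest expression of dependent TSSs: {', '.join(top)}")


if __name__ == "__main__":
    main()
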