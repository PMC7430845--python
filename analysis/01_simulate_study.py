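#!/usr/bin/env python
"""Generate the miniature synthetic promoter study that every later stage
analyzes: a 2-chromosome genome, stranded CTSS tracks for four cellular
models, planted H3K4me3/SOX10 peaks, ChIP signal, conservation, planted
binding motifs and CpG islands, an 11-tissue expression matrix, and the
ground-truth tables recording what was planted where.

Writes results/study/ (and prints the class and status composition)."""

from pathlib import Path

from promscan.synthetic_data import SimConfig, simulate_study

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    outdir = RESULTS / "study"
    cfg = SimConfig(seed=1)
    _, truth = simulate_study(cfg, outdir)
    prom = truth.promoters
    print(f"study written to {outdir}")
    print(f"{len(prom)} promoters over {cfg.n_chroms} chromosomes "
          f"of {cfg.chrom_length:,} bp")
    print("\npromoter classes:")
    print(prom["class_label"].value_counts().to_string())
    print("\nknockout-contrast statuses within the candidate (BOTH) class:")
    both = prom[prom["class_label"] == "BOTH"]
    print(both["sox10_status"].value_counts().to_string())
    print(f"\nplanted motif occurrences: {len(truth.motifs)}")


if __name__ == "__main__":
    main()
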