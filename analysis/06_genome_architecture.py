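#!/usr/bin/env python
"""Genome architecture of the consolidated catalog.

Classifies every retained miRNA as intergenic or intragenic (with miRTron
subtype), chains <=10-kb clusters, and writes the annotation, cluster table,
summary percentages and the plot-ready genome map (10,000 bp per map unit,
plus strand on the right, minus strand on the left) to results/.
"""

from pathlib import Path

import pandas as pd

from mirtissue import io as mio
from mirtissue.architecture import annotate_catalog, architecture_summary, export_genome_map
from mirtissue.config import AnalysisConfig

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"


def main() -> None:
    if not (RESULTS / "catalog_consolidated.bed").exists():
        raise SystemExit("run analysis/04_consolidate_catalog.py first")
    config = AnalysisConfig.from_yaml(STUDY.parent / "config.yaml")
    genome = mio.read_genome(STUDY / "genome.fasta")
    genes = mio.read_gff3(STUDY / "genes.gff3")
    retained = mio.read_catalog(RESULTS / "catalog_consolidated")

    annotations, clusters = annotate_catalog(
        retained, genes, chrom_names=list(genome), max_gap=config.cluster_max_gap
    )
    summary = architecture_summary(annotations, clusters)

    pd.DataFrame(
        [{"mirna": a.mirna_name, "class": a.arch_class,
          "host_gene": a.host_gene or "", "cluster": a.cluster_id or ""}
         for a in annotations]
    ).to_csv(RESULTS / "architecture.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"cluster": c.cluster_id, "chrom": c.chrom, "start": c.span[0],
          "end": c.span[1], "members": ",".join(c.members)} for c in clusters]
    ).to_csv(RESULTS / "clusters.tsv", sep="\t", index=False)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    pd.DataFrame(export_genome_map(retained, annotations, chrom_lengths)) \
        .to_csv(RESULTS / "genome_map.tsv", sep="\t", index=False)
    pd.Series(summary).round(4).rename("value") \
        .to_csv(RESULTS / "architecture_summary.tsv", sep="\t")

    print(f"{summary['pct_intergenic']:.1f}% of miRNAs are intergenic, "
          f"{summary['pct_intragenic']:.1f}% intragenic")
    print("of the intragenic miRNAs: "
          f"{summary['pct_intronic_of_intragenic']:.1f}% intronic, "
          f"{summary['pct_conventional_miRTron_of_intragenic']:.1f}% conventional "
          f"miRTrons, {summary['pct_tailed_3p_miRTron_of_intragenic']:.1f}% "
          f"3' tailed miRTrons, {summary['pct_exonic_of_intragenic']:.1f}% exonic")
    print(f"{summary['pct_mirnas_in_clusters']:.1f}% of miRNAs reside in "
          f"{int(summary['n_clusters'])} clusters; "
          f"{summary['pct_clustered_mirnas_intragenic']:.1f}% of clustered "
          "miRNAs are intragenic")


if __name__ == "__main__":
    main()
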