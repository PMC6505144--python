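#!/usr/bin/env python
"""Score the whole pipeline against the planted ground truth.

Re-runs every stage end-to-end on the simulated study inputs and compares
the outputs with the generator's manifest: per-read partition class,
per-locus architecture class, cluster co-membership and per-miRNA tissue
pattern labels. Also measures pattern recovery on planted 200-miRNA
expression matrices at 1e6 annotated reads per library, the depth at which
the four threshold rules are expected to separate cleanly.
"""

from pathlib import Path

import pandas as pd

from mirtissue import io as mio
from mirtissue.config import AnalysisConfig
from mirtissue.expression import classify_matrix, compute_rpm, log_transform, tissue_means
from mirtissue.pipeline import PipelineInputs, run_pipeline, validate_against_manifest
from mirtissue.synth import simulate_expression_matrix

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"
SOURCES = ("mirbase_v22", "aedes_ortholog", "prior_study", "candidate")


def main() -> None:
    if not STUDY.exists():
        raise SystemExit("run analysis/01_simulate_study.py first")
    config = AnalysisConfig.from_yaml(STUDY.parent / "config.yaml")
    RESULTS.mkdir(exist_ok=True)

    fastq = {p.stem: p for p in sorted(STUDY.glob("*.fastq"))}
    inputs = PipelineInputs(
        genome_fasta=STUDY / "genome.fasta", gene_gff3=STUDY / "genes.gff3",
        source_catalog_prefixes={s: STUDY / f"catalog_{s}" for s in SOURCES
                                 if (STUDY / f"catalog_{s}.bed").exists()},
        fastq=fastq,
        library_tissue={lib: lib.rsplit("_rep", 1)[0] for lib in fastq},
    )
    result = run_pipeline(config, inputs, ROOT / "scratch" / "pipeline_out")
    manifest = mio.read_manifest(STUDY / "manifest")
    recovery = validate_against_manifest(result, manifest)

    counts, layout, truth = simulate_expression_matrix(
        n_mirnas=200, depth=1_000_000, seed=config.seed, noise=True
    )
    labels = classify_matrix(
        log_transform(tissue_means(compute_rpm(counts), layout), 1.0))
    matrix_rec = sum(int(labels[n].labels == truth[n]) for n in truth) / len(truth)

    rows = {
        "partition_class_recovery": recovery["partition_class_recovery"],
        "architecture_recovery": recovery["architecture_recovery"],
        "cluster_recovery": recovery["cluster_recovery"],
        "pattern_recovery_at_study_depth": recovery["pattern_recovery"],
        "pattern_recovery_at_1e6_depth": matrix_rec,
    }
    pd.Series(rows).round(5).rename("fraction") \
        .to_csv(RESULTS / "recovery.tsv", sep="\t")
    for k, v in rows.items():
        print(f"{k}: {v:.4f}")
    print(f"\n(reads scored: {int(recovery['n_reads_scored']):,}; "
          f"loci scored: {int(recovery['n_loci_scored'])})")
    print("note: pattern recovery at the (scaled) study depth is limited by "
          "the counting floor — pan-low loci sit at ~1 annotated read per "
          "library, so exclusion/enrichment margins fluctuate; at 1e6 "
          "annotated reads the four rules separate cleanly")


if __name__ == "__main__":
    main()
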