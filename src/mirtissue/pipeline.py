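"""End-to-end orchestration: trim -> size-filter -> map -> consolidate ->
annotate/partition -> architecture -> expression -> pattern classification.

Every stage writes plain TSV/FASTA/BED/GFF3 so it can be re-run standalone;
conservation invariants are checked as the run proceeds and any violation
aborts with the failing check named. ``simulate_inputs`` materialises a full
synthetic study (genome, catalogs, gene models, 12 FASTQ libraries and the
ground-truth manifest) and ``validate_against_manifest`` scores how much of
the planted truth the pipeline recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as mio
from .architecture import annotate_catalog, architecture_summary, export_genome_map
from .catalog import ConsolidationReport, consolidate
from .config import AnalysisConfig
from .expression import (
    chromosome_profile,
    classify_matrix,
    compute_rpm,
    hierarchical_cluster,
    log_transform,
    pca,
    tissue_means,
    top_abundance,
)
from .mapping import GenomeIndex, HairpinCatalog, ReadPartition, mapping_rate, partition_library
from .reads import SizeFilterWindow, length_histogram, size_filter, trim_reads
from .synth import (
    GroundTruthManifest,
    SyntheticGenome,
    SyntheticGenomeSpec,
    default_tissue_profiles,
    design_tissue_patterns,
    generate_genome,
    simulate_library,
)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineInputs:
    genome_fasta: Path
    gene_gff3: Path
    source_catalog_prefixes: Dict[str, Path]  # source tag -> file prefix
    fastq: Dict[str, Path]  # library name -> fastq
    library_tissue: Dict[str, str]


@dataclass
class PipelineResult:
    report: Dict[str, object]
    consolidation: ConsolidationReport
    partitions: Dict[str, ReadPartition]
    annotations: list
    clusters: list
    arch_summary: Dict[str, float]
    counts: pd.DataFrame
    rpm: pd.DataFrame
    log_means: pd.DataFrame
    labels: Dict[str, object]  # mirna -> TissuePatternLabels


def simulate_inputs(
    config: AnalysisConfig,
    outdir: Path,
    genome_spec: Optional[SyntheticGenomeSpec] = None,
    depth_scale: float = 1.0,
    exact: bool = False,
    profile_overrides: Optional[Dict[str, object]] = None,
) -> Tuple[PipelineInputs, SyntheticGenome]:
    """Generate a complete synthetic study under ``outdir``.

    ``profile_overrides`` replaces fields on every tissue profile (e.g. a
    uniform ``library_depth`` for noise-free round-trip checks where every
    planted RPM value must be exactly representable in counts).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = genome_spec or SyntheticGenomeSpec.default(seed=config.seed)
    synth = generate_genome(spec)
    targets, truth = design_tissue_patterns(
        [l.name for l in synth.loci],
        tissues=config.tissues,
        seed=config.seed,
        high=config.pattern_high,
        low=config.pattern_low,
        delta=config.pattern_delta,
    )
    synth.manifest.pattern_labels = dict(truth)
    profiles = default_tissue_profiles(
        targets, tissues=config.tissues, replicates=config.replicates,
        depth_scale=depth_scale,
    )
    if profile_overrides:
        from dataclasses import replace as _replace

        profiles = [_replace(p, **profile_overrides) for p in profiles]

    mio.write_fasta(synth.genome, outdir / "genome.fasta")
    mio.write_gff3(synth.genes, outdir / "genes.gff3")
    prefixes = {}
    for source, catalog in synth.source_catalogs().items():
        if not catalog:
            continue
        prefix = outdir / f"catalog_{source}"
        mio.write_catalog(catalog, prefix)
        prefixes[source] = prefix

    fastq: Dict[str, Path] = {}
    library_tissue: Dict[str, str] = {}
    for profile in profiles:
        for rep in range(1, profile.replicates + 1):
            records, origins = simulate_library(
                profile, synth, rep, adapter=config.adapter,
                seed=config.seed, cycle_len=config.cycle_len, exact=exact,
            )
            lib = f"{profile.tissue_name}_rep{rep}"
            path = outdir / f"{lib}.fastq"
            mio.write_fastq(records, path)
            fastq[lib] = path
            library_tissue[lib] = profile.tissue_name
            synth.manifest.read_origins[lib] = origins
    mio.write_manifest(synth.manifest, outdir / "manifest")
    inputs = PipelineInputs(
        genome_fasta=outdir / "genome.fasta",
        gene_gff3=outdir / "genes.gff3",
        source_catalog_prefixes=prefixes,
        fastq=fastq,
        library_tissue=library_tissue,
    )
    return inputs, synth


SOURCE_ORDER = ("mirbase_v22", "aedes_ortholog", "prior_study", "candidate")


def run_pipeline(
    config: AnalysisConfig,
    inputs: PipelineInputs,
    outdir: Path,
    keep_read_classes: bool = True,
    write_read_classes: bool = False,
) -> PipelineResult:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fingerprint = config.fingerprint()
    report: Dict[str, object] = {"config_fingerprint": fingerprint, "stages": {}}

    genome = mio.read_genome(inputs.genome_fasta)
    index = GenomeIndex(genome)
    genes = mio.read_gff3(inputs.gene_gff3)

    # --- catalog consolidation ------------------------------------------------
    sources = [
        mio.read_catalog(inputs.source_catalog_prefixes[s])
        for s in SOURCE_ORDER
        if s in inputs.source_catalog_prefixes
    ]
    consolidation = consolidate(sources, index, config.min_reciprocal_overlap)
    retained = consolidation.retained
    mio.write_catalog(retained, outdir / "catalog_consolidated")
    removal_rows = [
        {"name": l.name, "source": l.source, "reason": reason}
        for l, reason in consolidation.removed
    ]
    mio.write_table(
        pd.DataFrame(removal_rows, columns=["name", "source", "reason"]),
        outdir / "catalog_removals.tsv",
        comment=f"config={fingerprint}", index=False,
    )
    report["stages"]["consolidate"] = {
        "input": sum(len(s) for s in sources),
        "retained": len(retained),
        "removed_multimapping": len(consolidation.removed_by_reason("multi-mapping")),
        "removed_redundant": len(consolidation.removed_by_reason("redundant-name")),
        "by_source": consolidation.counts_by_source(),
    }
    catalog = HairpinCatalog(retained)

    # --- per-library read processing + partition ------------------------------
    window = SizeFilterWindow(config.size_min, config.size_max)
    partitions: Dict[str, ReadPartition] = {}
    hist_rows = []
    part_rows = []
    for lib in sorted(inputs.fastq):
        raw = mio.read_fastq(inputs.fastq[lib])
        trimmed = trim_reads(
            (seq for _, seq in raw), config.adapter,
            config.trim_min_overlap, config.trim_error_rate,
        )
        for L, c in length_histogram(trimmed).items():
            hist_rows.append({"library": lib, "length": L, "count": c})
        kept_pairs = [
            (rid, seq)
            for (rid, _), seq in zip(raw, trimmed)
            if len(seq) in window
        ]
        rejected = len(raw) - len(kept_pairs)
        part = partition_library(
            kept_pairs, index, catalog, max_mismatch=config.max_mismatch,
            library=lib, keep_read_classes=keep_read_classes,
        )
        if part.total_filtered != len(kept_pairs):
            raise PipelineError(f"{lib}: size-filtered read conservation violated")
        try:
            part.check_conservation()
        except AssertionError as exc:
            raise PipelineError(str(exc)) from exc
        partitions[lib] = part
        if write_read_classes and keep_read_classes:
            mio.write_read_classes(part, outdir / f"read_classes.{lib}.tsv")
        row = {
            "library": lib, "tissue": inputs.library_tissue[lib],
            "raw_reads": len(raw), "size_rejected": rejected,
            "size_filtered": part.total_filtered,
            "mapped": part.all_count, "unmapped": part.unmapped_count,
            "mapping_rate_pct": 100.0 * mapping_rate(part),
            "annotated": part.annotated_count,
            "multimapping": part.multimapping_count,
            "unannotated": part.unannotated_count,
        }
        row.update(part.percentages())
        part_rows.append(row)
    part_df = pd.DataFrame(part_rows).set_index("library")
    mio.write_table(pd.DataFrame(hist_rows), outdir / "length_histograms.tsv",
                    comment=f"config={fingerprint}", index=False)
    mio.write_table(part_df, outdir / "partition_summary.tsv",
                    comment=f"config={fingerprint}")
    report["stages"]["partition"] = {
        "libraries": len(partitions),
        "mapped_total": int(part_df["mapped"].sum()),
        "annotated_total": int(part_df["annotated"].sum()),
    }

    # --- genome architecture --------------------------------------------------
    annotations, clusters = annotate_catalog(
        retained, genes, chrom_names=list(genome), max_gap=config.cluster_max_gap
    )
    arch_summary = architecture_summary(annotations, clusters)
    ann_df = pd.DataFrame(
        [
            {"name": a.mirna_name, "class": a.arch_class,
             "host_gene": a.host_gene or "", "cluster": a.cluster_id or ""}
            for a in annotations
        ]
    )
    mio.write_table(ann_df, outdir / "architecture.tsv",
                    comment=f"config={fingerprint}", index=False)
    cluster_df = pd.DataFrame(
        [
            {"cluster": c.cluster_id, "chrom": c.chrom, "start": c.span[0],
             "end": c.span[1], "n_members": len(c.members),
             "members": ",".join(c.members)}
            for c in clusters
        ],
        columns=["cluster", "chrom", "start", "end", "n_members", "members"],
    )
    mio.write_table(cluster_df, outdir / "clusters.tsv",
                    comment=f"config={fingerprint}", index=False)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    map_records = export_genome_map(retained, annotations, chrom_lengths)
    mio.write_table(pd.DataFrame(map_records), outdir / "genome_map.tsv",
                    comment=f"config={fingerprint}", index=False)
    report["stages"]["architecture"] = {k: round(v, 4) for k, v in arch_summary.items()}

    # --- expression -----------------------------------------------------------
    names = [l.name for l in retained]
    counts = pd.DataFrame(
        {lib: pd.Series(partitions[lib].mirna_counts) for lib in sorted(partitions)},
        index=names,
    ).fillna(0).astype(int)
    totals = pd.Series({lib: partitions[lib].annotated_count for lib in counts.columns})
    rpm = compute_rpm(counts, totals)
    col_sums = rpm.sum(axis=0)
    if not np.allclose(col_sums, 1e6, atol=1e-3):
        raise PipelineError("RPM conservation violated: columns do not sum to 1e6")
    means = tissue_means(rpm, inputs.library_tissue)
    log_means = log_transform(means, config.pseudocount)
    labels = classify_matrix(log_means, config.pattern_high, config.pattern_low,
                             config.pattern_delta)
    mio.write_table(counts, outdir / "counts.tsv", comment=f"config={fingerprint}")
    mio.write_table(rpm.round(4), outdir / "rpm.tsv", comment=f"config={fingerprint}")
    mio.write_table(
        log_means.round(5), outdir / "log10_tissue_means.tsv",
        comment=f"config={fingerprint} pseudocount={config.pseudocount}",
    )
    label_df = pd.DataFrame(
        [
            {"name": n, "labels": ";".join(sorted(labels[n].labels))}
            for n in names
        ]
    )
    mio.write_table(label_df, outdir / "tissue_patterns.tsv",
                    comment=f"config={fingerprint}", index=False)
    top = top_abundance(means, n=20)
    top_rows = [
        {"tissue": t, "rank": i + 1, "name": nm, "mean_rpm": round(v, 3)}
        for t, ranked in top.items()
        for i, (nm, v) in enumerate(ranked)
    ]
    mio.write_table(pd.DataFrame(top_rows), outdir / "top20.tsv",
                    comment=f"config={fingerprint}", index=False)

    loc_rows = []
    for lib, part in partitions.items():
        tissue = inputs.library_tissue[lib]
        for (chrom, pos, strand), c in part.annotated_loci.items():
            loc_rows.append({"tissue": tissue, "chrom": chrom, "pos": pos, "count": c})
    profile = chromosome_profile(
        pd.DataFrame(loc_rows), chrom_lengths, bin_bp=config.bin_bp
    )
    mio.write_table(profile["chromosome_pct"].round(4),
                    outdir / "chromosome_contribution_pct.tsv",
                    comment=f"config={fingerprint}")
    mio.write_table(profile["bins"], outdir / "chromosome_bins.tsv",
                    comment=f"config={fingerprint} bin_bp={config.bin_bp}")

    clust = hierarchical_cluster(log_means)
    (outdir / "dendrogram_rows.nwk").write_text(clust["rows"]["newick"] + "\n")
    if clust["cols"]:
        (outdir / "dendrogram_cols.nwk").write_text(clust["cols"]["newick"] + "\n")
    pc = pca(rpm)
    mio.write_table(pc["scores"].round(4), outdir / "pca_scores.tsv",
                    comment=f"config={fingerprint}")

    report["stages"]["expression"] = {
        "mirnas": len(names),
        "label_counts": _label_counts(labels),
        "pc1_var": float(pc["explained_variance_ratio"][0]),
    }
    mio.write_json(report, outdir / "run_report.json")
    return PipelineResult(
        report=report, consolidation=consolidation, partitions=partitions,
        annotations=annotations, clusters=clusters, arch_summary=arch_summary,
        counts=counts, rpm=rpm, log_means=log_means, labels=labels,
    )


def _label_counts(labels) -> Dict[str, int]:
    out: Dict[str, int] = {}
    for lab in labels.values():
        for l in lab.labels:
            key = l.split(":")[0]
            out[key] = out.get(key, 0) + 1
    return out


EXPECTED_CLASS = {"background": "unannotated"}


def validate_against_manifest(
    result: PipelineResult, manifest: GroundTruthManifest
) -> Dict[str, float]:
    """Per-axis recovery of the planted truth (fractions in [0, 1])."""
    # read partition classes ---------------------------------------------------
    n_reads = n_reads_ok = 0
    retained_names = set(result.counts.index)
    for lib, part in result.partitions.items():
        origins = manifest.read_origins.get(lib, {})
        for rid, cls in part.read_classes.items():
            origin = origins.get(rid)
            if origin is None or origin == "offsize":
                continue
            if origin == "alien":
                expected = "unmapped"
            elif origin == "background":
                expected = "unannotated"
            elif origin.startswith("multimap:"):
                expected = "multimapping"
            else:
                expected = "annotated"
            n_reads += 1
            n_reads_ok += int(cls == expected)

    # architecture classes -----------------------------------------------------
    ann = {a.mirna_name: a for a in result.annotations}
    arch_pairs = [
        (manifest.locus_classes[n], ann[n].arch_class)
        for n in manifest.locus_classes
        if n in ann
    ]
    arch_ok = sum(int(t == p) for t, p in arch_pairs)

    # cluster membership (co-member sets) --------------------------------------
    comates_true = manifest.cluster_comates()
    detected: Dict[str, frozenset] = {n: frozenset() for n in ann}
    for c in result.clusters:
        for m in c.members:
            detected[m] = frozenset(x for x in c.members if x != m)
    cl_pairs = [
        (comates_true[n], detected.get(n, frozenset()))
        for n in comates_true
        if n in ann
    ]
    cl_ok = sum(int(t == p) for t, p in cl_pairs)

    # tissue-pattern labels ----------------------------------------------------
    pat_pairs = [
        (manifest.pattern_labels[n], result.labels[n].labels)
        for n in manifest.pattern_labels
        if n in result.labels
    ]
    pat_ok = sum(int(t == p) for t, p in pat_pairs)

    def frac(ok: int, n: int) -> float:
        return ok / n if n else float("nan")

    return {
        "partition_class_recovery": frac(n_reads_ok, n_reads),
        "architecture_recovery": frac(arch_ok, len(arch_pairs)),
        "cluster_recovery": frac(cl_ok, len(cl_pairs)),
        "pattern_recovery": frac(pat_ok, len(pat_pairs)),
        "n_reads_scored": float(n_reads),
        "n_loci_scored": float(len(arch_pairs)),
        "n_patterns_scored": float(len(pat_pairs)),
    }
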