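"""Genome architecture of miRNA loci: intergenic/intragenic classes,
miRTron subtypes, <=10-kb clusters and the plot-ready genome map.

Class definitions (host strand matters only for miRTron subtypes, since
miRTron biogenesis is splicing-dependent):

* intergenic        — the hairpin overlaps no gene span on either strand
* conventional_miRTron — hairpin boundaries coincide exactly with an intron's
                      boundaries on the host strand
* tailed_3p_miRTron — hairpin 5' end flush with the intron's 5' splice site,
                      3' end leaving an intronic tail, host strand
* exonic            — hairpin fully inside an exon of the host gene
* intronic          — any other intragenic placement (fully intronic without
                      splice-site coincidence, or straddling a boundary)

Clusters chain loci on one chromosome transitively whenever consecutive
edge-to-edge distances are <= 10 kb (inclusive), strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .loci import GeneModel, MiRNALocus, interval_overlap

ARCH_CLASSES = (
    "intergenic",
    "intronic",
    "conventional_miRTron",
    "tailed_3p_miRTron",
    "exonic",
)
INTRAGENIC_CLASSES = ARCH_CLASSES[1:]


@dataclass(frozen=True)
class ArchitectureAnnotation:
    mirna_name: str
    arch_class: str
    host_gene: Optional[str] = None
    cluster_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.arch_class not in ARCH_CLASSES:
            raise ValueError(f"unknown architecture class {self.arch_class!r}")
        if (self.host_gene is None) != (self.arch_class == "intergenic"):
            raise ValueError(
                f"{self.mirna_name}: host gene must be set iff locus is intragenic"
            )


@dataclass(frozen=True)
class MiRNACluster:
    cluster_id: str
    chrom: str
    members: Tuple[str, ...]  # miRNA names, by genomic position
    span: Tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster needs at least 2 members")


def classify_locus(
    locus: MiRNALocus,
    genes: Sequence[GeneModel],
    chrom_names: Optional[Sequence[str]] = None,
    cluster_id: Optional[str] = None,
) -> ArchitectureAnnotation:
    """Assign exactly one architecture class to a miRNA locus."""
    if chrom_names is not None and locus.chrom not in set(chrom_names):
        raise ValueError(f"{locus.name}: chromosome {locus.chrom!r} not in genome")
    span = (locus.start, locus.end)
    overlapping = [
        g
        for g in genes
        if g.chrom == locus.chrom and interval_overlap(span, (g.start, g.end)) > 0
    ]
    if not overlapping:
        return ArchitectureAnnotation(locus.name, "intergenic", None, cluster_id)
    # host gene: largest overlap, deterministic tie-break by gene id
    host = max(
        overlapping,
        key=lambda g: (interval_overlap(span, (g.start, g.end)), g.gene_id),
    )
    if locus.strand == host.strand:
        for intron in host.introns:
            if span == intron:
                return ArchitectureAnnotation(
                    locus.name, "conventional_miRTron", host.gene_id, cluster_id
                )
        for intron in host.introns:
            if host.strand == "+":
                flush_5p = locus.start == intron[0] and locus.end < intron[1]
            else:
                flush_5p = locus.end == intron[1] and locus.start > intron[0]
            if flush_5p and interval_overlap(span, intron) == locus.length:
                return ArchitectureAnnotation(
                    locus.name, "tailed_3p_miRTron", host.gene_id, cluster_id
                )
    for exon in host.exons:
        if exon[0] <= locus.start and locus.end <= exon[1]:
            return ArchitectureAnnotation(locus.name, "exonic", host.gene_id, cluster_id)
    return ArchitectureAnnotation(locus.name, "intronic", host.gene_id, cluster_id)


def detect_clusters(
    loci: Sequence[MiRNALocus], max_gap: int = 10_000
) -> List[MiRNACluster]:
    """Chain loci within ``max_gap`` (edge-to-edge, inclusive) per chromosome."""
    clusters: List[MiRNACluster] = []
    by_chrom: Dict[str, List[MiRNALocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end, l.name))
        chain: List[MiRNALocus] = []
        chain_end = None
        k = sum(1 for c in clusters if c.chrom == chrom)

        def flush() -> None:
            nonlocal k
            if len(chain) >= 2:
                k += 1
                clusters.append(
                    MiRNACluster(
                        cluster_id=f"{chrom}:c{k}",
                        chrom=chrom,
                        members=tuple(l.name for l in chain),
                        span=(chain[0].start, max(l.end for l in chain)),
                    )
                )

        for locus in ordered:
            if chain and locus.start - chain_end <= max_gap:
                chain.append(locus)
                chain_end = max(chain_end, locus.end)
            else:
                flush()
                chain = [locus]
                chain_end = locus.end
        flush()
    return clusters


def cluster_membership(clusters: Sequence[MiRNACluster]) -> Dict[str, str]:
    """miRNA name -> cluster id for every clustered locus."""
    out: Dict[str, str] = {}
    for c in clusters:
        for name in c.members:
            if name in out:
                raise ValueError(f"{name} assigned to two clusters")
            out[name] = c.cluster_id
    return out


def annotate_catalog(
    loci: Sequence[MiRNALocus],
    genes: Sequence[GeneModel],
    chrom_names: Optional[Sequence[str]] = None,
    max_gap: int = 10_000,
) -> Tuple[List[ArchitectureAnnotation], List[MiRNACluster]]:
    """Classify every locus and detect clusters in one pass."""
    clusters = detect_clusters(loci, max_gap=max_gap)
    members = cluster_membership(clusters)
    annotations = [
        classify_locus(l, genes, chrom_names, cluster_id=members.get(l.name))
        for l in loci
    ]
    return annotations, clusters


def architecture_summary(
    annotations: Sequence[ArchitectureAnnotation],
    clusters: Sequence[MiRNACluster],
) -> Dict[str, float]:
    """Headline percentages of the genome-architecture analysis.

    Partition checks: intergenic + intragenic = 100 and the intragenic
    subtype percentages sum to 100 (when any intragenic locus exists).
    """
    n = len(annotations)
    if n == 0:
        raise ValueError("no annotations")
    by_name = {a.mirna_name: a for a in annotations}
    intragenic = [a for a in annotations if a.arch_class != "intergenic"]
    n_intra = len(intragenic)
    clustered = {name for c in clusters for name in c.members}
    clustered_intragenic = [
        name for name in clustered if by_name[name].arch_class != "intergenic"
    ]
    fully_intragenic_clusters = [
        c
        for c in clusters
        if all(by_name[m].arch_class != "intergenic" for m in c.members)
    ]
    pct = lambda a, b: 100.0 * a / b if b else 0.0
    summary = {
        "n_mirnas": float(n),
        "n_clusters": float(len(clusters)),
        "pct_intergenic": pct(n - n_intra, n),
        "pct_intragenic": pct(n_intra, n),
        "pct_mirnas_in_clusters": pct(len(clustered), n),
        "pct_clusters_fully_intragenic": pct(len(fully_intragenic_clusters), len(clusters)),
        "pct_clustered_mirnas_intragenic": pct(len(clustered_intragenic), len(clustered)),
    }
    for cls in INTRAGENIC_CLASSES:
        k = sum(1 for a in intragenic if a.arch_class == cls)
        summary[f"pct_{cls}_of_intragenic"] = pct(k, n_intra)
    return summary


def export_genome_map(
    loci: Sequence[MiRNALocus],
    annotations: Sequence[ArchitectureAnnotation],
    chromosome_lengths: Dict[str, int],
    scale_bp: int = 10_000,
) -> List[Dict[str, object]]:
    """Plot-ready genome map records at a fixed bp-per-unit scale.

    Plus-strand annotations draw on the right of the chromosome ideogram,
    minus-strand on the left; rendering itself is out of scope.
    """
    ann = {a.mirna_name: a for a in annotations}
    records = []
    for locus in sorted(loci, key=lambda l: (l.chrom, l.start)):
        a = ann[locus.name]
        records.append(
            {
                "mirna": locus.name,
                "chrom": locus.chrom,
                "position_bp": locus.start,
                "scaled_position": locus.start / scale_bp,
                "chrom_scaled_length": chromosome_lengths[locus.chrom] / scale_bp,
                "side": "right" if locus.strand == "+" else "left",
                "arch_class": a.arch_class,
                "intragenic": a.arch_class != "intergenic",
                "cluster_id": a.cluster_id or "",
            }
        )
    return records
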