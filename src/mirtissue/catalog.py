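"""Consolidation of the miRNA catalog from multiple annotation sources.

Sources (miRBase v22, Aedes orthologs, prior-study miRNAs, fresh candidates)
are unioned, loci whose hairpin or mature arm maps perfectly to more than one
genomic position are removed (multi-mapping reads cannot be attributed to
them), and redundantly named loci are collapsed with a fixed source
precedence: mirbase_v22 > aedes_ortholog > prior_study > candidate.

Two loci are considered redundant when their mature sequences are identical
*or* their genomic intervals overlap reciprocally by at least 50% — no
numeric redundancy rule is in common published use, so the standard
interval-merge convention is adopted and left configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .loci import SOURCE_PRECEDENCE, MiRNALocus, interval_overlap, revcomp
from .mapping import GenomeIndex

REMOVAL_REASONS = ("multi-mapping", "redundant-name")


class CatalogError(ValueError):
    pass


@dataclass
class ConsolidationReport:
    retained: List[MiRNALocus] = field(default_factory=list)
    removed: List[Tuple[MiRNALocus, str]] = field(default_factory=list)

    def removed_by_reason(self, reason: str) -> List[MiRNALocus]:
        return [l for l, r in self.removed if r == reason]

    def counts_by_source(self) -> Dict[str, Dict[str, int]]:
        out: Dict[str, Dict[str, int]] = {}
        for locus in self.retained:
            out.setdefault(locus.source, {"retained": 0, "removed": 0})["retained"] += 1
        for locus, _ in self.removed:
            out.setdefault(locus.source, {"retained": 0, "removed": 0})["removed"] += 1
        return out

    def merge(self, other: "ConsolidationReport") -> "ConsolidationReport":
        return ConsolidationReport(
            retained=list(other.retained), removed=self.removed + other.removed
        )


def _occurrences(index: GenomeIndex, seq: str) -> int:
    return len(index.lookup(seq))


def flag_multimapping_loci(
    loci: Sequence[MiRNALocus], index: GenomeIndex
) -> ConsolidationReport:
    """Remove loci whose hairpin OR either mature arm occurs >=2 times.

    A mature-only duplication still confounds counting of mature-length
    reads, hence arms are tested alongside the full hairpin. A locus whose
    hairpin is absent from the genome at its stated coordinates is a broken
    input and raises.
    """
    report = ConsolidationReport()
    for locus in loci:
        genome_slice = index.chroms.get(locus.chrom, "")[locus.start : locus.end]
        hp = locus.hairpin_seq.upper()
        if genome_slice != (hp if locus.strand == "+" else revcomp(hp)):
            raise CatalogError(
                f"hairpin of {locus.name} not found at "
                f"{locus.chrom}:{locus.start}-{locus.end}({locus.strand})"
            )
        multi = _occurrences(index, hp) >= 2 or any(
            _occurrences(index, m) >= 2 for m in locus.mature_seqs()
        )
        if multi:
            report.removed.append((locus, "multi-mapping"))
        else:
            report.retained.append(locus)
    return report


def _redundant(a: MiRNALocus, b: MiRNALocus, min_reciprocal_overlap: float) -> bool:
    if set(a.mature_seqs()) & set(b.mature_seqs()):
        return True
    if a.chrom != b.chrom:
        return False
    ov = interval_overlap((a.start, a.end), (b.start, b.end))
    return (
        ov >= min_reciprocal_overlap * a.length
        and ov >= min_reciprocal_overlap * b.length
    )


def deduplicate(
    loci: Sequence[MiRNALocus], min_reciprocal_overlap: float = 0.5
) -> ConsolidationReport:
    """Collapse redundant names; the survivor follows source precedence.

    Redundancy is transitive (union-find over pairwise redundancy); within a
    group the survivor is the locus with the best source precedence, ties
    broken by name, so the result is independent of input order.
    """
    loci = list(loci)
    parent = list(range(len(loci)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            if _redundant(loci[i], loci[j], min_reciprocal_overlap):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: Dict[int, List[MiRNALocus]] = {}
    for i, locus in enumerate(loci):
        groups.setdefault(find(i), []).append(locus)

    report = ConsolidationReport()
    for members in groups.values():
        members = sorted(members, key=lambda l: (SOURCE_PRECEDENCE[l.source], l.name))
        report.retained.append(members[0])
        for other in members[1:]:
            report.removed.append((other, "redundant-name"))
    report.retained.sort(key=lambda l: (l.chrom, l.start, l.name))
    return report


def consolidate(
    sources: Sequence[Sequence[MiRNALocus]],
    index: GenomeIndex,
    min_reciprocal_overlap: float = 0.5,
) -> ConsolidationReport:
    """Union the tagged sources, drop genome multi-mappers, then deduplicate."""
    union: List[MiRNALocus] = [locus for source in sources for locus in source]
    names = [l.name for l in union]
    if len(set(names)) != len(names):
        raise CatalogError("duplicate locus names across sources")
    mm_report = flag_multimapping_loci(union, index)
    dd_report = deduplicate(mm_report.retained, min_reciprocal_overlap)
    return mm_report.merge(dd_report)
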