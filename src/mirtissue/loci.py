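"""Core domain records: miRNA loci and protein-coding gene models.

Coordinates are 0-based half-open genomic intervals throughout the package
(BED convention). Mature-arm intervals are stored *hairpin-relative*, i.e.
offsets into ``hairpin_seq`` read 5'->3' along the hairpin strand, which is
what read annotation and hairpin vetting operate on; conversion to genomic
coordinates happens only at BED export time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

SOURCES = ("mirbase_v22", "aedes_ortholog", "prior_study", "candidate")

#: precedence used to pick the surviving name when loci are redundant
SOURCE_PRECEDENCE = {s: i for i, s in enumerate(SOURCES)}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MiRNALocus:
    """One miRNA gene: hairpin coordinates, sequence and mature arms."""

    name: str
    source: str
    chrom: str
    start: int
    end: int
    strand: str
    hairpin_seq: str
    mature_5p: Optional[Tuple[int, int]] = None  # hairpin-relative, half-open
    mature_3p: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source tag {self.source!r} for {self.name}")
        if not self.start < self.end:
            raise ValueError(f"{self.name}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.name}: strand must be '+' or '-'")
        if len(self.hairpin_seq) != self.end - self.start:
            raise ValueError(
                f"{self.name}: hairpin length {len(self.hairpin_seq)} != "
                f"interval length {self.end - self.start}"
            )
        for arm_name, arm in (("5p", self.mature_5p), ("3p", self.mature_3p)):
            if arm is None:
                continue
            a, b = arm
            if not (0 <= a < b <= len(self.hairpin_seq)):
                raise ValueError(f"{self.name}: mature {arm_name} arm outside hairpin")

    @property
    def length(self) -> int:
        return self.end - self.start

    def arm_seq(self, arm: str) -> Optional[str]:
        iv = self.mature_5p if arm == "5p" else self.mature_3p
        if iv is None:
            return None
        return self.hairpin_seq[iv[0] : iv[1]]

    def mature_seqs(self) -> list[str]:
        return [s for s in (self.arm_seq("5p"), self.arm_seq("3p")) if s]

    def arm_of_offset(self, offset: int, read_len: int) -> Optional[str]:
        """Attribute a read placed at ``offset`` within the hairpin to an arm.

        Uses midpoint containment: the read belongs to the arm whose interval
        contains the read midpoint; reads outside both arms count only to the
        hairpin total (returns None).
        """
        mid = offset + read_len / 2.0
        for arm_name, iv in (("5p", self.mature_5p), ("3p", self.mature_3p)):
            if iv is not None and iv[0] <= mid < iv[1]:
                return arm_name
        return None


@dataclass(frozen=True)
class GeneModel:
    """A host gene: sorted non-overlapping exons; introns are the gaps."""

    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError(f"{self.gene_id}: gene without exons")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        )


def interval_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    """Length of the overlap of two half-open intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))
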