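"""Genome placement and mismatch-tolerant miRNA annotation.

Reads are placed by exact match on both strands (a read's unique/multi-mapping
status is then unambiguous and oracle-checkable); unique reads are annotated
against the hairpin catalog by minimum Hamming distance over every same-length
window of every hairpin, in sense orientation, tolerating up to 2 mismatches.

The library-level entry point, :func:`partition_library`, produces the
four-way read partition used throughout the analysis:

    all (mapped, size-filtered) = annotated + multi-mapping + unannotated

with multi-mapping reads excluded from every downstream expression value.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .loci import MiRNALocus, revcomp

READ_CLASSES = ("annotated", "multimapping", "unannotated", "unmapped")


@dataclass(frozen=True)
class MappedRead:
    read_id: str
    loci: Tuple[Tuple[str, int, str], ...]  # (chrom, 0-based start, strand)

    @property
    def multiplicity(self) -> int:
        return len(self.loci)


class GenomeIndex:
    """Exhaustive exact-substring lookup over both strands of a genome.

    Forward-strand 20-mers are hashed; a query of length >= seed size is
    located by seed lookup plus full verification, and its minus-strand
    occurrences by looking up its reverse complement. Shorter queries fall
    back to a linear scan, so lookup is exhaustive for any length.
    """

    def __init__(self, chroms: Dict[str, str], seed_k: int = 20):
        self.chroms = {name: seq.upper() for name, seq in chroms.items()}
        self.seed_k = seed_k
        self._seed: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
        for name in sorted(self.chroms):
            seq = self.chroms[name]
            k = seed_k
            for i in range(len(seq) - k + 1):
                self._seed[seq[i : i + k]].append((name, i))

    def _scan(self, query: str) -> List[Tuple[str, int]]:
        hits = []
        for name in sorted(self.chroms):
            seq = self.chroms[name]
            i = seq.find(query)
            while i != -1:
                hits.append((name, i))
                i = seq.find(query, i + 1)
        return hits

    def _forward_occurrences(self, query: str) -> List[Tuple[str, int]]:
        k = self.seed_k
        if len(query) < k:
            return self._scan(query)
        out = []
        for name, i in self._seed.get(query[:k], ()):
            if self.chroms[name][i : i + len(query)] == query:
                out.append((name, i))
        return out

    def lookup(self, query: str) -> List[Tuple[str, int, str]]:
        """Every occurrence of ``query`` as (chrom, start, strand)."""
        query = query.upper()
        fwd = [(c, p, "+") for c, p in self._forward_occurrences(query)]
        rc = revcomp(query)
        rev = [(c, p, "-") for c, p in self._forward_occurrences(rc)]
        if rc == query:  # palindromic query: same placements, count once
            return sorted(fwd)
        return sorted(fwd + rev)


def map_read(read_id: str, seq: str, index: GenomeIndex) -> MappedRead:
    return MappedRead(read_id, tuple(index.lookup(seq)))


@dataclass(frozen=True)
class AnnotationHit:
    read_seq: str
    mirna_name: str
    mismatches: int
    offset: int  # start of the matched window within the hairpin
    arm: Optional[str] = None  # '5p' / '3p' / None (hairpin body)


class HairpinCatalog:
    """Mismatch-tolerant window lookup over a set of hairpin sequences.

    Hairpins are concatenated (with a separator byte that mismatches every
    base) and compared to a read with one vectorised Hamming scan per query;
    an exact-window hash serves the common 0-mismatch case. Ties are broken
    by fewest mismatches, then catalog order, then leftmost offset — which is
    exactly the order windows appear in the concatenation.
    """

    _SEP = 35  # '#'

    def __init__(self, loci: Sequence[MiRNALocus]):
        self.loci = list(loci)
        self._by_name = {l.name: l for l in self.loci}
        parts: List[bytes] = []
        cat_idx: List[int] = []
        offsets: List[int] = []
        hp_len: List[int] = []
        for idx, locus in enumerate(self.loci):
            # N in a catalog sequence must mismatch everything, like the separator
            s = locus.hairpin_seq.upper().replace("N", "#").encode()
            parts.append(s + b"#")
            n = len(s)
            cat_idx.extend([idx] * (n + 1))
            offsets.extend(list(range(n)) + [-1])
            hp_len.extend([n] * (n + 1))
        self._concat = np.frombuffer(b"".join(parts), dtype=np.uint8).copy()
        self._cat_idx = np.asarray(cat_idx, dtype=np.int32)
        self._offsets = np.asarray(offsets, dtype=np.int32)
        self._hp_len = np.asarray(hp_len, dtype=np.int32)
        self._exact: Dict[str, Tuple[int, int]] = {}
        for idx, locus in enumerate(self.loci):
            s = locus.hairpin_seq.upper()
            for L in range(18, 31):
                for off in range(0, len(s) - L + 1):
                    w = s[off : off + L]
                    if "N" not in w:
                        self._exact.setdefault(w, (idx, off))
        self._windows_cache: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}

    def __len__(self) -> int:
        return len(self.loci)

    def locus(self, name: str) -> MiRNALocus:
        return self._by_name[name]

    def _windows(self, L: int) -> Tuple[np.ndarray, np.ndarray]:
        cached = self._windows_cache.get(L)
        if cached is not None:
            return cached
        sw = np.lib.stride_tricks.sliding_window_view(self._concat, L)
        valid = (self._offsets[: len(sw)] >= 0) & (
            self._offsets[: len(sw)] + L <= self._hp_len[: len(sw)]
        )
        self._windows_cache[L] = (sw, valid)
        return sw, valid

    def best_hit(self, seq: str, max_mismatch: int = 2) -> Optional[AnnotationHit]:
        """Minimum-Hamming window over the whole catalog, or None."""
        seq = seq.upper()
        if not self.loci or not seq:
            return None
        if "N" not in seq:
            exact = self._exact.get(seq)
            if exact is not None:
                idx, off = exact
                locus = self.loci[idx]
                return AnnotationHit(seq, locus.name, 0, off, locus.arm_of_offset(off, len(seq)))
        L = len(seq)
        if L > len(self._concat):
            return None
        # a read N never matches a catalog base: encode it as a byte absent
        # from both the catalog alphabet and the separator
        q = np.frombuffer(seq.replace("N", "!").encode(), dtype=np.uint8)
        sw, valid = self._windows(L)
        mism = (sw != q).sum(axis=1)
        mism = np.where(valid, mism, L + 1)
        best = int(mism.min())
        if best > max_mismatch:
            return None
        row = int(np.flatnonzero(mism == best)[0])  # catalog order, then offset
        idx = int(self._cat_idx[row])
        off = int(self._offsets[row])
        locus = self.loci[idx]
        return AnnotationHit(seq, locus.name, best, off, locus.arm_of_offset(off, L))


def annotate_read(
    seq: str, catalog: HairpinCatalog, max_mismatch: int = 2
) -> Optional[AnnotationHit]:
    """Annotate one unique-mapping read against the hairpin catalog."""
    return catalog.best_hit(seq, max_mismatch=max_mismatch)


@dataclass
class ReadPartition:
    """Per-library four-way read partition and per-miRNA counts."""

    library: str
    all_count: int = 0  # mapped, size-filtered
    annotated_count: int = 0
    multimapping_count: int = 0
    unannotated_count: int = 0
    unmapped_count: int = 0
    read_classes: Dict[str, str] = field(default_factory=dict)
    mirna_counts: Counter = field(default_factory=Counter)  # name -> reads
    arm_counts: Counter = field(default_factory=Counter)  # (name, arm) -> reads
    annotated_loci: Counter = field(default_factory=Counter)  # (chrom,start,strand)->reads

    def check_conservation(self) -> None:
        if self.annotated_count + self.multimapping_count + self.unannotated_count != self.all_count:
            raise AssertionError(
                f"{self.library}: partition classes do not sum to mapped reads"
            )

    @property
    def total_filtered(self) -> int:
        return self.all_count + self.unmapped_count

    def percentages(self) -> Dict[str, float]:
        d = self.all_count or 1
        return {
            "annotated_pct": 100.0 * self.annotated_count / d,
            "multimapping_pct": 100.0 * self.multimapping_count / d,
            "unannotated_pct": 100.0 * self.unannotated_count / d,
        }


def partition_library(
    reads: Iterable[Tuple[str, str]],
    index: GenomeIndex,
    catalog: HairpinCatalog,
    max_mismatch: int = 2,
    library: str = "library",
    keep_read_classes: bool = True,
) -> ReadPartition:
    """Classify every size-filtered read of one library.

    ``reads`` is an iterable of (read_id, sequence). Work is done once per
    distinct sequence; multi-mapping reads are classed and dropped from all
    downstream quantification, unique reads are annotated or left unannotated.
    """
    part = ReadPartition(library=library)
    ids_by_seq: Dict[str, List[str]] = defaultdict(list)
    for rid, seq in reads:
        ids_by_seq[seq.upper()].append(rid)

    for seq in sorted(ids_by_seq):
        rids = ids_by_seq[seq]
        n = len(rids)
        placements = index.lookup(seq)
        if len(placements) == 0:
            cls = "unmapped"
            part.unmapped_count += n
        elif len(placements) >= 2:
            cls = "multimapping"
            part.multimapping_count += n
            part.all_count += n
        else:
            part.all_count += n
            hit = catalog.best_hit(seq, max_mismatch=max_mismatch)
            if hit is None:
                cls = "unannotated"
                part.unannotated_count += n
            else:
                cls = "annotated"
                part.annotated_count += n
                part.mirna_counts[hit.mirna_name] += n
                if hit.arm is not None:
                    part.arm_counts[(hit.mirna_name, hit.arm)] += n
                part.annotated_loci[placements[0]] += n
        if keep_read_classes:
            for rid in rids:
                part.read_classes[rid] = cls
    part.check_conservation()
    return part


def mapping_rate(partition: ReadPartition) -> float:
    """Fraction of size-filtered reads with at least one genomic placement."""
    total = partition.total_filtered
    return partition.all_count / total if total else 0.0
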