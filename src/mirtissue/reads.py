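"""Read preprocessing: 3' adapter trimming, size selection, length histograms.

Trimming follows standard single-end 3'-adapter semantics: at every start
position the adapter prefix is aligned against the remainder of the read
(overlap = min(adapter length, bases left)), and the read is truncated at the
leftmost position whose mismatch fraction is within ``error_rate``, requiring
at least ``min_overlap`` aligned bases. The community-standard defaults
(min_overlap=3, error_rate=0.1) are exposed through AnalysisConfig.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SizeFilterWindow:
    """Inclusive read-length window; the miRNA-focused default is 20-24 nt."""

    min_len: int = 20
    max_len: int = 24

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")

    def __contains__(self, length: int) -> bool:
        return self.min_len <= length <= self.max_len


def trim_adapter_seq(
    seq: str, adapter: str, min_overlap: int = 3, error_rate: float = 0.1
) -> str:
    """Truncate ``seq`` at the leftmost acceptable adapter alignment.

    Returns the sequence unchanged when no alignment satisfies the overlap
    and error constraints.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not (0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    n, m = len(seq), len(adapter)
    for pos in range(0, n - min_overlap + 1):
        overlap = min(m, n - pos)
        allowed = int(error_rate * overlap)
        mismatches = 0
        ok = True
        window = seq[pos : pos + overlap]
        for a, b in zip(window, adapter):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    ok = False
                    break
        if ok:
            return seq[:pos]
    return seq


def trim_adapter(
    read: ReadRecord, adapter: str, min_overlap: int = 3, error_rate: float = 0.1
) -> ReadRecord:
    return ReadRecord(read.read_id, trim_adapter_seq(read.sequence, adapter, min_overlap, error_rate))


def trim_reads(
    seqs: Iterable[str], adapter: str, min_overlap: int = 3, error_rate: float = 0.1
) -> List[str]:
    """Trim a whole library, memoised by sequence.

    Small-RNA libraries are dominated by a few thousand distinct sequences,
    so caching the per-sequence result makes trimming effectively linear in
    the number of *distinct* reads.
    """
    cache: Dict[str, str] = {}
    out: List[str] = []
    for s in seqs:
        t = cache.get(s)
        if t is None:
            t = trim_adapter_seq(s, adapter, min_overlap, error_rate)
            cache[s] = t
        out.append(t)
    return out


def size_filter(
    seqs: Sequence[str], window: SizeFilterWindow = SizeFilterWindow()
) -> Tuple[List[str], int]:
    """Retain reads whose length falls inside the inclusive window.

    Returns (retained, rejected_count); retained + rejected == input count.
    """
    retained = [s for s in seqs if len(s) in window]
    return retained, len(seqs) - len(retained)


def length_histogram(seqs: Iterable[str]) -> Dict[int, int]:
    """Map read length -> read count (counts sum to the number of reads)."""
    return dict(sorted(Counter(len(s) for s in seqs).items()))
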