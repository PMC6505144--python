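"""Vetting of candidate pre-miRNA hairpins.

A candidate passes when it satisfies all three RNase-III-cleavage
plausibility criteria:

1. the hairpin folds into a stable structure with minimum free energy
   <= -30 kcal/mol ("at least -30 kcal/mol" read as *at least that stable*;
   the boundary value -30.0 passes);
2. the star arm — the mature arm with fewer supporting reads (ties resolve
   to 3p) — has at least one read;
3. in the folded duplex each arm's 3' end extends >= 2 nt past the region
   paired with the other arm (the canonical Drosha/Dicer 2-nt 3' overhang),
   required on both arms by default and relaxable to one.

Folding is a pluggable backend. The default is ViennaRNA's thermodynamic
model through its python bindings; a self-contained Nussinov-style
base-pair-maximisation backend with crude per-pair energies is provided as
an approximate fallback and is clearly labelled as such in its reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Protocol, Tuple


class FoldingError(RuntimeError):
    pass


class FoldingBackend(Protocol):
    name: str

    def fold(self, sequence: str) -> Tuple[float, str]:
        """Return (mfe in kcal/mol, dot-bracket structure)."""
        ...


class ViennaRNABackend:
    """Thermodynamic MFE folding via the ViennaRNA python bindings."""

    name = "viennarna"

    def __init__(self) -> None:
        import RNA  # deferred: bindings ship with the ViennaRNA installation

        self._rna = RNA

    def fold(self, sequence: str) -> Tuple[float, str]:
        structure, mfe = self._rna.fold(sequence.replace("T", "U").replace("t", "u"))
        return float(mfe), structure


class NussinovBackend:
    """Approximate fallback folder: Nussinov-style energy minimisation.

    Minimises a sum of per-pair pseudo-energies (GC -3, AU -2, GU -1
    kcal/mol) with a minimum hairpin loop of 3 nt. No stacking or loop
    entropies — suitable for threshold logic and structure plumbing, not for
    quantitative thermodynamics.
    """

    name = "nussinov-approx"
    _PAIR_E = {
        ("G", "C"): -3.0, ("C", "G"): -3.0,
        ("A", "T"): -2.0, ("T", "A"): -2.0,
        ("A", "U"): -2.0, ("U", "A"): -2.0,
        ("G", "T"): -1.0, ("T", "G"): -1.0,
        ("G", "U"): -1.0, ("U", "G"): -1.0,
    }
    _MIN_LOOP = 3

    def fold(self, sequence: str) -> Tuple[float, str]:
        s = sequence.upper()
        n = len(s)
        if n == 0:
            raise FoldingError("cannot fold an empty sequence")
        E = [[0.0] * n for _ in range(n)]
        for span in range(self._MIN_LOOP + 1, n):
            for i in range(0, n - span):
                j = i + span
                best = min(E[i + 1][j], E[i][j - 1])
                pe = self._PAIR_E.get((s[i], s[j]))
                if pe is not None:
                    best = min(best, E[i + 1][j - 1] + pe)
                for k in range(i + 1, j):
                    best = min(best, E[i][k] + E[k + 1][j])
                E[i][j] = best
        structure = ["."] * n

        def traceback(i: int, j: int) -> None:
            while i < j:
                if E[i][j] == 0.0:
                    return
                if E[i][j] == E[i + 1][j]:
                    i += 1
                    continue
                if E[i][j] == E[i][j - 1]:
                    j -= 1
                    continue
                pe = self._PAIR_E.get((s[i], s[j]))
                if pe is not None and E[i][j] == E[i + 1][j - 1] + pe:
                    structure[i], structure[j] = "(", ")"
                    i, j = i + 1, j - 1
                    continue
                for k in range(i + 1, j):
                    if E[i][j] == E[i][k] + E[k + 1][j]:
                        traceback(i, k)
                        i = k + 1
                        break
                else:  # pragma: no cover - defensive
                    return

        traceback(0, n - 1)
        return E[0][n - 1], "".join(structure)


def default_backend() -> FoldingBackend:
    try:
        return ViennaRNABackend()
    except ImportError:
        return NussinovBackend()


def parse_dot_bracket(structure: str) -> Dict[int, int]:
    """Position -> paired position for a balanced dot-bracket string."""
    stack: List[int] = []
    pairs: Dict[int, int] = {}
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
        elif c != ".":
            raise ValueError(f"bad dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return pairs


def duplex_overhangs(
    pairs: Dict[int, int],
    arm_5p: Tuple[int, int],
    arm_3p: Tuple[int, int],
) -> Optional[Tuple[int, int]]:
    """3' overhang lengths (5p arm, 3p arm) implied by the folded duplex.

    The overhang of an arm is how far its 3' end extends past its last
    nucleotide paired to the other arm. Returns None when the two arms share
    no base pair (no duplex at all).
    """
    a5, b5 = arm_5p
    a3, b3 = arm_3p
    paired_5p = [i for i in range(a5, b5) if a3 <= pairs.get(i, -1) < b3]
    paired_3p = [j for j in range(a3, b3) if a5 <= pairs.get(j, -1) < b5]
    if not paired_5p or not paired_3p:
        return None
    return (b5 - 1) - max(paired_5p), (b3 - 1) - max(paired_3p)


@dataclass(frozen=True)
class HairpinEvaluation:
    name: str
    mfe: float
    structure: str
    backend: str
    stable_hairpin: bool          # criterion 1
    star_read_support: bool       # criterion 2
    duplex_overhang_ok: bool      # criterion 3
    star_arm: str
    overhangs: Optional[Tuple[int, int]]

    @property
    def verdict(self) -> bool:
        return self.stable_hairpin and self.star_read_support and self.duplex_overhang_ok


def evaluate_candidate(
    name: str,
    hairpin_seq: str,
    mature_5p: Tuple[int, int],
    mature_3p: Tuple[int, int],
    read_counts: Tuple[int, int],
    backend: Optional[FoldingBackend] = None,
    mfe_threshold: float = -30.0,
    min_overhang: int = 2,
    require_both_overhangs: bool = True,
) -> HairpinEvaluation:
    """Apply the three plausibility criteria to one candidate hairpin.

    ``read_counts`` are (5p reads, 3p reads). The verdict is the conjunction
    of the three per-criterion flags.
    """
    for arm in (mature_5p, mature_3p):
        if not (0 <= arm[0] < arm[1] <= len(hairpin_seq)):
            raise ValueError(f"{name}: mature arm outside hairpin")
    backend = backend or default_backend()
    try:
        mfe, structure = backend.fold(hairpin_seq)
    except Exception as exc:  # propagate with candidate name attached
        raise FoldingError(f"folding failed for candidate {name}: {exc}") from exc
    if len(structure) != len(hairpin_seq):
        raise FoldingError(f"backend returned wrong-length structure for {name}")

    stable = mfe <= mfe_threshold
    n5, n3 = read_counts
    star_arm = "3p" if n3 <= n5 else "5p"
    star_reads = n3 if star_arm == "3p" else n5
    star_ok = star_reads >= 1

    overhangs = duplex_overhangs(parse_dot_bracket(structure), mature_5p, mature_3p)
    if overhangs is None:
        overhang_ok = False
    elif require_both_overhangs:
        overhang_ok = min(overhangs) >= min_overhang
    else:
        overhang_ok = max(overhangs) >= min_overhang

    return HairpinEvaluation(
        name=name,
        mfe=mfe,
        structure=structure,
        backend=backend.name,
        stable_hairpin=stable,
        star_read_support=star_ok,
        duplex_overhang_ok=overhang_ok,
        star_arm=star_arm,
        overhangs=overhangs,
    )
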