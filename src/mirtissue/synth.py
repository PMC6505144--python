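"""Synthetic mini-genome and tissue read-library generator with ground truth.

Everything downstream of raw FASTQ can be exercised against this module:
it plants miRNA hairpins of every architecture class (intergenic, intronic,
conventional miRTron, 3'-tailed miRTron, exonic), chains some of them into
<=10-kb clusters, duplicates decoy hairpins verbatim to create genuine
multi-mapping loci, fabricates redundant catalog entries under alternative
names, and simulates per-tissue replicate libraries whose per-miRNA
abundances follow configurable planted expression patterns. A
:class:`GroundTruthManifest` records the origin of every read and the true
class/cluster/pattern of every locus, so recovery can be scored exactly.

The default :meth:`SyntheticGenomeSpec.default` mirrors the catalog
composition and genome architecture of the tissue atlas this package
re-implements: 139 retained miRNAs (103 miRBase, 8 Aedes orthologs,
21 prior-study, 7 candidates; 89 intergenic / 44 intronic / 3 conventional
miRTrons / 2 tailed miRTrons / 1 exonic; 16 clusters holding 52 loci, 22 of
them intragenic) plus 38 multi-mapping and 8 redundantly named decoy
entries, over six chromosomes named like the AgamP4 assembly.

Randomness: one top-level seed is fanned out to sub-generators through
``numpy.random.SeedSequence.spawn``, so generation is byte-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .expression import classify_tissue_pattern
from .loci import GeneModel, MiRNALocus, revcomp
from .mapping import GenomeIndex, HairpinCatalog

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_TISSUES = ("fat_body", "midgut", "ovary", "remainder")

#: study-condition defaults: per-replicate size-filtered depths (10x scaled
#: down from the sequencing study emulated), multi-mapping and unannotated
#: shares of mapped size-filtered reads, and a small non-genomic fraction so
#: the measured mapping rate lands in the ~99.6% regime.
TISSUE_DEFAULTS: Dict[str, Dict[str, float]] = {
    "fat_body": {"size_filtered_depth": 190_000, "multimap_fraction": 0.262},
    "midgut": {"size_filtered_depth": 310_000, "multimap_fraction": 0.418},
    "ovary": {"size_filtered_depth": 40_000, "multimap_fraction": 0.366},
    "remainder": {"size_filtered_depth": 120_000, "multimap_fraction": 0.686},
}
DEFAULT_UNANNOTATED_FRACTION = 0.065
DEFAULT_UNMAPPED_FRACTION = 0.004
DEFAULT_OFF_SIZE_FRACTION = 0.2
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter
#: downstream library sequence read through after the adapter on short inserts,
#: so every simulated read has the full cycle length
POST_ADAPTER = "AACTCCAGTCACATCACGATCTCGTATGCCGTCTTCTGCTTG"
DEFAULT_LENGTH_SPECTRUM = {20: 0.08, 21: 0.17, 22: 0.40, 23: 0.22, 24: 0.13}
#: qualitative off-size peaks per tissue (magnitudes are not published)
OFF_SIZE_SPECTRA: Dict[str, Dict[int, float]] = {
    "fat_body": {29: 0.35, 32: 0.35, 41: 0.30},
    "midgut": {29: 0.35, 32: 0.35, 41: 0.30},
    "ovary": {25: 0.2, 26: 0.2, 27: 0.2, 28: 0.15, 29: 0.15, 30: 0.1},
    "remainder": {29: 0.7, 31: 0.3},
}


class PackingError(RuntimeError):
    """Requested loci exceed chromosome capacity."""


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    chromosome_lengths: Dict[str, int]
    n_mirnas_per_class: Dict[str, int]
    clusters: Tuple[Tuple[int, bool], ...] = ()  # (size, intragenic)
    n_multimap_decoys: Dict[str, int] = field(default_factory=dict)
    n_redundant_prior: int = 0
    source_counts: Optional[Dict[str, int]] = None
    seed: int = 0
    hairpin_len_range: Tuple[int, int] = (70, 100)
    arm_len: int = 22
    background_pool_size: int = 800
    off_size_pool_size: int = 400
    alien_pool_size: int = 60

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.chromosome_lengths.values()):
            raise ValueError("chromosome lengths must be > 0")
        if any(v < 0 for v in self.n_mirnas_per_class.values()):
            raise ValueError("class counts must be >= 0")
        if not (60 <= self.hairpin_len_range[0] <= self.hairpin_len_range[1] <= 120):
            raise ValueError("hairpin lengths must lie in [60, 120]")
        intr = sum(s for s, intra in self.clusters if intra)
        if intr > self.n_mirnas_per_class.get("intronic", 0):
            raise ValueError("intragenic clusters request more intronic loci than exist")
        inter = sum(s for s, intra in self.clusters if not intra)
        if inter > self.n_mirnas_per_class.get("intergenic", 0):
            raise ValueError("intergenic clusters request more intergenic loci than exist")
        if self.source_counts is not None:
            if sum(self.source_counts.values()) != self.n_loci:
                raise ValueError("source_counts must sum to the number of loci")

    @property
    def n_loci(self) -> int:
        return sum(self.n_mirnas_per_class.values())

    @property
    def n_multimap_loci(self) -> int:
        return sum(self.n_multimap_decoys.values())

    @classmethod
    def default(cls, seed: int = 0) -> "SyntheticGenomeSpec":
        """The study-condition genome: 139 retained loci, 16 clusters."""
        clusters = tuple([(4, True)] + [(3, True)] * 6 + [(4, False)] * 3 + [(3, False)] * 6)
        return cls(
            chromosome_lengths={
                "2L": 520_000, "2R": 540_000, "3L": 460_000,
                "3R": 480_000, "X": 380_000, "UNKN": 140_000,
            },
            n_mirnas_per_class={
                "intergenic": 89, "intronic": 44, "conventional_miRTron": 3,
                "tailed_3p_miRTron": 2, "exonic": 1,
            },
            clusters=clusters,
            n_multimap_decoys={"mirbase_v22": 26, "prior_study": 12},
            n_redundant_prior=8,
            source_counts={
                "mirbase_v22": 103, "aedes_ortholog": 8,
                "prior_study": 21, "candidate": 7,
            },
            seed=seed,
        )

    @classmethod
    def small(cls, seed: int = 0) -> "SyntheticGenomeSpec":
        """A fast test-sized genome with every feature represented."""
        return cls(
            chromosome_lengths={"chr1": 200_000, "chr2": 180_000},
            n_mirnas_per_class={
                "intergenic": 8, "intronic": 6, "conventional_miRTron": 2,
                "tailed_3p_miRTron": 2, "exonic": 1,
            },
            clusters=((3, True), (2, False), (3, False)),
            n_multimap_decoys={"mirbase_v22": 2, "prior_study": 1},
            n_redundant_prior=1,
            source_counts={
                "mirbase_v22": 9, "aedes_ortholog": 3,
                "prior_study": 4, "candidate": 3,
            },
            seed=seed,
            background_pool_size=300,
            off_size_pool_size=150,
        )


@dataclass(frozen=True)
class TissueProfileSpec:
    """Per-tissue simulation profile; fractions refer to mapped size-filtered reads."""

    tissue_name: str
    replicates: int
    planted_pattern: Mapping[str, float]  # miRNA -> target mean RPM in this tissue
    length_spectrum: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_SPECTRUM)
    )
    off_size_spectrum: Mapping[int, float] = field(
        default_factory=lambda: {29: 1.0}
    )
    multimap_fraction: float = 0.3
    unannotated_fraction: float = DEFAULT_UNANNOTATED_FRACTION
    unmapped_fraction: float = DEFAULT_UNMAPPED_FRACTION
    off_size_fraction: float = DEFAULT_OFF_SIZE_FRACTION
    library_depth: int = 100_000  # total reads per replicate, all sizes
    arm_bias_5p: float = 0.85

    def __post_init__(self) -> None:
        if not self.planted_pattern:
            raise ValueError("planted_pattern must not be empty")
        for spec_name, spectrum in (
            ("length_spectrum", self.length_spectrum),
            ("off_size_spectrum", self.off_size_spectrum),
        ):
            if abs(sum(spectrum.values()) - 1.0) > 1e-9:
                raise ValueError(f"{spec_name} probabilities must sum to 1")
        for frac_name in (
            "multimap_fraction", "unannotated_fraction",
            "unmapped_fraction", "off_size_fraction",
        ):
            if not 0.0 <= getattr(self, frac_name) <= 1.0:
                raise ValueError(f"{frac_name} must be in [0, 1]")
        if self.library_depth <= 0 or self.replicates <= 0:
            raise ValueError("library_depth and replicates must be > 0")


@dataclass
class GroundTruthManifest:
    """Everything the generator knows that the pipeline must recover."""

    locus_classes: Dict[str, str] = field(default_factory=dict)
    locus_cluster_group: Dict[str, Optional[int]] = field(default_factory=dict)
    locus_sources: Dict[str, str] = field(default_factory=dict)
    pattern_labels: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    read_origins: Dict[str, Dict[str, str]] = field(default_factory=dict)

    def cluster_comates(self) -> Dict[str, FrozenSet[str]]:
        """miRNA -> the set of planted cluster companions (empty if unclustered)."""
        groups: Dict[int, List[str]] = {}
        for name, g in self.locus_cluster_group.items():
            if g is not None:
                groups.setdefault(g, []).append(name)
        out: Dict[str, FrozenSet[str]] = {}
        for name, g in self.locus_cluster_group.items():
            if g is None:
                out[name] = frozenset()
            else:
                out[name] = frozenset(m for m in groups[g] if m != name)
        return out


@dataclass
class SyntheticGenome:
    spec: SyntheticGenomeSpec
    genome: Dict[str, str]
    loci: List[MiRNALocus]  # retained, single-copy by construction
    decoy_loci: List[MiRNALocus]  # duplicated verbatim at >=2 positions
    decoy_placements: Dict[str, List[Tuple[str, int, str]]]
    redundant_loci: List[MiRNALocus]  # same locus under an alternative name
    genes: List[GeneModel]
    manifest: GroundTruthManifest
    background_pool: List[Tuple[str, int, str]]  # (chrom, pos, seq), 20-24 nt
    off_size_pool: List[Tuple[str, int]]  # gene-free positions for long reads
    alien_pool: List[str]  # verified non-genomic sequences
    index: GenomeIndex

    def source_catalogs(self) -> Dict[str, List[MiRNALocus]]:
        """Per-source catalogs as the consolidation stage receives them."""
        out: Dict[str, List[MiRNALocus]] = {s: [] for s in
                                            ("mirbase_v22", "aedes_ortholog",
                                             "prior_study", "candidate")}
        for locus in self.loci + self.decoy_loci + self.redundant_loci:
            out[locus.source].append(locus)
        for src in out:
            out[src].sort(key=lambda l: (l.chrom, l.start, l.name))
        return out

    def all_hairpin_loci(self) -> List[MiRNALocus]:
        return self.loci + self.decoy_loci


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=n)]).decode()


def _make_arms(h: int, arm_len: int) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    # 4-nt flanks leave room for +/-2 nt 3' length jitter inside the hairpin
    return (4, 4 + arm_len), (h - 4 - arm_len, h - 4)


class _Unit:
    """One placement request: a locus, a cluster, or one decoy copy."""

    def __init__(self, kind: str, width: int, payload: dict):
        self.kind = kind
        self.width = width
        self.payload = payload
        self.chrom: str = ""
        self.start: int = -1


def _plan_units(spec: SyntheticGenomeSpec, rng: np.random.Generator) -> List[_Unit]:
    units: List[_Unit] = []
    hp_lo, hp_hi = spec.hairpin_len_range

    def new_hairpin() -> Tuple[int, str]:
        h = int(rng.integers(hp_lo, hp_hi + 1))
        return h, _random_seq(rng, h)

    counts = dict(spec.n_mirnas_per_class)
    # clusters consume intronic / intergenic loci
    for ci, (size, intragenic) in enumerate(spec.clusters):
        members = [new_hairpin() for _ in range(size)]
        gaps = None
        if intragenic:
            counts["intronic"] -= size
            width = 150 + sum(150 + 100 + h + 100 + 150 for h, _ in members)
        else:
            counts["intergenic"] -= size
            gaps = [int(rng.integers(300, 8000)) for _ in range(size - 1)]
            width = sum(h for h, _ in members) + sum(gaps)
        units.append(
            _Unit(
                "intragenic_cluster" if intragenic else "intergenic_cluster",
                width,
                {"members": members, "group": ci, "gaps": gaps,
                 "strand": "+" if rng.random() < 0.5 else "-"},
            )
        )
    singles = []
    for cls in ("intergenic", "intronic", "conventional_miRTron",
                "tailed_3p_miRTron", "exonic"):
        singles += [cls] * counts.get(cls, 0)
    for cls in singles:
        h, seq = new_hairpin()
        strand = "+" if rng.random() < 0.5 else "-"
        if cls == "intergenic":
            width = h
        elif cls == "intronic":
            width = 150 + (100 + h + 100) + 150
        elif cls == "conventional_miRTron":
            width = 150 + h + 150
        elif cls == "tailed_3p_miRTron":
            width = 150 + (h + 50) + 150
        else:  # exonic
            width = (60 + h + 60) + 200 + 150
        units.append(_Unit("single", width, {"cls": cls, "h": h, "seq": seq,
                                             "strand": strand}))
    # decoys: one hairpin, two placements
    for source in sorted(spec.n_multimap_decoys):
        for di in range(spec.n_multimap_decoys[source]):
            h, seq = new_hairpin()
            key = f"{source}:{di}"
            for copy in range(2):
                units.append(
                    _Unit("decoy_copy", h,
                          {"decoy_key": key, "source": source, "h": h, "seq": seq,
                           "copy": copy, "strand": "+" if rng.random() < 0.5 else "-"})
                )
    order = rng.permutation(len(units))
    return [units[i] for i in order]


def _place_units(
    units: List[_Unit],
    chrom_lengths: Dict[str, int],
    rng: np.random.Generator,
    margin_base: int = 10_500,
) -> None:
    cursors = {c: 1_000 for c in chrom_lengths}
    for unit in units:
        margin = margin_base + int(rng.integers(0, 1_500))
        # deterministic choice: the chromosome with the most remaining room
        best = max(sorted(chrom_lengths),
                   key=lambda c: chrom_lengths[c] - cursors[c])
        start = cursors[best] + margin
        if start + unit.width + 1_000 > chrom_lengths[best]:
            raise PackingError(
                f"requested loci exceed capacity of chromosome {best!r} "
                f"({chrom_lengths[best]} bp)"
            )
        unit.chrom, unit.start = best, start
        cursors[best] = start + unit.width


def _free_intervals(
    chrom_lengths: Dict[str, int],
    occupied: Dict[str, List[Tuple[int, int]]],
    pad: int = 100,
) -> Dict[str, List[Tuple[int, int]]]:
    free: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, length in chrom_lengths.items():
        ivs = sorted(occupied.get(chrom, []))
        out = []
        cursor = 0
        for s, e in ivs:
            if s - pad > cursor:
                out.append((cursor, s - pad))
            cursor = max(cursor, e + pad)
        if cursor < length:
            out.append((cursor, length))
        free[chrom] = [iv for iv in out if iv[1] - iv[0] > 200]
    return free


def generate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Build the planted genome, gene models, catalogs and manifest.

    Every construction guarantee the manifest advertises is *verified* before
    returning: retained hairpins and their length-jittered arm windows occur
    exactly once in the genome and match no other hairpin within 2
    mismatches, decoy hairpins occur at exactly two positions, background
    reads map uniquely and annotate to nothing, alien reads do not map.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_plan, rng_seq, rng_assign, rng_pool = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    units = _plan_units(spec, rng_plan)
    _place_units(units, spec.chromosome_lengths, rng_plan)

    chrom_arrays = {
        c: _BASES[rng_seq.integers(0, 4, size=n)].copy()
        for c, n in spec.chromosome_lengths.items()
    }

    def patch(chrom: str, start: int, seq: str, strand: str) -> None:
        s = seq if strand == "+" else revcomp(seq)
        chrom_arrays[chrom][start : start + len(s)] = np.frombuffer(
            s.encode(), dtype=np.uint8
        )

    # materialise loci / genes from placed units -------------------------------
    planted: List[dict] = []  # retained loci, pre-naming
    genes: List[GeneModel] = []
    decoy_placed: Dict[str, List[Tuple[str, int, str, int, str]]] = {}
    gene_n = 0
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in spec.chromosome_lengths}

    def add_gene(chrom: str, strand: str, exons: List[Tuple[int, int]]) -> str:
        nonlocal gene_n
        gene_n += 1
        gid = f"gene{gene_n:04d}"
        genes.append(GeneModel(gid, chrom, strand, tuple(exons)))
        occupied[chrom].append((exons[0][0], exons[-1][1]))
        return gid

    for unit in units:
        c, s0 = unit.chrom, unit.start
        if unit.kind == "single":
            cls, h, seq, strand = (unit.payload[k] for k in ("cls", "h", "seq", "strand"))
            if cls == "intergenic":
                hp_start = s0
            elif cls == "intronic":
                add_gene(c, strand, [(s0, s0 + 150),
                                     (s0 + 150 + 100 + h + 100, s0 + 150 + 100 + h + 100 + 150)])
                hp_start = s0 + 150 + 100
            elif cls == "conventional_miRTron":
                add_gene(c, strand, [(s0, s0 + 150), (s0 + 150 + h, s0 + 150 + h + 150)])
                hp_start = s0 + 150
            elif cls == "tailed_3p_miRTron":
                intron = (s0 + 150, s0 + 150 + h + 50)
                add_gene(c, strand, [(s0, s0 + 150), (intron[1], intron[1] + 150)])
                # the hairpin 5' end sits at the intron's 5' splice site
                hp_start = intron[0] if strand == "+" else intron[1] - h
            else:  # exonic
                exon1 = (s0, s0 + 60 + h + 60)
                add_gene(c, strand, [exon1, (exon1[1] + 200, exon1[1] + 200 + 150)])
                hp_start = s0 + 60
            patch(c, hp_start, seq, strand)
            occupied[c].append((hp_start, hp_start + h))
            planted.append({"cls": cls, "chrom": c, "start": hp_start, "h": h,
                            "seq": seq, "strand": strand, "group": None})
        elif unit.kind == "intragenic_cluster":
            members, group = unit.payload["members"], unit.payload["group"]
            strand = unit.payload["strand"]
            exons = [(s0, s0 + 150)]
            cursor = s0 + 150
            for h, seq in members:
                hp_start = cursor + 100
                patch(c, hp_start, seq, strand)
                occupied[c].append((hp_start, hp_start + h))
                planted.append({"cls": "intronic", "chrom": c, "start": hp_start,
                                "h": h, "seq": seq, "strand": strand, "group": group})
                cursor = cursor + 100 + h + 100
                exons.append((cursor, cursor + 150))
                cursor += 150
            add_gene(c, strand, exons)
        elif unit.kind == "intergenic_cluster":
            members, group = unit.payload["members"], unit.payload["group"]
            gaps = unit.payload["gaps"] + [0]
            strand = unit.payload["strand"]
            cursor = s0
            for (h, seq), gap in zip(members, gaps):
                patch(c, cursor, seq, strand)
                occupied[c].append((cursor, cursor + h))
                planted.append({"cls": "intergenic", "chrom": c, "start": cursor,
                                "h": h, "seq": seq, "strand": strand, "group": group})
                cursor += h + gap
        elif unit.kind == "decoy_copy":
            h, seq, strand = (unit.payload[k] for k in ("h", "seq", "strand"))
            patch(c, s0, seq, strand)
            occupied[c].append((s0, s0 + h))
            decoy_placed.setdefault(unit.payload["decoy_key"], []).append(
                (c, s0, strand, h, seq)
            )

    # name + source assignment for retained loci -------------------------------
    planted.sort(key=lambda p: (p["chrom"], p["start"]))
    n = len(planted)
    source_counts = spec.source_counts or {"mirbase_v22": n}
    source_of: List[str] = []
    for src in ("mirbase_v22", "aedes_ortholog", "prior_study", "candidate"):
        source_of += [src] * source_counts.get(src, 0)
    source_of = [source_of[i] for i in rng_assign.permutation(n)]
    prefix = {"mirbase_v22": "aga-mir", "aedes_ortholog": "aae-mir",
              "prior_study": "pn-mir", "candidate": "cand-mir"}
    counters = {src: 0 for src in prefix}
    loci: List[MiRNALocus] = []
    manifest = GroundTruthManifest()
    for p, src in zip(planted, source_of):
        counters[src] += 1
        name = f"{prefix[src]}-{counters[src]:03d}"
        a5, a3 = _make_arms(p["h"], spec.arm_len)
        locus = MiRNALocus(name, src, p["chrom"], p["start"], p["start"] + p["h"],
                           p["strand"], p["seq"], a5, a3)
        loci.append(locus)
        manifest.locus_classes[name] = p["cls"]
        manifest.locus_cluster_group[name] = p["group"]
        manifest.locus_sources[name] = src

    decoy_loci: List[MiRNALocus] = []
    decoy_placements: Dict[str, List[Tuple[str, int, str]]] = {}
    for key in sorted(decoy_placed):
        placements = sorted(decoy_placed[key])
        src = key.split(":")[0]
        name = f"{'aga' if src == 'mirbase_v22' else 'pn'}-mm-{key.split(':')[1]}"
        c, s0, strand, h, seq = placements[0]
        a5, a3 = _make_arms(h, spec.arm_len)
        decoy_loci.append(MiRNALocus(name, src, c, s0, s0 + h, strand, seq, a5, a3))
        decoy_placements[name] = [(c, s, st) for c, s, st, _, _ in placements]

    redundant_loci: List[MiRNALocus] = []
    mirbase_retained = [l for l in loci if l.source == "mirbase_v22"]
    for i in range(spec.n_redundant_prior):
        twin = mirbase_retained[i]
        redundant_loci.append(replace(twin, name=f"pn-dup-{i+1:02d}", source="prior_study"))

    genome = {c: bytes(a).decode() for c, a in chrom_arrays.items()}

    # verification & fix-up ----------------------------------------------------
    def jitter_windows(locus: MiRNALocus) -> List[str]:
        out = []
        for arm in (locus.mature_5p, locus.mature_3p):
            for L in range(spec.arm_len - 2, spec.arm_len + 3):
                out.append(locus.hairpin_seq[arm[0] : arm[0] + L])
        return out

    for attempt in range(4):
        index = GenomeIndex(genome)
        catalog = HairpinCatalog(loci + decoy_loci)
        bad: List[str] = []
        for locus in loci:
            ws = [locus.hairpin_seq] + jitter_windows(locus)
            if any(len(index.lookup(w)) != 1 for w in ws):
                bad.append(locus.name)
                continue
            for w in jitter_windows(locus):
                hit = catalog.best_hit(w, max_mismatch=2)
                if hit is None or hit.mirna_name != locus.name or hit.mismatches != 0:
                    bad.append(locus.name)
                    break
        for locus in decoy_loci:
            ws = [locus.hairpin_seq] + jitter_windows(locus)
            if any(len(index.lookup(w)) != 2 for w in ws):
                bad.append(locus.name)
        if not bad:
            break
        # re-draw the offending hairpins in place and re-verify
        rng_fix = np.random.default_rng(ss.spawn(1)[0])
        by_name = {l.name: l for l in loci + decoy_loci}
        for name in set(bad):
            old = by_name[name]
            fresh = _random_seq(rng_fix, old.length)
            placements = decoy_placements.get(name, [(old.chrom, old.start, old.strand)])
            for c, s, st in placements:
                arr = np.frombuffer(genome[c].encode(), dtype=np.uint8).copy()
                piece = fresh if st == "+" else revcomp(fresh)
                arr[s : s + old.length] = np.frombuffer(piece.encode(), dtype=np.uint8)
                genome[c] = bytes(arr).decode()
            new_locus = replace(old, hairpin_seq=fresh)
            if name in decoy_placements:
                decoy_loci = [new_locus if l.name == name else l for l in decoy_loci]
            else:
                loci = [new_locus if l.name == name else l for l in loci]
                redundant_loci = [
                    replace(r, hairpin_seq=fresh) if (r.chrom, r.start) == (old.chrom, old.start) else r
                    for r in redundant_loci
                ]
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not construct collision-free hairpins")

    # background / off-size / alien pools --------------------------------------
    free = _free_intervals(spec.chromosome_lengths, occupied)
    flat = [(c, s, e) for c in sorted(free) for s, e in free[c]]
    weights = np.array([e - s for _, s, e in flat], dtype=float)
    weights /= weights.sum()

    def free_position(max_len: int) -> Tuple[str, int]:
        ci = int(rng_pool.choice(len(flat), p=weights))
        c, s, e = flat[ci]
        pos = int(rng_pool.integers(s, max(s + 1, e - max_len)))
        return c, pos

    background_pool: List[Tuple[str, int, str]] = []
    attempts = 0
    while len(background_pool) < spec.background_pool_size and attempts < 40 * spec.background_pool_size:
        attempts += 1
        L = int(rng_pool.integers(20, 25))
        c, pos = free_position(L)
        w = genome[c][pos : pos + L]
        if len(w) < L:
            continue
        if len(index.lookup(w)) != 1:
            continue
        if catalog.best_hit(w, max_mismatch=2) is not None:
            continue
        background_pool.append((c, pos, w))
    if len(background_pool) < spec.background_pool_size:  # pragma: no cover
        raise RuntimeError("could not build a clean background pool")

    off_size_pool = [free_position(50) for _ in range(spec.off_size_pool_size)]

    alien_pool: List[str] = []
    while len(alien_pool) < spec.alien_pool_size:
        w = _random_seq(rng_pool, int(rng_pool.integers(20, 25)))
        if len(index.lookup(w)) == 0:
            alien_pool.append(w)

    genes.sort(key=lambda g: (g.chrom, g.start))
    return SyntheticGenome(
        spec=spec, genome=genome, loci=loci, decoy_loci=decoy_loci,
        decoy_placements=decoy_placements, redundant_loci=redundant_loci,
        genes=genes, manifest=manifest, background_pool=background_pool,
        off_size_pool=off_size_pool, alien_pool=alien_pool,
        index=index,
    )


# ---------------------------------------------------------------------------
# expression-pattern design
# ---------------------------------------------------------------------------

PATTERN_LOG_VALUES = {
    "pan_high": 4.2,
    "pan_low": 1.2,
    "mid": 2.6,
    "enriched_target": 3.9,
    "enriched_other": 2.6,
    "excluded_target": 1.3,
    "excluded_other": 2.8,
}


def design_tissue_patterns(
    names: Sequence[str],
    tissues: Sequence[str] = DEFAULT_TISSUES,
    seed: int = 0,
    high: float = 3.5,
    low: float = 2.0,
    delta: float = 0.5,
) -> Tuple[pd.DataFrame, Dict[str, FrozenSet[str]]]:
    """Plant per-tissue target RPM so each tissue's targets sum to 1e6.

    Role allocation scales with catalog size: a handful of very abundant
    "filler" loci absorb the residual read mass per tissue (they come out
    pan-high, as the most abundant miRNAs in real libraries do), a pan-high
    and a pan-low block sit well clear of the 3.5 / 2.0 boundaries, and each
    tissue receives enriched and excluded loci with >=1.0 log10 margins
    (twice the 0.5 classification delta). Ground-truth labels are obtained
    by applying the classification rules to the exact planted values.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    names = list(names)
    n = len(names)
    n_fill = max(3, round(0.04 * n))
    n_high = max(2, round(0.06 * n))
    n_enr = max(1, round(0.02 * n))
    n_exc = max(1, round(0.02 * n))
    needed = n_fill + n_high + (n_enr + n_exc) * len(tissues)
    if needed > n:
        raise ValueError(f"need at least {needed} miRNAs for the planted patterns")
    order = [names[i] for i in rng.permutation(n)]
    it = iter(order)
    take = lambda k: [next(it) for _ in range(k)]
    fillers, pan_high = take(n_fill), take(n_high)
    enriched = {t: take(n_enr) for t in tissues}
    excluded = {t: take(n_exc) for t in tissues}
    rest = list(it)
    pan_low = rest[: max(1, int(0.7 * len(rest)))]
    mid = rest[len(pan_low):]

    V = PATTERN_LOG_VALUES
    logv = pd.DataFrame(np.nan, index=names, columns=list(tissues))
    logv.loc[pan_high, :] = V["pan_high"]
    logv.loc[pan_low, :] = V["pan_low"]
    logv.loc[mid, :] = V["mid"]
    for t in tissues:
        logv.loc[enriched[t], :] = V["enriched_other"]
        logv.loc[enriched[t], t] = V["enriched_target"]
    for t in tissues:
        logv.loc[excluded[t], :] = V["excluded_other"]
        logv.loc[excluded[t], t] = V["excluded_target"]
    rpm = 10.0 ** logv
    rpm.loc[fillers, :] = 0.0
    residual = 1e6 - rpm.sum(axis=0)
    if (residual <= 0).any():
        raise ValueError("planted non-filler mass exceeds 1e6 RPM")
    rpm.loc[fillers, :] = (residual / n_fill).values
    filler_log = np.log10(rpm.loc[fillers, :])
    assert float(filler_log.min().min()) >= high + 0.3
    assert float((filler_log.max(axis=1) - filler_log.min(axis=1)).max()) < delta / 2

    truth = {
        name: classify_tissue_pattern(
            np.log10(rpm.loc[name, :]).to_dict(), high, low, delta, name=name
        ).labels
        for name in names
    }
    return rpm, truth


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------


def default_tissue_profiles(
    targets: pd.DataFrame,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    replicates: int = 3,
    depth_scale: float = 1.0,
) -> List[TissueProfileSpec]:
    """Study-condition profiles: per-tissue depths, multi-mapping shares,
    6.5% unannotated and 0.4% unmappable reads."""
    profiles = []
    for t in tissues:
        d = TISSUE_DEFAULTS[t]
        sf_depth = max(1, int(d["size_filtered_depth"] * depth_scale))
        total = int(round(sf_depth / (1.0 - DEFAULT_OFF_SIZE_FRACTION)))
        profiles.append(
            TissueProfileSpec(
                tissue_name=t,
                replicates=replicates,
                planted_pattern=targets[t].to_dict(),
                off_size_spectrum=OFF_SIZE_SPECTRA[t],
                multimap_fraction=d["multimap_fraction"],
                library_depth=total,
            )
        )
    return profiles


def _integer_counts(
    total: int, probs: np.ndarray, rng: np.random.Generator, exact: bool
) -> np.ndarray:
    if not exact:
        return rng.multinomial(total, probs)
    raw = probs * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def simulate_library(
    profile: TissueProfileSpec,
    synth: SyntheticGenome,
    replicate: int,
    adapter: str = DEFAULT_ADAPTER,
    seed: int = 0,
    cycle_len: int = 50,
    exact: bool = False,
) -> Tuple[List[Tuple[str, str, str]], Dict[str, str]]:
    """Simulate one replicate library as (read_id, sequence, quality) records.

    Reads are mature-arm windows (3' length jitter per the length spectrum)
    with the 3' adapter appended and the whole read truncated to the cycle
    length; qualities are a constant Phred 'I'. The returned origin map
    records exactly one origin per emitted read, and the record count equals
    ``library_depth`` exactly.
    """
    if len(adapter) < 10:
        raise ValueError("adapter must be >= 10 nt")
    loci_by_name = {l.name: l for l in synth.loci}
    missing = [m for m in profile.planted_pattern if m not in loci_by_name]
    if missing:
        raise ValueError(f"planted miRNAs absent from locus set: {missing[:3]}")
    rng = np.random.default_rng(
        np.random.SeedSequence(
            (seed, zlib.crc32(profile.tissue_name.encode()), replicate)
        )
    )
    depth = profile.library_depth
    off_n = int(round(depth * profile.off_size_fraction))
    sized = depth - off_n
    unmapped_n = int(round(sized * profile.unmapped_fraction))
    mapped = sized - unmapped_n
    mm_n = int(round(mapped * profile.multimap_fraction))
    bg_n = int(round(mapped * profile.unannotated_fraction))
    annot_n = mapped - mm_n - bg_n

    lengths = sorted(profile.length_spectrum)
    len_p = np.array([profile.length_spectrum[L] for L in lengths])

    def arm_reads(locus: MiRNALocus, count: int) -> List[str]:
        if count == 0:
            return []
        n5 = int(round(count * profile.arm_bias_5p)) if not exact else int(
            round(count * profile.arm_bias_5p)
        )
        reads = []
        for arm_iv, k in ((locus.mature_5p, n5), (locus.mature_3p, count - n5)):
            if k <= 0:
                continue
            ls = rng.choice(lengths, size=k, p=len_p) if not exact else np.full(k, 22)
            for L in ls:
                reads.append(locus.hairpin_seq[arm_iv[0] : arm_iv[0] + int(L)])
        return reads

    inserts: List[str] = []
    origins: List[str] = []

    mirnas = sorted(profile.planted_pattern)
    targets = np.array([profile.planted_pattern[m] for m in mirnas], dtype=float)
    counts = _integer_counts(annot_n, targets / targets.sum(), rng, exact)
    for name, k in zip(mirnas, counts):
        rs = arm_reads(loci_by_name[name], int(k))
        inserts += rs
        origins += [name] * len(rs)

    if mm_n:
        decoys = synth.decoy_loci
        dcounts = _integer_counts(mm_n, np.full(len(decoys), 1.0 / len(decoys)), rng, exact)
        for locus, k in zip(decoys, dcounts):
            rs = arm_reads(locus, int(k))
            inserts += rs
            origins += [f"multimap:{locus.name}"] * len(rs)

    if bg_n:
        picks = rng.integers(0, len(synth.background_pool), size=bg_n)
        for i in picks:
            inserts.append(synth.background_pool[int(i)][2])
            origins.append("background")

    if unmapped_n:
        picks = rng.integers(0, len(synth.alien_pool), size=unmapped_n)
        for i in picks:
            inserts.append(synth.alien_pool[int(i)])
            origins.append("alien")

    if off_n:
        off_lengths = sorted(profile.off_size_spectrum)
        off_p = np.array([profile.off_size_spectrum[L] for L in off_lengths])
        ls = rng.choice(off_lengths, size=off_n, p=off_p)
        picks = rng.integers(0, len(synth.off_size_pool), size=off_n)
        for i, L in zip(picks, ls):
            c, pos = synth.off_size_pool[int(i)]
            inserts.append(synth.genome[c][pos : pos + int(L)])
            origins.append("offsize")

    assert len(inserts) == depth
    order = rng.permutation(depth)
    lib = f"{profile.tissue_name}_rep{replicate}"
    records: List[Tuple[str, str, str]] = []
    origin_map: Dict[str, str] = {}
    tail = adapter + POST_ADAPTER
    for serial, idx in enumerate(order):
        rid = f"{lib}:{serial:07d}"
        seq = (inserts[int(idx)] + tail)[:cycle_len]
        records.append((rid, seq, "I" * len(seq)))
        origin_map[rid] = origins[int(idx)]
    return records, origin_map


def simulate_expression_matrix(
    n_mirnas: int = 200,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    replicates: int = 3,
    depth: int = 1_000_000,
    seed: int = 0,
    noise: bool = True,
) -> Tuple[pd.DataFrame, Dict[str, str], Dict[str, FrozenSet[str]]]:
    """Planted-pattern count matrix without read-level simulation.

    Returns (counts, library -> tissue layout, truth labels). ``depth`` is
    the annotated-read total of each library; with ``noise`` the counts are
    multinomial draws, without it they are the exact expectations.
    """
    names = [f"mir-sim-{i:03d}" for i in range(n_mirnas)]
    targets, truth = design_tissue_patterns(names, tissues, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xE)))
    layout: Dict[str, str] = {}
    cols = {}
    for t in tissues:
        p = targets[t].values / targets[t].values.sum()
        for r in range(1, replicates + 1):
            lib = f"{t}|rep{r}"
            layout[lib] = t
            cols[lib] = _integer_counts(depth, p, rng, exact=not noise)
    counts = pd.DataFrame(cols, index=names)
    return counts, layout, truth
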