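"""Exact-match genome placement, mismatch-tolerant annotation, partition."""

import numpy as np
import pytest

from mirtissue.loci import MiRNALocus, revcomp
from mirtissue.mapping import (
    GenomeIndex,
    HairpinCatalog,
    annotate_read,
    map_read,
    mapping_rate,
    partition_library,
)
from mirtissue.synth import TissueProfileSpec, simulate_library


# -- independent oracles ----------------------------------------------------

def brute_force_placements(genome, query):
    """Scan every offset of every chromosome on both strands."""
    hits = []
    rc = revcomp(query)
    for chrom in sorted(genome):
        seq = genome[chrom]
        for i in range(len(seq) - len(query) + 1):
            w = seq[i : i + len(query)]
            if w == query:
                hits.append((chrom, i, "+"))
            if w == rc and rc != query:
                hits.append((chrom, i, "-"))
    return sorted(hits)


def brute_force_best_hit(read, hairpins, max_mismatch=2):
    """Exhaustive Hamming window scan; ties by (mismatch, order, offset)."""
    best = None
    for idx, (name, hp) in enumerate(hairpins):
        for off in range(len(hp) - len(read) + 1):
            w = hp[off : off + len(read)]
            mm = sum(a != b or a == "N" or b == "N" for a, b in zip(read, w))
            key = (mm, idx, off)
            if mm <= max_mismatch and (best is None or key < best):
                best = key
    if best is None:
        return None
    return hairpins[best[1]][0], best[0], best[2]


def _random_genome(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


# -- genome placement -------------------------------------------------------

def test_index_lookup_equals_brute_force_on_toy_genome(rng):
    genome = {"c1": _random_genome(rng, 600), "c2": _random_genome(rng, 400)}
    index = GenomeIndex(genome)
    for _ in range(200):
        L = int(rng.integers(15, 25))  # includes lengths below the seed size
        if rng.random() < 0.7:
            chrom = "c1" if rng.random() < 0.6 else "c2"
            pos = int(rng.integers(0, len(genome[chrom]) - L))
            query = genome[chrom][pos : pos + L]
            if rng.random() < 0.5:
                query = revcomp(query)
        else:
            query = _random_genome(rng, L)
        assert index.lookup(query) == brute_force_placements(genome, query)


def test_planted_copy_number_drives_multiplicity(rng):
    unit = _random_genome(rng, 80)
    genome = {"c1": _random_genome(rng, 300) + unit + _random_genome(rng, 300),
              "c2": unit + _random_genome(rng, 200)}
    index = GenomeIndex(genome)
    read = unit[10:32]
    assert map_read("r", read, index).multiplicity == 2
    single = genome["c1"][50:72]
    assert map_read("r", single, index).multiplicity == 1


def test_read_with_n_never_maps(rng):
    genome = {"c1": _random_genome(rng, 500)}
    index = GenomeIndex(genome)
    read = genome["c1"][100:122]
    assert index.lookup(read[:-1] + "N") == []


# -- annotation -------------------------------------------------------------

def _catalog_from(seqs):
    loci = [
        MiRNALocus(f"h{i}", "mirbase_v22", "cX", 1000 * i, 1000 * i + len(s),
                   "+", s, (4, 26), (len(s) - 26, len(s) - 4))
        for i, s in enumerate(seqs)
    ]
    return HairpinCatalog(loci), [(l.name, l.hairpin_seq) for l in loci]


def _mutate(rng, seq, k):
    s = list(seq)
    for pos in rng.choice(len(s), size=k, replace=False):
        s[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
    return "".join(s)


def test_annotation_equals_exhaustive_window_scan(rng):
    hairpins = [_random_genome(rng, 80) for _ in range(10)]
    catalog, pairs = _catalog_from(hairpins)
    for _ in range(150):
        L = int(rng.integers(20, 25))
        if rng.random() < 0.7:
            hp = hairpins[int(rng.integers(len(hairpins)))]
            off = int(rng.integers(0, len(hp) - L))
            read = _mutate(rng, hp[off : off + L], int(rng.integers(0, 4)))
        else:
            read = _random_genome(rng, L)
        hit = annotate_read(read, catalog)
        oracle = brute_force_best_hit(read, pairs)
        if oracle is None:
            assert hit is None
        else:
            assert (hit.mirna_name, hit.mismatches, hit.offset) == oracle


def test_best_hit_prefers_fewer_mismatches(rng):
    h1, h2 = _random_genome(rng, 80), _random_genome(rng, 80)
    catalog, _ = _catalog_from([h1, h2])
    # 1 mismatch against h1's window; h2 offers nothing within 2 mismatches
    window = h1[20:42]
    read = _mutate(rng, window, 1)
    hit = catalog.best_hit(read)
    assert hit.mirna_name == "h0" and hit.mismatches == 1


def test_three_mismatches_is_unannotated(rng):
    hp = _random_genome(rng, 80)
    catalog, pairs = _catalog_from([hp])
    read = _mutate(rng, hp[10:32], 3)
    assert annotate_read(read, catalog) is None
    assert brute_force_best_hit(read, pairs) is None


def test_catalog_order_irrelevant_for_distinct_distances(rng):
    hairpins = [_random_genome(rng, 80) for _ in range(6)]
    cat_a, _ = _catalog_from(hairpins)
    cat_b, _ = _catalog_from(hairpins[::-1])
    read = _mutate(rng, hairpins[2][15:37], 1)
    ha, hb = cat_a.best_hit(read), cat_b.best_hit(read)
    assert ha.mismatches == hb.mismatches == 1
    assert cat_a.loci[[l.name for l in cat_a.loci].index(ha.mirna_name)].hairpin_seq \
        == cat_b.loci[[l.name for l in cat_b.loci].index(hb.mirna_name)].hairpin_seq


def test_exact_tie_breaks_by_catalog_order_then_offset(rng):
    shared = _random_genome(rng, 22)
    h1 = _random_genome(rng, 20) + shared + _random_genome(rng, 38)
    h2 = shared + _random_genome(rng, 58)
    catalog, _ = _catalog_from([h1, h2])
    hit = catalog.best_hit(shared)
    assert (hit.mirna_name, hit.offset, hit.mismatches) == ("h0", 20, 0)


def test_read_with_n_mismatches_every_window(rng):
    hp = _random_genome(rng, 80)
    catalog, _ = _catalog_from([hp])
    read = hp[10:32]
    assert catalog.best_hit(read).mismatches == 0
    noisy = "NNN" + read[3:]
    hit = catalog.best_hit(noisy)
    assert hit is None  # 3 N positions exceed the 2-mismatch budget


def test_arm_attribution_by_midpoint(rng):
    hp = _random_genome(rng, 80)
    catalog, _ = _catalog_from([hp])
    assert catalog.best_hit(hp[4:26]).arm == "5p"
    assert catalog.best_hit(hp[54:76]).arm == "3p"
    assert catalog.best_hit(hp[30:52]).arm is None  # loop region


# -- partition --------------------------------------------------------------

def _simulate(small_genome, **overrides):
    targets = {l.name: 1e6 / len(small_genome.loci) for l in small_genome.loci}
    kwargs = dict(
        tissue_name="midgut", replicates=1, planted_pattern=targets,
        multimap_fraction=0.25, off_size_fraction=0.1, library_depth=20_000,
    )
    kwargs.update(overrides)
    profile = TissueProfileSpec(**kwargs)
    return simulate_library(profile, small_genome, 1, seed=5)


def test_partition_assignment_matches_manifest(small_genome):
    records, origins = _simulate(small_genome)
    catalog = HairpinCatalog(small_genome.loci)
    reads = [(rid, seq) for rid, seq, _ in records]
    from mirtissue.reads import trim_reads
    trimmed = trim_reads((s for _, s in reads), "TGGAATTCTCGGGTGCCAAGG")
    kept = [(rid, t) for (rid, _), t in zip(reads, trimmed) if 20 <= len(t) <= 24]
    part = partition_library(kept, small_genome.index, catalog, library="t")
    part.check_conservation()
    expected = {"background": "unannotated", "alien": "unmapped"}
    for rid, cls in part.read_classes.items():
        origin = origins[rid]
        if origin == "offsize":
            continue
        want = expected.get(origin,
                            "multimapping" if origin.startswith("multimap:") else "annotated")
        assert cls == want
    assert 0.99 <= mapping_rate(part) <= 1.0


def test_no_duplicated_loci_means_no_multimapping_reads(small_genome):
    records, _ = _simulate(small_genome, multimap_fraction=0.0,
                           unannotated_fraction=0.0, unmapped_fraction=0.0,
                           off_size_fraction=0.0, library_depth=5_000)
    catalog = HairpinCatalog(small_genome.loci)
    # reads still carry adapter tails -> trim first
    from mirtissue.reads import trim_reads
    trimmed = trim_reads((s for _, s, _ in records), "TGGAATTCTCGGGTGCCAAGG")
    kept = [(r[0], t) for r, t in zip(records, trimmed) if 20 <= len(t) <= 24]
    part = partition_library(kept, small_genome.index, catalog, library="t")
    assert part.multimapping_count == 0
    assert part.unannotated_count == 0
    assert part.unmapped_count == 0
    assert part.annotated_count == part.all_count == len(kept)


def test_multimapping_reads_never_reach_expression_counts(small_genome):
    records, origins = _simulate(small_genome)
    from mirtissue.reads import trim_reads
    trimmed = trim_reads((s for _, s, _ in records), "TGGAATTCTCGGGTGCCAAGG")
    kept = [(r[0], t) for r, t in zip(records, trimmed) if 20 <= len(t) <= 24]
    part = partition_library(kept, small_genome.index,
                             HairpinCatalog(small_genome.loci), library="t")
    assert sum(part.mirna_counts.values()) == part.annotated_count
    decoy_names = {l.name for l in small_genome.decoy_loci}
    assert not decoy_names & set(part.mirna_counts)
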