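"""Synthetic genome/library generator: construction guarantees, determinism."""

import numpy as np
import pytest

from mirtissue.loci import revcomp
from mirtissue.synth import (
    PackingError,
    SyntheticGenomeSpec,
    TissueProfileSpec,
    design_tissue_patterns,
    generate_genome,
    simulate_expression_matrix,
    simulate_library,
)


def test_spec_validation():
    with pytest.raises(ValueError):
        SyntheticGenomeSpec({"c": 0}, {"intergenic": 1})
    with pytest.raises(ValueError):
        SyntheticGenomeSpec({"c": 10_000}, {"intergenic": -1})
    with pytest.raises(ValueError):
        SyntheticGenomeSpec({"c": 100_000}, {"intergenic": 5},
                            clusters=((3, True),))  # no intronic loci to consume
    with pytest.raises(ValueError):
        SyntheticGenomeSpec({"c": 100_000}, {"intergenic": 2},
                            hairpin_len_range=(30, 50))


def test_infeasible_packing_names_the_chromosome():
    spec = SyntheticGenomeSpec({"tiny": 30_000}, {"intergenic": 10})
    with pytest.raises(PackingError, match="tiny"):
        generate_genome(spec)


def test_generation_is_reproducible_bytewise(tmp_path):
    from mirtissue import io as mio

    spec = SyntheticGenomeSpec(
        {"c1": 150_000}, {"intergenic": 4, "intronic": 2},
        background_pool_size=50, off_size_pool_size=20, seed=42,
    )
    a, b = generate_genome(spec), generate_genome(spec)
    assert a.genome == b.genome
    assert a.loci == b.loci
    assert a.background_pool == b.background_pool
    for g, sub in ((a, "a"), (b, "b")):
        d = tmp_path / sub
        d.mkdir()
        mio.write_fasta(g.genome, d / "genome.fasta")
        mio.write_gff3(g.genes, d / "genes.gff3")
        mio.write_catalog(g.loci, d / "catalog")
    for name in ("genome.fasta", "genes.gff3", "catalog.bed", "catalog.fasta"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_no_duplication_requested_means_single_occurrences(small_genome):
    # every retained hairpin occurs exactly once (strand-aware search)
    for locus in small_genome.loci:
        occ = sum(
            g.count(locus.hairpin_seq) + g.count(revcomp(locus.hairpin_seq))
            for g in small_genome.genome.values()
        )
        assert occ == 1


def test_decoys_are_byte_identical_at_two_positions(small_genome):
    for locus in small_genome.decoy_loci:
        placements = small_genome.decoy_placements[locus.name]
        assert len(placements) == 2
        seqs = []
        for chrom, start, strand in placements:
            s = small_genome.genome[chrom][start : start + locus.length]
            seqs.append(s if strand == "+" else revcomp(s))
        assert seqs[0] == seqs[1] == locus.hairpin_seq


def test_conventional_mirtron_spans_an_entire_intron(small_genome):
    genes = {g.gene_id: g for g in small_genome.genes}
    found = 0
    ann = small_genome.manifest.locus_classes
    for locus in small_genome.loci:
        if ann[locus.name] != "conventional_miRTron":
            continue
        found += 1
        host = next(g for g in genes.values()
                    if g.chrom == locus.chrom and g.start <= locus.start < g.end)
        assert (locus.start, locus.end) in host.introns
        assert host.strand == locus.strand
    assert found >= 2


def test_planted_hairpins_do_not_overlap_each_other(small_genome):
    by_chrom = {}
    for locus in small_genome.loci + small_genome.decoy_loci:
        by_chrom.setdefault(locus.chrom, []).append((locus.start, locus.end))
    for ivs in by_chrom.values():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2


# -- library simulation -----------------------------------------------------

def _flat_targets(genome):
    return {l.name: 1e6 / len(genome.loci) for l in genome.loci}


def test_library_depth_is_conserved_exactly(small_genome):
    profile = TissueProfileSpec("midgut", 1, _flat_targets(small_genome),
                                library_depth=9_973)
    records, origins = simulate_library(profile, small_genome, 1, seed=3)
    assert len(records) == 9_973
    assert len(origins) == 9_973  # exactly one origin per emitted read
    assert {rid for rid, _, _ in records} == set(origins)


def test_library_simulation_is_reproducible(small_genome):
    profile = TissueProfileSpec("ovary", 1, _flat_targets(small_genome),
                                library_depth=4_000)
    a = simulate_library(profile, small_genome, 1, seed=8)
    b = simulate_library(profile, small_genome, 1, seed=8)
    assert a == b
    c = simulate_library(profile, small_genome, 2, seed=8)
    assert c != a  # replicates draw different reads


def test_planted_count_is_within_three_binomial_sd(small_genome):
    targets = _flat_targets(small_genome)
    # put one miRNA at 500 RPM, renormalise the rest
    star = small_genome.loci[0].name
    others = {k: v for k, v in targets.items() if k != star}
    scale = (1e6 - 500) / sum(others.values())
    targets = {star: 500.0, **{k: v * scale for k, v in others.items()}}
    profile = TissueProfileSpec(
        "midgut", 1, targets, multimap_fraction=0.0, unannotated_fraction=0.0,
        unmapped_fraction=0.0, off_size_fraction=0.0, library_depth=400_000,
    )
    records, origins = simulate_library(profile, small_genome, 1, seed=21)
    n = sum(1 for o in origins.values() if o == star)
    p = 500e-6
    expected = 400_000 * p
    sd = np.sqrt(400_000 * p * (1 - p))
    assert abs(n - expected) <= 3 * sd


def test_reads_are_arm_windows_with_adapter(small_genome):
    profile = TissueProfileSpec(
        "midgut", 1, _flat_targets(small_genome), multimap_fraction=0.0,
        unannotated_fraction=0.0, unmapped_fraction=0.0, off_size_fraction=0.0,
        library_depth=500,
    )
    records, origins = simulate_library(profile, small_genome, 1, seed=4)
    by_name = {l.name: l for l in small_genome.loci}
    from mirtissue.synth import POST_ADAPTER

    tail = "TGGAATTCTCGGGTGCCAAGG" + POST_ADAPTER
    for rid, seq, qual in records:
        assert len(seq) == 50 and qual == "I" * 50
        locus = by_name[origins[rid]]
        # insert must be a hairpin window starting at one of the arm starts
        matched = False
        for arm in (locus.mature_5p, locus.mature_3p):
            for L in range(20, 25):
                insert = locus.hairpin_seq[arm[0] : arm[0] + L]
                if seq == (insert + tail)[:50]:
                    matched = True
        assert matched


def test_empty_pattern_and_short_adapter_raise(small_genome):
    with pytest.raises(ValueError):
        TissueProfileSpec("t", 1, {})
    profile = TissueProfileSpec("t", 1, _flat_targets(small_genome),
                                library_depth=100)
    with pytest.raises(ValueError):
        simulate_library(profile, small_genome, 1, adapter="ACGT")
    with pytest.raises(ValueError):
        TissueProfileSpec("t", 1, {"x": 1.0}, length_spectrum={20: 0.5, 22: 0.4})
    with pytest.raises(ValueError):
        TissueProfileSpec("t", 1, {"x": 1.0}, multimap_fraction=1.2)


# -- planted expression patterns --------------------------------------------

def test_pattern_targets_sum_to_one_million_per_tissue():
    names = [f"m{i}" for i in range(60)]
    targets, truth = design_tissue_patterns(names, seed=5)
    assert np.allclose(targets.sum(axis=0), 1e6)
    assert set(truth) == set(names)
    all_labels = set().union(*truth.values())
    assert any(l == "pan_high" for l in all_labels)
    assert any(l == "pan_low" for l in all_labels)
    assert any(l.startswith("enriched:") for l in all_labels)
    assert any(l.startswith("excluded:") for l in all_labels)


def test_expression_matrix_shapes_and_truth():
    counts, layout, truth = simulate_expression_matrix(
        n_mirnas=50, replicates=2, depth=100_000, seed=3
    )
    assert counts.shape == (50, 8)
    assert all(counts.sum(axis=0) == 100_000)
    assert set(layout.values()) == {"fat_body", "midgut", "ovary", "remainder"}
    assert len(truth) == 50
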