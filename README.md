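# mirtissue

Tissue-level small-RNA/miRNA transcriptome analysis for mosquito genomes,
built as a fully tested pipeline over synthetic data with known ground
truth. The package is aimed at vector-biology and small-RNA researchers who
want the complete analytical chain of a tissue miRNA atlas — from raw
single-end small-RNA FASTQ to tissue expression-pattern calls — as
reusable, oracle-checked library code rather than a one-off workbench
session.

## What it computes

**Read processing.** 50-cycle reads are trimmed of the 3' adapter
(leftmost alignment with ≥3-nt overlap and ≤10% mismatches) and
size-selected to the miRNA window, 20–24 nt inclusive.

**Four-way partition.** Size-filtered reads are placed on the genome by
exact match on both strands. A read with one placement is *unique*, with
two or more *multi-mapping* (tallied, then removed from all quantification,
as is standard for miRNA studies). Unique reads are annotated against the
hairpin catalog by minimum Hamming distance over every same-length hairpin
window, allowing up to 2 mismatches; the rest are *unannotated*. In every
library

    annotated + multi-mapping + unannotated = mapped size-filtered reads

holds exactly.

**Catalog consolidation.** Four tagged sources (miRBase-style entries,
*Aedes* orthologs, prior-study miRNAs, fresh candidates) are unioned; loci
whose hairpin or mature arm has ≥2 perfect genomic placements are removed,
and redundant names are collapsed with source precedence
`mirbase_v22 > aedes_ortholog > prior_study > candidate`.

**Candidate vetting.** A candidate pre-miRNA passes iff (1) its folded
minimum free energy is ≤ −30 kcal/mol (ViennaRNA backend by default),
(2) the star arm (the lower-read arm) has ≥1 read, and (3) the folded
5p/3p duplex leaves ≥2-nt 3' overhangs — the Drosha/Dicer signature.

**Genome architecture.** Each miRNA is intergenic or intragenic; intragenic
loci subdivide into intronic, conventional miRTron (hairpin = entire
intron), 3'-tailed miRTron (5' end flush with the 5' splice site, intronic
3' tail) and exonic. Loci within 10 kb (edge-to-edge, chained transitively)
form clusters. A plot-ready genome map is exported at 10,000 bp per unit,
plus strand right / minus strand left.

**Expression.** Annotated counts are normalised to reads per million,
RPM = count × 10⁶ / (library annotated total), averaged across replicates
per tissue, then log₁₀-transformed (pseudocount 1). Tissue patterns follow
four threshold rules on log₁₀ mean RPM: pan-tissue high (all tissues
≥ 3.5), pan-tissue low (all ≤ 2.0), tissue exclusion (second-lowest −
lowest ≥ 0.5) and tissue enrichment (highest − second-highest ≥ 0.5).
UPGMA clustering (Euclidean metric) over both axes, centred unscaled
SVD-PCA of libraries, chromosome contribution profiles, top-20 rankings,
row-wise min–max scaling for cluster co-expression, and the 2^−ΔCt qPCR
utility round out the stage.

**Synthetic data.** `mirtissue.synth` generates a six-chromosome
mini-genome with planted hairpins of every architecture class, ≤10-kb
clusters, verbatim-duplicated multi-mapping decoys, redundantly named
catalog entries, and per-tissue replicate libraries whose per-miRNA
abundances follow planted pattern labels — every read's origin is recorded
in a manifest, so recovery can be scored exactly.

## Worked example

```bash
python analysis/01_simulate_study.py --seed 1 --depth-scale 0.25
python analysis/03_map_partition.py
python analysis/04_consolidate_catalog.py
python analysis/06_genome_architecture.py
```

The consolidation step prints:

```
input entries: 185
retained unique miRNAs: 139
removed multi-mapping: 38
removed redundant names: 8
```

i.e. of 185 tagged input entries, 38 were discarded because their hairpin
or mature arm occurs at more than one genomic position (26 of the
miRBase-style source, 12 of the prior-study source), 8 prior-study names
duplicated retained miRBase loci, and 139 unique miRNAs remain. The
architecture step then prints:

```
64.0% of miRNAs are intergenic, 36.0% intragenic
of the intragenic miRNAs: 88.0% intronic, 6.0% conventional miRTrons,
4.0% 3' tailed miRTrons, 2.0% exonic
37.4% of miRNAs reside in 16 clusters; 42.3% of clustered miRNAs are intragenic
```

which is exactly the planted composition — the classifier and cluster
chaining recover the generator's ground truth locus for locus
(`analysis/08_validate_recovery.py` scores this at 100% for partition
classes, architecture classes and cluster co-membership). Per-library
partition percentages land on the planted per-tissue study conditions,
e.g. multi-mapping shares of 26.2% (fat body), 41.8% (midgut), 36.6%
(ovary) and 68.6% (remainder) at a 99.6% mapping rate.

## Command line

A thin CLI mirrors the stages: `mirtissue simulate | trim | sizefilter |
partition | vet | run | validate` (see `mirtissue --help`). All
intermediate files are plain FASTA/FASTQ/BED/GFF3/TSV so any stage can be
run standalone.
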