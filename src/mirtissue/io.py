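"""Readers/writers for the plain-text interchange formats of the pipeline.

FASTA/FASTQ go through Biopython (pyfaidx for genome access), GFF3 parsing
through gffutils; BED and all tabular outputs are TSV handled with pandas.
Coordinates on disk follow the usual conventions: BED is 0-based half-open,
GFF3 1-based inclusive.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from pyfaidx import Fasta

from .loci import GeneModel, MiRNALocus, revcomp
from .synth import GroundTruthManifest

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


# -- FASTA ------------------------------------------------------------------

def write_fasta(seqs: Dict[str, str], path: Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_genome(path: Path) -> Dict[str, str]:
    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


# -- FASTQ ------------------------------------------------------------------

def write_fastq(records: Iterable[Tuple[str, str, str]], path: Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: Path) -> List[Tuple[str, str]]:
    with open(path) as fh:
        return [(rid.split()[0], seq) for rid, seq, _ in FastqGeneralIterator(fh)]


# -- BED / catalogs ---------------------------------------------------------

def write_bed(df: pd.DataFrame, path: Path) -> None:
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)


def _arm_genomic(locus: MiRNALocus, arm: Tuple[int, int]) -> Tuple[int, int]:
    if locus.strand == "+":
        return locus.start + arm[0], locus.start + arm[1]
    return locus.end - arm[1], locus.end - arm[0]


def write_catalog(loci: Sequence[MiRNALocus], prefix: Path) -> None:
    """Write one catalog as <prefix>.fasta / .bed / .mature.bed / .tsv.

    The FASTA holds hairpin sequences (hairpin strand); the main BED the
    hairpin intervals; the mature BED one line per arm named ``mirna|arm``.
    The TSV carries source tags and hairpin-relative arm intervals so a
    catalog round-trips losslessly.
    """
    prefix = Path(prefix)
    write_fasta({l.name: l.hairpin_seq for l in loci}, prefix.with_suffix(".fasta"))
    rows = [
        {"chrom": l.chrom, "start": l.start, "end": l.end,
         "name": l.name, "score": 0, "strand": l.strand}
        for l in loci
    ]
    write_bed(pd.DataFrame(rows, columns=BED6_COLUMNS), prefix.with_suffix(".bed"))
    arm_rows = []
    meta_rows = []
    for l in loci:
        meta = {"name": l.name, "source": l.source}
        for arm_name, arm in (("5p", l.mature_5p), ("3p", l.mature_3p)):
            if arm is None:
                meta[f"{arm_name}_start"], meta[f"{arm_name}_end"] = -1, -1
                continue
            g = _arm_genomic(l, arm)
            arm_rows.append({"chrom": l.chrom, "start": g[0], "end": g[1],
                             "name": f"{l.name}|{arm_name}", "score": 0,
                             "strand": l.strand})
            meta[f"{arm_name}_start"], meta[f"{arm_name}_end"] = arm
        meta_rows.append(meta)
    write_bed(pd.DataFrame(arm_rows, columns=BED6_COLUMNS),
              prefix.with_suffix(".mature.bed"))
    pd.DataFrame(meta_rows).to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)


def read_catalog(prefix: Path) -> List[MiRNALocus]:
    prefix = Path(prefix)
    seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(prefix.with_suffix(".fasta")), "fasta")}
    bed = read_bed(prefix.with_suffix(".bed")).set_index("name")
    meta = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t").set_index("name")
    loci = []
    for name, row in bed.iterrows():
        m = meta.loc[name]
        arm = lambda a: (
            None
            if int(m[f"{a}_start"]) < 0
            else (int(m[f"{a}_start"]), int(m[f"{a}_end"]))
        )
        loci.append(
            MiRNALocus(name, str(m["source"]), row["chrom"], int(row["start"]),
                       int(row["end"]), row["strand"], seqs[name],
                       arm("5p"), arm("3p"))
        )
    loci.sort(key=lambda l: (l.chrom, l.start, l.name))
    return loci


# -- GFF3 -------------------------------------------------------------------

def write_gff3(genes: Sequence[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tmirtissue\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tmirtissue\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tmirtissue\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}.t1\n"
                )


def read_gff3(path: Path) -> List[GeneModel]:
    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    for gene in db.features_of_type("gene"):
        exons = []
        for mrna in db.children(gene, featuretype="mRNA"):
            for exon in db.children(mrna, featuretype="exon"):
                exons.append((exon.start - 1, exon.end))
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand, tuple(sorted(set(exons)))))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


# -- manifest ---------------------------------------------------------------

def write_manifest(manifest: GroundTruthManifest, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "name": name,
            "arch_class": manifest.locus_classes[name],
            "cluster_group": (
                "" if manifest.locus_cluster_group.get(name) is None
                else manifest.locus_cluster_group[name]
            ),
            "source": manifest.locus_sources.get(name, ""),
            "pattern_labels": ";".join(sorted(manifest.pattern_labels.get(name, ()))),
        }
        for name in sorted(manifest.locus_classes)
    ]
    pd.DataFrame(rows).to_csv(outdir / "manifest_loci.tsv", sep="\t", index=False)
    for lib in sorted(manifest.read_origins):
        origins = manifest.read_origins[lib]
        with open(outdir / f"manifest_reads.{lib}.tsv", "w") as fh:
            fh.write("read_id\torigin\n")
            for rid in sorted(origins):
                fh.write(f"{rid}\t{origins[rid]}\n")


def read_manifest(outdir: Path) -> GroundTruthManifest:
    outdir = Path(outdir)
    m = GroundTruthManifest()
    df = pd.read_csv(outdir / "manifest_loci.tsv", sep="\t", keep_default_na=False)
    for _, row in df.iterrows():
        name = row["name"]
        m.locus_classes[name] = row["arch_class"]
        m.locus_cluster_group[name] = (
            None if row["cluster_group"] == "" else int(row["cluster_group"])
        )
        m.locus_sources[name] = row["source"]
        labels = str(row["pattern_labels"])
        m.pattern_labels[name] = frozenset(x for x in labels.split(";") if x)
    for path in sorted(outdir.glob("manifest_reads.*.tsv")):
        lib = path.name[len("manifest_reads."):-len(".tsv")]
        reads = pd.read_csv(path, sep="\t")
        m.read_origins[lib] = dict(zip(reads["read_id"], reads["origin"]))
    return m


def write_read_classes(partition, path: Path) -> None:
    """Per-read class assignment as TSV (read_id, class)."""
    with open(path, "w") as fh:
        fh.write("read_id\tclass\n")
        for rid in sorted(partition.read_classes):
            fh.write(f"{rid}\t{partition.read_classes[rid]}\n")


# -- generic TSV with commented header --------------------------------------

def write_table(df: pd.DataFrame, path: Path, comment: Optional[str] = None,
                index: bool = True) -> None:
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
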