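#!/usr/bin/env python
"""Consolidate the miRNA catalog from its four tagged annotation sources.

Unions the miRBase-style, Aedes-ortholog, prior-study and fresh-candidate
catalogs, removes loci whose hairpin or mature arm has multiple perfect
genomic placements, collapses redundant names by source precedence, and
writes the consolidated catalog plus a per-removal report to results/.
"""

from pathlib import Path

import pandas as pd

from mirtissue import io as mio
from mirtissue.catalog import consolidate
from mirtissue.config import AnalysisConfig
from mirtissue.mapping import GenomeIndex

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"
SOURCES = ("mirbase_v22", "aedes_ortholog", "prior_study", "candidate")


def main() -> None:
    if not STUDY.exists():
        raise SystemExit("run analysis/01_simulate_study.py first")
    config = AnalysisConfig.from_yaml(STUDY.parent / "config.yaml")
    RESULTS.mkdir(exist_ok=True)

    index = GenomeIndex(mio.read_genome(STUDY / "genome.fasta"))
    sources = [mio.read_catalog(STUDY / f"catalog_{s}") for s in SOURCES
               if (STUDY / f"catalog_{s}.bed").exists()]
    report = consolidate(sources, index, config.min_reciprocal_overlap)

    mio.write_catalog(report.retained, RESULTS / "catalog_consolidated")
    removals = pd.DataFrame(
        [{"name": l.name, "source": l.source, "reason": r}
         for l, r in report.removed]
    )
    removals.to_csv(RESULTS / "catalog_removals.tsv", sep="\t", index=False)
    by_source = pd.DataFrame(report.counts_by_source()).T.fillna(0).astype(int)
    by_source.to_csv(RESULTS / "catalog_by_source.tsv", sep="\t")

    print(f"input entries: {len(report.retained) + len(report.removed)}")
    print(f"retained unique miRNAs: {len(report.retained)}")
    print(f"removed multi-mapping: {len(report.removed_by_reason('multi-mapping'))}")
    print(f"removed redundant names: {len(report.removed_by_reason('redundant-name'))}")
    print("\nper source:")
    print(by_source.to_string())


if __name__ == "__main__":
    main()
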