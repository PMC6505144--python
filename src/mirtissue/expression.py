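"""miRNA quantification and tissue expression-pattern analysis.

Counts of annotated reads are normalised to reads per million (RPM) against
each library's annotated-read total, averaged across biological replicates
per tissue, and log10-transformed (average first, then log, pseudocount for
zeros). Tissue patterns follow four threshold rules on log10 mean RPM:

* pan-tissue high  — every tissue >= 3.5
* pan-tissue low   — every tissue <= 2.0
* exclusion(t_min) — (2nd lowest - lowest) >= 0.5
* enrichment(t_max)— (highest - 2nd highest) >= 0.5

The axes are non-exclusive: a miRNA can be pan-high and tissue-enriched at
once (only pan-high/pan-low are mutually exclusive when high > low).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.decomposition import PCA as _SKPCA


def compute_rpm(counts: pd.DataFrame, library_totals: Optional[pd.Series] = None) -> pd.DataFrame:
    """counts (miRNA x library) -> RPM against each library's annotated total.

    When ``library_totals`` is omitted the column sums are used (i.e. all
    annotated reads are attributed to some miRNA, and each RPM column sums to
    1e6 exactly).
    """
    if library_totals is None:
        library_totals = counts.sum(axis=0)
    library_totals = library_totals.reindex(counts.columns)
    if (library_totals <= 0).any() or library_totals.isna().any():
        bad = library_totals.index[(library_totals <= 0) | library_totals.isna()]
        raise ValueError(f"non-positive annotated totals for libraries: {list(bad)}")
    return counts * 1e6 / library_totals


def tissue_means(
    rpm: pd.DataFrame, library_tissue: Mapping[str, str]
) -> pd.DataFrame:
    """Average RPM across replicate libraries of each tissue."""
    groups = pd.Series({lib: library_tissue[lib] for lib in rpm.columns})
    means = rpm.T.groupby(groups).mean().T
    return means[sorted(means.columns, key=list(dict.fromkeys(library_tissue.values())).index)]


def log_transform(means: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log10(mean RPM + pseudocount); the mean is taken *before* the log."""
    if pseudocount <= 0 and (means <= 0).any().any():
        raise ValueError("pseudocount must be positive when zero means are present")
    return np.log10(means + pseudocount)


@dataclass(frozen=True)
class TissuePatternLabels:
    mirna_name: str
    labels: FrozenSet[str]  # e.g. {"pan_high", "enriched:midgut"}
    margins: Dict[str, float]

    def __post_init__(self) -> None:
        if "pan_high" in self.labels and "pan_low" in self.labels:
            raise ValueError(f"{self.mirna_name}: pan_high and pan_low are exclusive")


def classify_tissue_pattern(
    values: Mapping[str, float],
    high: float = 3.5,
    low: float = 2.0,
    delta: float = 0.5,
    name: str = "",
) -> TissuePatternLabels:
    """Apply the four pattern rules to one miRNA's per-tissue log10 mean RPM.

    Boundary semantics are inclusive exactly as the thresholds read: values
    of 3.5 / 2.0 satisfy the pan rules, a margin of exactly ``delta``
    satisfies exclusion/enrichment.
    """
    if len(values) < 2:
        raise ValueError("need at least two tissues")
    tissues = sorted(values, key=lambda t: (values[t], t))
    v = [values[t] for t in tissues]
    labels = set()
    margins = {
        "pan_high": min(v) - high,
        "pan_low": low - max(v),
        "exclusion": v[1] - v[0],
        "enrichment": v[-1] - v[-2],
    }
    if all(x >= high for x in v):
        labels.add("pan_high")
    if all(x <= low for x in v):
        labels.add("pan_low")
    if margins["exclusion"] >= delta:
        labels.add(f"excluded:{tissues[0]}")
    if margins["enrichment"] >= delta:
        labels.add(f"enriched:{tissues[-1]}")
    return TissuePatternLabels(name, frozenset(labels), margins)


def classify_matrix(
    log_means: pd.DataFrame, high: float = 3.5, low: float = 2.0, delta: float = 0.5
) -> Dict[str, TissuePatternLabels]:
    """Pattern labels for every row of a miRNA x tissue log10-mean matrix."""
    return {
        name: classify_tissue_pattern(row.to_dict(), high, low, delta, name=name)
        for name, row in log_means.iterrows()
    }


def top_abundance(means: pd.DataFrame, n: int = 20) -> Dict[str, List[Tuple[str, float]]]:
    """Top-n miRNAs per tissue by mean RPM, ties broken alphabetically."""
    out = {}
    for tissue in means.columns:
        ranked = sorted(means[tissue].items(), key=lambda kv: (-kv[1], kv[0]))
        out[tissue] = ranked[:n]
    return out


def chromosome_profile(
    read_loci: pd.DataFrame,
    chromosome_lengths: Mapping[str, int],
    bin_bp: int = 100_000,
) -> Dict[str, pd.DataFrame]:
    """Chromosome contributions and positional hot spots of annotated reads.

    ``read_loci`` columns: tissue, chrom, pos, count. Returns
    ``chromosome_pct`` (tissue x chrom, rows sum to 100), ``bins`` (binned
    counts per tissue) and ``bin_tissue_pct`` (per-bin contribution of each
    tissue, summing to 100 where a bin is nonzero).
    """
    df = read_loci.copy()
    df["bin"] = (df["pos"] // bin_bp).astype(int)
    chroms = sorted(chromosome_lengths)
    per_chrom = (
        df.groupby(["tissue", "chrom"])["count"].sum().unstack(fill_value=0)
    ).reindex(columns=chroms, fill_value=0)
    chrom_pct = per_chrom.div(per_chrom.sum(axis=1), axis=0) * 100.0
    bins = df.groupby(["chrom", "bin", "tissue"])["count"].sum().unstack(fill_value=0)
    bin_tot = bins.sum(axis=1)
    bin_pct = bins.div(bin_tot.where(bin_tot > 0, 1), axis=0) * 100.0
    return {"chromosome_pct": chrom_pct, "bins": bins, "bin_tissue_pct": bin_pct}


def hierarchical_cluster(matrix: pd.DataFrame) -> Dict[str, object]:
    """UPGMA (average linkage, Euclidean) over rows and columns.

    Returns linkage matrices, deterministic leaf orders and Newick exports.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    out: Dict[str, object] = {}
    for axis, data, labels in (
        ("rows", matrix.values, list(matrix.index)),
        ("cols", matrix.values.T, list(matrix.columns)),
    ):
        if data.shape[0] < 2:
            out[axis] = None
            continue
        Z = sch.linkage(data, method="average", metric="euclidean")
        order = [labels[i] for i in sch.leaves_list(Z)]
        out[axis] = {"linkage": Z, "leaf_order": order, "newick": _to_newick(Z, labels)}
    return out


def _to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    tree = sch.to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{node.dist:.6g}"
        return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

    return rec(tree) + ";"


def pca(rpm: pd.DataFrame, n_components: Optional[int] = None) -> Dict[str, object]:
    """SVD-based PCA of libraries (columns) in miRNA space, centred only.

    No variance scaling is applied, keeping the original variability of the
    data. Returns per-library component scores and explained-variance
    fractions (summing to 1 over all components).
    """
    X = rpm.T.values  # libraries as samples
    if X.shape[0] < 2:
        raise ValueError("need at least 2 libraries")
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    model = _SKPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    return {
        "scores": pd.DataFrame(
            scores, index=rpm.columns, columns=[f"PC{i+1}" for i in range(scores.shape[1])]
        ),
        "explained_variance_ratio": model.explained_variance_ratio_,
    }


def relative_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise min-max scaling to [0, 1]; constant rows map to 0.5."""
    lo = matrix.min(axis=1)
    hi = matrix.max(axis=1)
    span = hi - lo
    scaled = matrix.sub(lo, axis=0).div(span.where(span > 0, 1.0), axis=0)
    scaled.loc[span == 0, :] = 0.5
    return scaled


def delta_ct(ct_target, ct_reference):
    """Relative qPCR expression, 2**-(Ct_target - Ct_reference)."""
    return 2.0 ** -(np.asarray(ct_target, dtype=float) - np.asarray(ct_reference, dtype=float))


def delta_ct_table(ct: pd.DataFrame, reference: str) -> pd.DataFrame:
    """2^-dCt for a Ct table (targets x samples) against a reference row.

    ``reference`` names the normaliser row (e.g. a ribosomal housekeeping
    gene); the reference itself comes out as 1.0 in every sample.
    """
    if reference not in ct.index:
        raise ValueError(f"reference {reference!r} not in Ct table")
    if not np.isfinite(ct.values).all():
        raise ValueError("Ct values must be finite")
    return 2.0 ** -(ct.sub(ct.loc[reference], axis=1))
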