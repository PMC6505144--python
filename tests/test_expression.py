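"""RPM quantification, pattern classification, clustering and ordination."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirtissue.expression import (
    chromosome_profile,
    classify_matrix,
    classify_tissue_pattern,
    compute_rpm,
    delta_ct,
    hierarchical_cluster,
    log_transform,
    pca,
    relative_scale,
    tissue_means,
    top_abundance,
)
from mirtissue.synth import simulate_expression_matrix


# -- RPM --------------------------------------------------------------------

def test_rpm_arithmetic_and_conservation():
    counts = pd.DataFrame({"lib1": [500, 999_500], "lib2": [500, 1_999_500]},
                          index=["x", "y"])
    totals = pd.Series({"lib1": 1_000_000, "lib2": 2_000_000})
    rpm = compute_rpm(counts, totals)
    assert rpm.loc["x", "lib1"] == 500.0
    assert rpm.loc["x", "lib2"] == 250.0
    assert np.allclose(compute_rpm(counts).sum(axis=0), 1e6)


def test_rpm_rejects_zero_totals():
    counts = pd.DataFrame({"lib1": [0, 0]}, index=["x", "y"])
    with pytest.raises(ValueError):
        compute_rpm(counts)


def test_log_transform_average_before_log():
    means = pd.DataFrame({"t": [1000.0, 0.0]}, index=["a", "b"])
    lg = log_transform(means, pseudocount=1.0)
    assert lg.loc["a", "t"] == pytest.approx(np.log10(1001), abs=1e-12)
    assert lg.loc["b", "t"] == 0.0
    # averaging replicates {10, 1000} then logging is not log-then-average
    avg_then_log = np.log10((10 + 1000) / 2 + 1)
    log_then_avg = (np.log10(11) + np.log10(1001)) / 2
    assert avg_then_log == pytest.approx(2.7042, abs=1e-4)
    assert abs(avg_then_log - log_then_avg) > 0.2


def test_tissue_means_average_replicates():
    rpm = pd.DataFrame({"t1_r1": [10.0], "t1_r2": [1000.0], "t2_r1": [7.0]},
                       index=["m"])
    means = tissue_means(rpm, {"t1_r1": "t1", "t1_r2": "t1", "t2_r1": "t2"})
    assert means.loc["m", "t1"] == 505.0
    assert means.loc["m", "t2"] == 7.0


# -- pattern classification -------------------------------------------------

@pytest.mark.parametrize(
    "values,expected",
    [
        ((4.0, 3.8, 3.6, 3.5), {"pan_high"}),
        ((4.0, 4.0, 4.0, 3.4), {"excluded:t4"}),
        ((4.2, 3.0, 2.9, 2.8), {"enriched:t1"}),
        ((2.0, 2.0, 2.0, 2.0), {"pan_low"}),
        ((3.5, 3.5, 3.5, 3.5), {"pan_high"}),          # boundary: >= 3.5
        ((3.0, 3.0, 3.0, 2.5), {"excluded:t4"}),       # margin exactly 0.5
        ((3.0, 2.5, 2.5, 2.5), {"enriched:t1"}),       # margin exactly 0.5
        ((2.6, 2.6, 2.6, 2.6), set()),
        ((4.0, 4.0, 4.0, 4.0), {"pan_high"}),
    ],
)
def test_pattern_rules(values, expected):
    labels = classify_tissue_pattern(
        dict(zip(("t1", "t2", "t3", "t4"), values)), name="m"
    )
    assert labels.labels == frozenset(expected)


def test_pan_high_and_midgut_enrichment_can_coexist():
    # mirrors the observation that a miRNA can be globally high yet enriched
    labels = classify_tissue_pattern(
        {"fat_body": 4.0, "midgut": 4.8, "ovary": 4.0, "remainder": 4.1}, name="m"
    )
    assert labels.labels == frozenset({"pan_high", "enriched:midgut"})


def test_labels_follow_tissues_under_permutation():
    vals = {"t1": 4.2, "t2": 3.0, "t3": 2.9, "t4": 1.5}
    a = classify_tissue_pattern(vals, name="m").labels
    permuted = {"t4": 1.5, "t3": 2.9, "t1": 4.2, "t2": 3.0}
    assert classify_tissue_pattern(permuted, name="m").labels == a
    assert a == frozenset({"enriched:t1", "excluded:t4"})


@given(st.lists(st.floats(min_value=-1, max_value=6, allow_nan=False),
                min_size=2, max_size=6))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_pan_high_and_pan_low_are_mutually_exclusive(values):
    labels = classify_tissue_pattern(
        {f"t{i}": v for i, v in enumerate(values)}, name="m"
    ).labels
    assert not ({"pan_high", "pan_low"} <= labels)
    assert sum(1 for l in labels if l.startswith("excluded:")) <= 1
    assert sum(1 for l in labels if l.startswith("enriched:")) <= 1


def test_classifier_requires_two_tissues():
    with pytest.raises(ValueError):
        classify_tissue_pattern({"t1": 3.0}, name="m")


# -- rankings / profiles ----------------------------------------------------

def test_top_abundance_orders_and_breaks_ties_alphabetically():
    means = pd.DataFrame({"t": [5.0, 9.0, 5.0]}, index=["b", "c", "a"])
    ranked = top_abundance(means, n=20)["t"]
    assert ranked == [("c", 9.0), ("a", 5.0), ("b", 5.0)]
    assert len(top_abundance(means, n=2)["t"]) == 2


def test_chromosome_profile_percentages():
    df = pd.DataFrame(
        [
            {"tissue": "mg", "chrom": "c1", "pos": 150_000, "count": 90},
            {"tissue": "ov", "chrom": "c1", "pos": 150_000, "count": 10},
            {"tissue": "mg", "chrom": "c2", "pos": 10_000, "count": 10},
        ]
    )
    prof = chromosome_profile(df, {"c1": 400_000, "c2": 200_000}, bin_bp=100_000)
    assert prof["chromosome_pct"].loc["mg", "c1"] == pytest.approx(90.0)
    assert prof["chromosome_pct"].loc["ov", "c1"] == pytest.approx(100.0)
    assert np.allclose(prof["chromosome_pct"].sum(axis=1), 100.0)
    bin_pct = prof["bin_tissue_pct"].loc[("c1", 1)]
    assert bin_pct["mg"] == pytest.approx(90.0)
    assert bin_pct["ov"] == pytest.approx(10.0)


def test_hot_spot_bin_is_the_planted_bin():
    rows = [{"tissue": "mg", "chrom": "c1", "pos": 250_000 + i, "count": 50}
            for i in range(5)]
    rows.append({"tissue": "mg", "chrom": "c1", "pos": 10_000, "count": 1})
    prof = chromosome_profile(pd.DataFrame(rows), {"c1": 400_000}, bin_bp=100_000)
    assert prof["bins"]["mg"].idxmax() == ("c1", 2)


# -- clustering -------------------------------------------------------------

def brute_force_upgma_heights(X):
    """Naive all-pairs average-linkage merge heights."""
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([
                np.linalg.norm(np.asarray(X[a]) - np.asarray(X[b]))
                for a in clusters[i] for b in clusters[j]
            ])
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] \
            + [clusters[i] + clusters[j]]
    return heights


def test_upgma_hand_computed_three_points():
    X = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0]],
                     index=["a", "b", "c"])
    Z = hierarchical_cluster(X)["rows"]["linkage"]
    assert Z[0, 2] == pytest.approx(0.0)   # identical rows merge first at 0
    assert Z[1, 2] == pytest.approx(5.0)   # mean of (5, 5)
    assert np.all(np.diff(Z[:, 2]) >= 0)   # monotone merge heights


def test_upgma_equals_brute_force_on_small_matrices(rng):
    for n in (4, 6, 8):
        X = rng.normal(size=(n, 3))
        Z = hierarchical_cluster(pd.DataFrame(X))["rows"]["linkage"]
        assert np.allclose(sorted(Z[:, 2]), sorted(brute_force_upgma_heights(X)),
                           atol=1e-9)


def test_row_permutation_preserves_tree_topology(rng):
    X = pd.DataFrame(rng.normal(size=(6, 4)),
                     index=[f"m{i}" for i in range(6)])
    perm = X.sample(frac=1, random_state=1)
    def leaf_pairs(df):
        res = hierarchical_cluster(df)["rows"]
        Z, labels = res["linkage"], list(df.index)
        merges = set()
        clusters = {i: frozenset([labels[i]]) for i in range(len(labels))}
        for k, (i, j, d, _) in enumerate(Z):
            merged = clusters[int(i)] | clusters[int(j)]
            clusters[len(labels) + k] = merged
            merges.add((merged, round(d, 9)))
        return merges
    assert leaf_pairs(X) == leaf_pairs(perm)


def test_newick_export_contains_all_leaves():
    X = pd.DataFrame([[0.0, 1.0], [1.0, 0.0], [5.0, 5.0]], index=["a", "b", "c"])
    nwk = hierarchical_cluster(X)["rows"]["newick"]
    assert nwk.endswith(";")
    for leaf in "abc":
        assert leaf in nwk


# -- PCA --------------------------------------------------------------------

def test_identical_libraries_coincide_in_score_space():
    rpm = pd.DataFrame({"l1": [10.0, 5.0, 1.0], "l2": [10.0, 5.0, 1.0],
                        "l3": [0.0, 2.0, 9.0]})
    scores = pca(rpm)["scores"]
    assert np.allclose(scores.loc["l1"], scores.loc["l2"], atol=1e-9)


def test_one_dimensional_data_loads_on_first_component(rng):
    base = rng.normal(size=10)
    rpm = pd.DataFrame({f"l{i}": base * (i + 1) for i in range(5)})
    evr = pca(rpm)["explained_variance_ratio"]
    assert evr[0] > 0.999


def test_replicates_group_by_tissue_in_pc_space():
    counts, layout, _ = simulate_expression_matrix(
        n_mirnas=120, replicates=3, depth=500_000, seed=9
    )
    rpm = compute_rpm(counts)
    scores = pca(rpm)["scores"][["PC1", "PC2"]]
    within, between = [], []
    for a, b in itertools.combinations(scores.index, 2):
        d = np.linalg.norm(scores.loc[a] - scores.loc[b])
        (within if layout[a] == layout[b] else between).append(d)
    assert max(within) < min(between)


# -- misc -------------------------------------------------------------------

def test_relative_scale_rows():
    X = pd.DataFrame([[1.0, 2.0, 3.0], [7.0, 7.0, 7.0]], index=["a", "b"])
    scaled = relative_scale(X)
    assert list(scaled.loc["a"]) == [0.0, 0.5, 1.0]
    assert list(scaled.loc["b"]) == [0.5, 0.5, 0.5]


def test_coexpressed_cluster_members_have_identical_scaled_profiles():
    base = np.array([100.0, 400.0, 50.0, 20.0])
    X = pd.DataFrame([base, base * 10], index=["m1", "m2"])
    scaled = relative_scale(X)
    assert np.allclose(scaled.loc["m1"], scaled.loc["m2"])


@pytest.mark.parametrize("ct_t,ct_r,expected", [(20, 20, 1.0), (21, 20, 0.5),
                                                (18, 20, 4.0)])
def test_delta_ct(ct_t, ct_r, expected):
    assert delta_ct(ct_t, ct_r) == pytest.approx(expected)


def test_delta_ct_table_normalises_against_reference_row():
    from mirtissue.expression import delta_ct_table

    ct = pd.DataFrame({"s1": [20.0, 21.0, 18.0], "s2": [22.0, 22.0, 22.0]},
                      index=["rpS7", "mirA", "mirB"])
    rel = delta_ct_table(ct, "rpS7")
    assert np.allclose(rel.loc["rpS7"], 1.0)
    assert rel.loc["mirA", "s1"] == pytest.approx(0.5)
    assert rel.loc["mirB", "s1"] == pytest.approx(4.0)
    assert rel.loc["mirA", "s2"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        delta_ct_table(ct, "missing")
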