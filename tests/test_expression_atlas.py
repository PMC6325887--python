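"""Specificity classification, profile clustering and neighbor analyses."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from lincatlas import (
    ExpressionMatrix,
    GeneModel,
    Interval,
    calibrate_expressed_threshold,
    clamp_log2fc,
    classify_specificity,
    cluster_profiles,
    find_neighbors,
    log_transform,
    make_profile_matrix,
    neighbor_correlations,
    paper_shape_expression,
    profile_normalize,
    specificity_counts,
)
from lincatlas.core_io import ValidationError

STAGES = [f"s{i}" for i in range(1, 10)]


def _matrix(rows: dict[str, list[float]], stages=STAGES) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=stages))


# ------------------------------------------------------------- log transform

def test_log_transform_of_zero_is_log2_pseudocount():
    m = _matrix({"g": [0.0] * 9})
    assert log_transform(m).iloc[0, 0] == pytest.approx(math.log2(0.01))


def test_log_transform_value_point_99_is_zero():
    m = _matrix({"g": [0.99] * 9})
    assert log_transform(m).iloc[0, 0] == pytest.approx(0.0)


def test_log_transform_preserves_ordering():
    m = _matrix({"g": [0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0]})
    assert log_transform(m).iloc[0].is_monotonic_increasing


# ---------------------------------------------------------------- specificity

def test_single_stage_profile_is_exclusive():
    (call,) = classify_specificity(_matrix({"g": [5, 0, 0, 0, 0, 0, 0, 0, 0]}))
    assert call.category == "exclusive"
    assert call.stage == "s1"
    assert call.n_stages_expressed == 1


def test_all_stage_profile_within_tenfold_is_ubiquitous():
    (call,) = classify_specificity(_matrix({"g": [1, 2, 3, 4, 5, 6, 7, 8, 9]}))
    assert call.category == "ubiquitous"
    assert call.max_min_ratio == pytest.approx(9.0)


def test_all_stage_profile_beyond_tenfold_is_broad_variable():
    (call,) = classify_specificity(_matrix({"g": [0.5] + [10.0] * 8}))
    assert call.category == "broad_variable"
    assert call.max_min_ratio == pytest.approx(20.0)


def test_silent_gene_is_not_expressed():
    (call,) = classify_specificity(_matrix({"g": [0.0] * 9}))
    assert call.category == "not_expressed"


def test_classes_partition_the_gene_set():
    m, _ = paper_shape_expression(3)
    counts = specificity_counts(classify_specificity(m))
    assert sum(counts.values()) == 170


def test_classification_invariant_under_co_scaled_threshold():
    m, _ = paper_shape_expression(4)
    base = [(c.gene_id, c.category) for c in classify_specificity(m, 0.1)]
    scaled = ExpressionMatrix(m.values * 7.0)
    assert base == [(c.gene_id, c.category) for c in classify_specificity(scaled, 0.7)]


def test_threshold_calibration_recovers_planted_counts():
    m, _ = paper_shape_expression(5)
    t = calibrate_expressed_threshold(m, target_ubiquitous=12, target_exclusive=8)
    assert 0.0 <= t <= 1.0
    counts = specificity_counts(classify_specificity(m, t))
    assert counts["ubiquitous"] == 12 and counts["exclusive"] == 8


# --------------------------------------------------------------- normalization

def test_constant_profile_normalizes_to_zero_vector():
    m = _matrix({"g": [3.0] * 9})
    assert np.allclose(profile_normalize(m, "s1").iloc[0], 0.0)


def test_profile_normalization_is_scale_invariant():
    m = _matrix({"g": [1, 2, 4, 8, 1, 2, 4, 8, 1]})
    doubled = ExpressionMatrix(m.values * 2)
    v1 = profile_normalize(m, "s1").iloc[0].to_numpy()
    v2 = profile_normalize(doubled, "s1").iloc[0].to_numpy()
    assert np.allclose(v1, v2, atol=0.02)  # pseudocount breaks exact equality


def test_profile_normalization_matches_direct_formula():
    m = _matrix({"g": [1, 2, 4, 8, 1, 2, 4, 8, 1]})
    vec = profile_normalize(m, "s1").iloc[0]
    row = m.values.iloc[0]
    for j, stage in enumerate(STAGES[1:], start=1):
        assert vec[stage] == pytest.approx(
            math.log2((row.iloc[j] + 0.01) / (row.iloc[0] + 0.01)))


def test_unknown_reference_stage_raises():
    with pytest.raises(KeyError):
        profile_normalize(_matrix({"g": [1.0] * 9}), "nope")


# ------------------------------------------------------------------ clustering

def test_kmeans_recovers_three_planted_profiles_exactly():
    matrix, manifest = make_profile_matrix(7, n_per_shape=40)
    clustering = cluster_profiles(matrix, k=3, seed=7, reference_stage="embryo")
    genes = list(clustering.assignments)
    truth = [manifest.profiles[g] for g in genes]
    found = [clustering.assignments[g] for g in genes]
    assert adjusted_rand_score(truth, found) == pytest.approx(1.0)


def test_k_of_one_gives_the_mean_vector_as_centroid():
    matrix, _ = make_profile_matrix(8, n_per_shape=10)
    clustering = cluster_profiles(matrix, k=1, seed=0, reference_stage="embryo")
    expected = profile_normalize(matrix, "embryo").to_numpy().mean(axis=0)
    assert np.allclose(clustering.centroids[0], expected)


def test_clustering_is_deterministic_given_seed():
    matrix, _ = make_profile_matrix(9, n_per_shape=15)
    c1 = cluster_profiles(matrix, k=3, seed=42, reference_stage="embryo")
    c2 = cluster_profiles(matrix, k=3, seed=42, reference_stage="embryo")
    assert c1.assignments == c2.assignments


def test_min_rpkm_filter_and_too_few_genes_error():
    m = _matrix({f"g{i}": [0.5] * 9 for i in range(20)})  # all below RPKM 1
    with pytest.raises(ValidationError):
        cluster_profiles(m, k=3, seed=0, reference_stage="s1")


# ------------------------------------------------------------------- neighbors

def _gene(gid, start, end, chrom="c", biotype="mRNA"):
    return GeneModel(gid, biotype, Interval(chrom, start, end, "+"),
                     (Interval(chrom, start, end, "+"),))


def test_neighbor_window_inclusion_and_exclusion():
    linc = _gene("linc", 1_000_000, 1_001_000, biotype="lincRNA")
    near = _gene("near", 1_051_000, 1_052_000)     # 50 kb downstream
    far = _gene("far", 1_151_001, 1_152_000)       # 150 kb downstream
    edge = _gene("edge", 1_100_999, 1_102_000)     # 1 bp inside the window
    recs = find_neighbors(linc, [near, far, edge])
    ids = {r.neighbor_id: r for r in recs}
    assert set(ids) == {"near", "edge"}
    assert ids["near"].signed_distance == 50_000
    assert ids["near"].rank == 1 and ids["edge"].rank == 2


def test_neighbor_ranks_run_outward_on_both_sides():
    linc = _gene("linc", 500_000, 501_000, biotype="lincRNA")
    genes = [_gene("u2", 420_000, 421_000), _gene("u1", 480_000, 481_000),
             _gene("d1", 510_000, 511_000), _gene("d2", 540_000, 541_000)]
    recs = find_neighbors(linc, genes)
    assert [(r.neighbor_id, r.rank) for r in recs] == [
        ("u2", -2), ("u1", -1), ("d1", 1), ("d2", 2)]
    assert recs[1].signed_distance == -(500_000 - 481_000)


def test_find_neighbors_matches_brute_force_oracle():
    rng = np.random.default_rng(12)
    for trial in range(30):
        genes = []
        for i in range(60):
            start = int(rng.integers(0, 2_000_000))
            genes.append(_gene(f"g{i}", start, start + int(rng.integers(200, 5000))))
        linc = _gene("L", 900_000, 902_000, biotype="lincRNA")
        window = 100_000
        got = {r.neighbor_id for r in find_neighbors(linc, genes, window)}
        lo, hi = linc.span.start - window, linc.span.end + window
        expected = {g.gene_id for g in genes if g.span.end > lo and g.span.start < hi}
        assert got == expected


def test_neighbor_correlation_identical_profiles_is_one():
    m = _matrix({"L": [1, 2, 4, 8, 1, 2, 4, 8, 1], "N": [1, 2, 4, 8, 1, 2, 4, 8, 1]})
    linc = _gene("L", 0, 100, biotype="lincRNA")
    (rec,) = neighbor_correlations(find_neighbors(linc, [_gene("N", 200, 300)]), m)
    assert rec.pearson_r == pytest.approx(1.0)


def test_constant_neighbor_flagged_undefined_not_dropped():
    m = _matrix({"L": [1, 2, 4, 8, 1, 2, 4, 8, 1], "N": [3.0] * 9})
    linc = _gene("L", 0, 100, biotype="lincRNA")
    (rec,) = neighbor_correlations(find_neighbors(linc, [_gene("N", 200, 300)]), m)
    assert rec.pearson_r is None and not rec.r_defined


def test_missing_gene_in_matrix_raises():
    m = _matrix({"L": [1.0] * 9})
    linc = _gene("L", 0, 100, biotype="lincRNA")
    with pytest.raises(KeyError):
        neighbor_correlations(find_neighbors(linc, [_gene("N", 200, 300)]), m)


def test_planted_coexpression_recovered_on_average():
    # 200 neighbor pairs drawn with a Gaussian copula at rho=0.9 on the log
    # scale; the mean recovered Pearson r across 9 stages stays within 0.1.
    rng = np.random.default_rng(77)
    rho, rs = 0.9, []
    for _ in range(200):
        z = rng.normal(size=9)
        y = rho * z + math.sqrt(1 - rho ** 2) * rng.normal(size=9)
        x_rpkm = np.maximum(2.0 ** (3 + z) - 0.01, 0)
        y_rpkm = np.maximum(2.0 ** (3 + y) - 0.01, 0)
        m = _matrix({"L": list(x_rpkm), "N": list(y_rpkm)})
        linc = _gene("L", 0, 100, biotype="lincRNA")
        (rec,) = neighbor_correlations(find_neighbors(linc, [_gene("N", 200, 300)]), m)
        rs.append(rec.pearson_r)
    assert abs(float(np.mean(rs)) - rho) < 0.1


# ------------------------------------------------------------------ log2 FC

def test_clamp_log2fc_values_and_bounds():
    out = clamp_log2fc([1.0, 2.0 ** 7, 2.0 ** -9, 4.0])
    assert list(out) == [0.0, 5.0, -5.0, 2.0]


def test_clamp_is_idempotent():
    out = clamp_log2fc([0.001, 1.0, 1000.0])
    assert np.allclose(np.clip(out, -5, 5), out)


def test_clamp_rejects_nonpositive_ratio():
    with pytest.raises(ValidationError):
        clamp_log2fc([0.0, 1.0])
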