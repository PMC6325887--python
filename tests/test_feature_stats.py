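"""Statistical tests against independent brute-force and closed-form oracles."""

import itertools
import math

import numpy as np
import pytest

from lincatlas import (
    GeneModel,
    Interval,
    ScoreTrack,
    chi_square_test,
    compare_feature,
    conservation_summary,
    make_gene_models,
    make_genome,
    pearson_r,
    rank_sum_test,
    sample_random_genes,
)
from lincatlas.core_io import ValidationError
from lincatlas.feature_stats import extract_feature


def _model(chrom="c", start=0, end=100, strand="+", gid="g"):
    return GeneModel(gid, "lincRNA", Interval(chrom, start, end, strand),
                     (Interval(chrom, start, end, strand),))


# -------------------------------------------------------------- conservation

def test_conservation_fully_scored():
    t = ScoreTrack()
    t.add_interval("c", 0, 100, 1.0)
    s = conservation_summary(t, _model())
    assert s.mean_score == 1.0 and s.base_coverage == 1.0


def test_conservation_half_scored():
    t = ScoreTrack()
    t.add_interval("c", 0, 50, 0.5)
    s = conservation_summary(t, _model())
    assert s.mean_score == 0.5 and s.base_coverage == 0.5


def test_conservation_unscored_transcript_has_undefined_mean():
    s = conservation_summary(ScoreTrack(), _model())
    assert s.mean_score is None and s.base_coverage == 0.0


def test_adding_unannotated_bases_keeps_mean_but_lowers_coverage():
    t = ScoreTrack()
    t.add_interval("c", 0, 50, 0.7)
    short = conservation_summary(t, _model(end=50))
    longer = conservation_summary(t, _model(end=100))
    assert longer.mean_score == pytest.approx(short.mean_score)
    assert longer.base_coverage < short.base_coverage


# ------------------------------------------------------------------ rank sum

def _exact_mwu_p(a, b):
    """Exhaustive-permutation two-sided Mann-Whitney p (tie-free inputs)."""
    pooled = sorted(a) + sorted(b)
    n_a, n_b = len(a), len(b)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    u_obs = sum(ranks[v] for v in a) - n_a * (n_a + 1) / 2
    m = min(u_obs, n_a * n_b - u_obs)
    hits = total = 0
    for combo in itertools.combinations(range(n_a + n_b), n_a):
        u = sum(i + 1 for i in combo) - n_a * (n_a + 1) / 2
        total += 1
        if u <= m or u >= n_a * n_b - m:
            hits += 1
    return min(1.0, hits / total)


def test_rank_sum_separated_groups_exact_p():
    res = rank_sum_test([1, 2, 3], [10, 11, 12])
    assert res.method == "exact"
    assert res.two_sided_p == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings


def test_rank_sum_identical_groups_p_near_one():
    res = rank_sum_test([1, 2, 5, 9], [1, 2, 5, 9])
    assert res.two_sided_p > 0.8


def test_rank_sum_is_symmetric_in_groups():
    rng = np.random.default_rng(3)
    a, b = rng.normal(size=6), rng.normal(size=9)
    assert rank_sum_test(a, b).two_sided_p == pytest.approx(
        rank_sum_test(b, a).two_sided_p)


@pytest.mark.parametrize("seed", range(12))
def test_rank_sum_exact_matches_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    n_a, n_b = rng.integers(2, 9, size=2)
    vals = rng.permutation(100)[: n_a + n_b].astype(float)  # tie-free
    a, b = vals[:n_a], vals[n_a:]
    assert rank_sum_test(a, b).two_sided_p == pytest.approx(
        _exact_mwu_p(list(a), list(b)), abs=1e-12)


def test_rank_sum_empty_group_rejected():
    with pytest.raises(ValidationError):
        rank_sum_test([], [1.0])


# ------------------------------------------------------------------- pearson

def test_pearson_perfect_anticorrelation():
    x = [1.0, 2.0, 5.0]
    assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)


def test_pearson_affine_invariance():
    x = [1.0, 2.0, 3.0, 7.0]
    assert pearson_r(x, [2 * v + 7 for v in x]) == pytest.approx(1.0)


def test_pearson_matches_closed_form():
    x, y = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])
    num = ((x - x.mean()) * (y - y.mean())).sum()
    den = math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
    assert pearson_r(x, y) == pytest.approx(num / den)


def test_pearson_constant_vector_is_nan():
    assert math.isnan(pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


# ---------------------------------------------------------------- chi-square

def test_chi_square_identical_rows():
    res = chi_square_test([[5, 10, 5], [5, 10, 5]])
    assert res.statistic == pytest.approx(0.0)
    assert res.two_sided_p == pytest.approx(1.0)


def test_chi_square_diagonal_table():
    res = chi_square_test([[10, 0], [0, 10]])
    assert res.statistic == pytest.approx(20.0)
    assert "df=1" in res.method


def test_chi_square_matches_textbook_formula():
    table = np.array([[12.0, 7.0], [5.0, 16.0]])
    n = table.sum()
    expected = np.outer(table.sum(1), table.sum(0)) / n
    stat = ((table - expected) ** 2 / expected).sum()
    assert chi_square_test(table).statistic == pytest.approx(stat)


def test_chi_square_zero_expected_rejected():
    with pytest.raises(ValidationError):
        chi_square_test([[0, 5], [0, 7]])


# ------------------------------------------------------------------ sampling

def test_sampling_is_deterministic_and_without_replacement():
    models = [_model(gid=f"g{i}") for i in range(30)]
    s1 = sample_random_genes(models, 10, seed=5)
    s2 = sample_random_genes(models, 10, seed=5)
    assert s1 == s2
    assert len({m.gene_id for m in s1}) == 10


def test_sampling_full_population_is_a_permutation():
    models = [_model(gid=f"g{i}") for i in range(8)]
    assert sorted(m.gene_id for m in sample_random_genes(models, 8, 0)) == sorted(
        m.gene_id for m in models)
    with pytest.raises(ValidationError):
        sample_random_genes(models, 9, 0)


def test_sampling_inclusion_frequency_is_uniform():
    models = [_model(gid=f"g{i}") for i in range(10)]
    hits = {m.gene_id: 0 for m in models}
    n_rep, n = 2000, 3
    for seed in range(n_rep):
        for m in sample_random_genes(models, n, seed):
            hits[m.gene_id] += 1
    freqs = np.array(list(hits.values())) / n_rep
    assert np.allclose(freqs, n / 10, atol=0.05)


# ----------------------------------------------------------- compare_feature

def test_lincrnas_shorter_than_mrnas_on_synthetic_annotation():
    genome = make_genome(11, n_chrom=2, chrom_length=2_000_000)
    models = make_gene_models(11, genome, n_linc=200, n_mrna=300)
    lincs = [m for m in models if m.biotype == "lincRNA"]
    mrnas = sample_random_genes([m for m in models if m.biotype == "mRNA"], 200, 11)
    res, sa, sb = compare_feature(lincs, mrnas, "length")
    assert sa["median"] < sb["median"]
    assert res.two_sided_p < 0.05
    res_e, ea, eb = compare_feature(lincs, mrnas, "exon_count")
    assert ea["median"] < eb["median"]
    assert res_e.two_sided_p < 0.05


def test_compare_feature_identical_groups():
    models = [_model(gid=f"g{i}", end=100 + i) for i in range(10)]
    res, _, _ = compare_feature(models, models, "length")
    assert res.two_sided_p > 0.8


def test_compare_feature_is_rank_sum_on_extracted_vectors(bundle):
    lincs, mrnas = bundle["lincs"][:30], bundle["mrnas"][:30]
    res, _, _ = compare_feature(lincs, mrnas, "exon_count")
    direct = rank_sum_test(extract_feature(lincs, "exon_count"),
                           extract_feature(mrnas, "exon_count"))
    assert res == direct
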