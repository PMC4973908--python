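"""QC filters, greedy tag pruning (vs brute-force oracle), imputation,
standardization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import snpclust as sc
from snpclust.datatypes import MISSING
from snpclust.preprocess import PreprocessError, _pairwise_complete_r2

from conftest import make_genotype_data


# ---------------------------------------------------------------------------
# missingness


def test_sample_above_3pct_missing_removed():
    rng = np.random.default_rng(0)
    geno = rng.integers(0, 3, size=(100, 100)).astype(np.int8)
    geno[0, :4] = MISSING  # 4% missing on sample 0
    g = make_genotype_data(geno, pos=list(range(1, 101)))
    out = sc.filter_missingness(g, sc.QcParams())
    assert out.n_samples == 99
    assert "s0" not in set(out.samples["sample_id"])


def test_snp_at_exactly_threshold_retained():
    geno = np.ones((100, 100), dtype=np.int8)
    geno[::2, :] = 0
    geno[0, 0] = MISSING  # SNP 0: exactly 1% missing -> retained (strict "above")
    g = make_genotype_data(geno, pos=list(range(1, 101)))
    out = sc.filter_missingness(g, sc.QcParams())
    assert out.n_snps == 100 and out.n_samples == 100


def test_fully_observed_matrix_unchanged():
    geno = np.tile([0, 1, 2], (9, 4))[:, :10].astype(np.int8)
    g = make_genotype_data(geno, pos=list(range(1, 11)))
    out = sc.filter_missingness(g, sc.QcParams())
    np.testing.assert_array_equal(out.genotypes, g.genotypes)


def test_snp_rate_recomputed_after_sample_filter():
    # SNP 0 is missing only in the to-be-dropped sample: kept afterwards
    geno = np.ones((20, 2), dtype=np.int8)
    geno[0, 0] = MISSING
    geno[0, 1] = MISSING  # sample 0: 100% missing -> dropped
    g = make_genotype_data(geno, pos=[1, 2])
    out = sc.filter_missingness(g, sc.QcParams(snp_miss_max=0.01))
    assert out.n_samples == 19 and out.n_snps == 2


# ---------------------------------------------------------------------------
# MAF


@pytest.mark.parametrize(
    "freq,kept",
    [(0.04, False), (0.05, True), (0.5, True), (0.96, False)],
    ids=["maf4pct-out", "maf5pct-boundary-in", "het-in", "freq96-out"],
)
def test_maf_boundaries(freq, kept):
    rng = np.random.default_rng(1)
    col = rng.binomial(2, freq, size=2000).astype(np.int8)
    # force the realized frequency to the target exactly by construction
    col = np.zeros(2000, dtype=np.int8)
    n_b = int(round(freq * 2 * 2000))
    col[: n_b // 2] = 2
    if n_b % 2:
        col[n_b // 2] = 1
    anchor = np.tile([0, 1, 2, 1], 500).astype(np.int8)  # MAF 0.5, always kept
    g = make_genotype_data(np.column_stack([col, anchor]), pos=[1, 2])
    out = sc.filter_maf(g, sc.QcParams())
    assert ("snp0" in set(out.snps["snp_id"])) == kept


# ---------------------------------------------------------------------------
# tag pruning


def brute_force_greedy_prune(geno, pos, r2_max, window):
    """Independent oracle: same contract, quadratic scan over all pairs."""
    kept = []
    for j in range(geno.shape[1]):
        ok = True
        for k in kept:
            if abs(pos[j] - pos[k]) <= window:
                if _pairwise_complete_r2(geno[:, j], geno[:, k]) > r2_max:
                    ok = False
                    break
        if ok:
            kept.append(j)
    return kept


def test_duplicate_snp_dropped_independent_kept():
    rng = np.random.default_rng(2)
    a = rng.integers(0, 3, 200).astype(np.int8)
    b = rng.integers(0, 3, 200).astype(np.int8)
    g = make_genotype_data(np.column_stack([a, a, b]), pos=[1000, 1100, 1200])
    out = sc.tag_snp_prune(g, sc.QcParams())
    assert list(out.snps["snp_id"]) == ["snp0", "snp2"]


def test_window_limits_comparisons():
    rng = np.random.default_rng(3)
    a = rng.integers(0, 3, 200).astype(np.int8)
    g = make_genotype_data(np.column_stack([a, a]), pos=[1, 600_002])
    out = sc.tag_snp_prune(g, sc.QcParams())  # duplicate but outside 500 kb
    assert out.n_snps == 2


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_tag_prune_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    m = rng.integers(5, 50)
    n = 60
    # correlated batches to generate realistic LD
    base = rng.integers(0, 3, size=(n, 4)).astype(np.int8)
    cols = []
    for j in range(m):
        src = base[:, rng.integers(0, 4)].copy()
        flip = rng.random(n) < rng.uniform(0, 0.5)
        src[flip] = rng.integers(0, 3, flip.sum())
        cols.append(src)
    geno = np.column_stack(cols)
    pos = np.sort(rng.choice(np.arange(1, 2_000_000), size=m, replace=False))
    g = make_genotype_data(geno, pos=list(pos))
    p = sc.QcParams()
    kept = sc.tag_snp_prune(g, p)
    oracle = brute_force_greedy_prune(geno, pos, p.tag_r2, p.tag_window_bp)
    assert list(kept.snps["snp_id"]) == [f"snp{j}" for j in oracle]


# ---------------------------------------------------------------------------
# imputation


def test_impute_degenerate_distribution():
    col = np.zeros(50, dtype=np.int8)
    col[7] = MISSING
    g = make_genotype_data(col[:, None])
    out = sc.impute_random(g, sc.QcParams(seed=0))
    assert out.genotypes[7, 0] == 0


def test_impute_deterministic_under_seed():
    rng = np.random.default_rng(4)
    geno = rng.integers(0, 3, size=(200, 20)).astype(np.int8)
    geno[rng.random(geno.shape) < 0.1] = MISSING
    g = make_genotype_data(geno, pos=list(range(1, 21)))
    a = sc.impute_random(g, sc.QcParams(seed=5))
    b = sc.impute_random(g, sc.QcParams(seed=5))
    np.testing.assert_array_equal(a.genotypes, b.genotypes)
    # non-missing entries untouched
    obs = geno != MISSING
    np.testing.assert_array_equal(a.genotypes[obs], geno[obs])


def test_impute_law_of_large_numbers():
    # observed distribution (0: 1/2, 1: 1/4, 2: 1/4); 10,000 imputed entries
    observed = np.array([0, 0, 1, 2] * 25, dtype=np.int8)
    col = np.concatenate([observed, np.full(10_000, MISSING, dtype=np.int8)])
    g = make_genotype_data(col[:, None])
    out = sc.impute_random(g, sc.QcParams(seed=6))
    imputed = out.genotypes[100:, 0]
    freqs = np.bincount(imputed, minlength=3) / 10_000
    np.testing.assert_allclose(freqs, [0.5, 0.25, 0.25], atol=0.02)


# ---------------------------------------------------------------------------
# standardization


def test_standardize_closed_form():
    g = make_genotype_data(np.array([[0], [1], [2]], dtype=np.int8))
    x = sc.standardize(g)
    np.testing.assert_allclose(x.values[:, 0], [-1.0, 0.0, 1.0])


def test_standardize_moments_and_idempotence():
    rng = np.random.default_rng(7)
    geno = rng.integers(0, 3, size=(300, 30)).astype(np.int8)
    g = make_genotype_data(geno, pos=list(range(1, 31)))
    x = sc.standardize(g)
    assert np.abs(x.values.mean(axis=0)).max() < 1e-10
    np.testing.assert_allclose(x.values.var(axis=0, ddof=1), 1.0, atol=1e-10)
    # already-standardized columns are a fixed point of z-scoring
    z = (x.values - x.values.mean(0)) / x.values.std(0, ddof=1)
    np.testing.assert_allclose(z, x.values, atol=1e-12)


def test_standardize_rejects_missing_and_zero_variance():
    g = make_genotype_data(np.array([[MISSING], [1], [2]], dtype=np.int8))
    with pytest.raises(PreprocessError):
        sc.standardize(g)
    g2 = make_genotype_data(np.ones((5, 1), dtype=np.int8))
    with pytest.raises(PreprocessError, match="zero-variance"):
        sc.standardize(g2)


def test_qc_stage_order_counts():
    """Sample filter, then SNP filter, then MAF, then pruning."""
    rng = np.random.default_rng(8)
    n, m = 100, 40
    geno = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    geno[:, 0] = np.tile([0, 1], 50)             # healthy SNP
    geno[0, :10] = MISSING                       # sample 0: 25% missing
    geno[1:4, 1] = MISSING                       # SNP 1: 3% missing on retained samples
    geno[:, 2] = 0
    geno[:2, 2] = 1                              # SNP 2: MAF 1% -> dropped
    geno[:, 3] = geno[:, 0]                      # duplicate of SNP 0 -> pruned
    g = make_genotype_data(geno, pos=[1000 * (j + 1) for j in range(m)])
    p = sc.QcParams(seed=0)
    g1 = sc.filter_missingness(g, p)
    assert g1.n_samples == n - 1 and g1.n_snps == m - 1
    g2 = sc.filter_maf(g1, p)
    assert g2.n_snps == m - 2
    g3 = sc.tag_snp_prune(g2, p)
    assert "snp3" not in set(g3.snps["snp_id"])
    g4 = sc.impute_random(g3, p)
    assert not g4.is_missing().any()
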