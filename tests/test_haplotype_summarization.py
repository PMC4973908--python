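"""Locus grouping, EM phasing (vs an exhaustive-EM oracle), haplotype
classification, feature pruning and matrix assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest

import snpclust as sc
from snpclust.contributor_selection import ComponentSelection, SelectionResult
from snpclust.haplotype_summarization import (
    DegenerateLocusError,
    HaplotypeFeature,
    LocusGroup,
    SummarizationParams,
    build_feature_matrix,
    classify_haplotypes,
    group_loci,
    phase_em,
    prune_correlated,
)

from conftest import make_genotype_data


def make_selection(per_component, snps):
    sels = [
        ComponentSelection(c, np.asarray(idx, dtype=int), 2, np.zeros(len(idx)))
        for c, idx in per_component
    ]
    return SelectionResult(sels, snps)


def snp_table(chrom_pos):
    return pd.DataFrame(
        {
            "snp_id": [f"snp{j}" for j in range(len(chrom_pos))],
            "chrom": [str(c) for c, _ in chrom_pos],
            "pos_bp": [p for _, p in chrom_pos],
            "allele_a": "A",
            "allele_b": "B",
        }
    )


# ---------------------------------------------------------------------------
# locus grouping


def test_group_loci_chains_sub_megabase_gaps():
    snps = snp_table([("8", 1_000_000), ("8", 1_500_000), ("8", 2_400_000)])
    sel = make_selection([(0, [0, 1, 2])], snps)
    groups, leftovers = group_loci(sel, snps)
    assert len(groups) == 1 and not leftovers
    assert groups[0].n_snps == 3
    assert (groups[0].start_bp, groups[0].end_bp) == (1_000_000, 2_400_000)


def test_group_loci_gap_above_megabase_splits():
    snps = snp_table([("8", 1_000_000), ("8", 2_100_000)])
    sel = make_selection([(0, [0, 1])], snps)
    groups, leftovers = group_loci(sel, snps)
    assert not groups and len(leftovers) == 2


def test_group_loci_exact_megabase_gap_splits():
    # "closer than 1,000,000" is strict: a gap of exactly 1 Mb separates
    snps = snp_table([("8", 1_000_000), ("8", 2_000_000)])
    sel = make_selection([(0, [0, 1])], snps)
    groups, leftovers = group_loci(sel, snps)
    assert not groups and len(leftovers) == 2


def test_group_loci_respects_chromosomes_and_components():
    snps = snp_table([("1", 100), ("1", 200), ("2", 150), ("2", 250)])
    sel = make_selection([(0, [0, 1]), (1, [2, 3])], snps)
    groups, leftovers = group_loci(sel, snps)
    assert len(groups) == 2 and not leftovers
    assert {g.chrom for g in groups} == {"1", "2"}
    assert {g.component for g in groups} == {0, 1}


# ---------------------------------------------------------------------------
# phasing


def exhaustive_em_oracle(genotypes, max_iter=300, tol=1e-7):
    """Independent exhaustive-phasing EM over all 2^(h-1) phasings/sample."""
    n, L = genotypes.shape
    hap_list = [np.array(h, dtype=np.uint8) for h in itertools.product((0, 1), repeat=L)]
    hap_ids = {h.tobytes(): i for i, h in enumerate(hap_list)}
    pairs_per_sample = []
    for s in range(n):
        g = genotypes[s]
        het = np.flatnonzero(g == 1)
        pairs = []
        for bits in itertools.product((0, 1), repeat=len(het)):
            h1 = (g // 2).astype(np.uint8)
            h1[het] = bits
            h2 = (g - h1).astype(np.uint8)
            key = tuple(sorted((h1.tobytes(), h2.tobytes())))
            pairs.append(key)
        pairs_per_sample.append(sorted(set(pairs)))
    used = sorted({h for pairs in pairs_per_sample for pair in pairs for h in pair})
    freq = {h: 1.0 / len(used) for h in used}
    for _ in range(max_iter):
        counts = {h: 0.0 for h in used}
        for pairs in pairs_per_sample:
            ws = []
            for h1, h2 in pairs:
                mult = 1.0 if h1 == h2 else 2.0
                ws.append(mult * freq[h1] * freq[h2])
            tot = sum(ws)
            for (h1, h2), w in zip(pairs, ws):
                counts[h1] += w / tot
                counts[h2] += w / tot
        new = {h: c / (2 * n) for h, c in counts.items()}
        delta = max(abs(new[h] - freq[h]) for h in used)
        freq = new
        if delta < tol:
            break
    return freq


def test_phase_all_homozygous_is_exact():
    geno = np.array([[0, 2, 0, 2], [2, 2, 0, 0], [0, 0, 0, 0]])
    ph = phase_em(geno, seed=0)
    np.testing.assert_array_equal(ph.haplotypes[0::2] + ph.haplotypes[1::2], geno)
    np.testing.assert_array_equal(ph.haplotypes[0], [0, 1, 0, 1])


def test_phase_single_het_site_unique():
    geno = np.array([[0, 1, 2], [0, 1, 2]])
    ph = phase_em(geno, seed=0)
    pairs = {tuple(sorted((h1.tobytes(), h2.tobytes())))
             for h1, h2 in zip(ph.haplotypes[0::2], ph.haplotypes[1::2])}
    assert pairs == {tuple(sorted((bytes([0, 0, 1]), bytes([0, 1, 1]))))}


def test_phase_rejects_missing():
    with pytest.raises(ValueError):
        phase_em(np.array([[0, -1], [1, 1]]))


@pytest.mark.parametrize("n_snps", [3, 5, 6])
def test_phase_matches_exhaustive_em_oracle(n_snps):
    rng = np.random.default_rng(n_snps)
    pool = np.array(
        [rng.integers(0, 2, n_snps) for _ in range(3)], dtype=np.uint8
    )
    draws = pool[rng.choice(3, size=(120, 2), p=[0.5, 0.3, 0.2]).reshape(-1)]
    geno = (draws[0::2] + draws[1::2]).astype(np.int64)
    ph = phase_em(geno, window=8, seed=0)
    oracle = exhaustive_em_oracle(geno)
    est = {h: f for h, f in ph.hap_freqs.items()}
    tv = 0.5 * sum(
        abs(est.get(h, 0.0) - oracle.get(h, 0.0)) for h in set(est) | set(oracle)
    )
    assert tv < 1e-4


def test_phase_frequency_recovery_three_haplotype_pool():
    rng = np.random.default_rng(99)
    pool = np.array([[0, 0, 0, 0], [1, 1, 1, 0], [0, 1, 0, 1]], dtype=np.uint8)
    probs = [0.55, 0.3, 0.15]
    draws = pool[rng.choice(3, size=(2000, 2), p=probs).reshape(-1)]
    geno = (draws[0::2] + draws[1::2]).astype(np.int64)
    ph = phase_em(geno, seed=0)
    tv = 0.5 * sum(
        abs(ph.hap_freqs.get(pool[i].tobytes(), 0.0) - probs[i]) for i in range(3)
    ) + 0.5 * sum(
        f for h, f in ph.hap_freqs.items()
        if h not in {p.tobytes() for p in pool}
    )
    assert tv < 0.05
    # unambiguous samples (<= 1 het site) must be phased exactly
    het_counts = (geno == 1).sum(axis=1)
    unamb = np.flatnonzero(het_counts <= 1)
    correct = 0
    for s in unamb:
        inferred = {ph.haplotypes[2 * s].tobytes(), ph.haplotypes[2 * s + 1].tobytes()}
        truth = {draws[2 * s].tobytes(), draws[2 * s + 1].tobytes()}
        correct += inferred == truth
    assert correct / unamb.size >= 0.95


def test_phase_consistency_invariant_on_random_input():
    rng = np.random.default_rng(12)
    geno = rng.integers(0, 3, size=(40, 20)).astype(np.int64)
    ph = phase_em(geno, window=6, seed=0)
    np.testing.assert_array_equal(
        ph.haplotypes[0::2].astype(int) + ph.haplotypes[1::2].astype(int), geno
    )


# ---------------------------------------------------------------------------
# classification


def _locus(n_snps, chrom="8"):
    return LocusGroup(0, chrom, np.arange(n_snps), 100, 100 + n_snps)


def test_classify_complementary_pool_reproduces_genotype():
    rng = np.random.default_rng(13)
    hap_class = rng.integers(0, 2, size=2 * 300)
    pool = np.array([[0] * 5, [1] * 5], dtype=np.uint8)
    haps = pool[hap_class]
    ph = sc.PhasedLocus(haps, {}, True)
    feat = classify_haplotypes(ph, _locus(5), seed=0)
    counts_one_site = haps[0::2, 0] + haps[1::2, 0]
    # class-2 counts equal the genotype at any site (or its mirror image)
    assert (
        np.array_equal(feat.per_sample_count, counts_one_site)
        or np.array_equal(feat.per_sample_count, 2 - counts_one_site)
    )
    assert sum(feat.class_frequencies) == pytest.approx(1.0)
    assert feat.class_frequencies[0] >= feat.class_frequencies[1]


def test_classify_two_family_locus_recovers_family_genotype():
    """Inversion-like locus: two divergent 20-SNP families, 5% mutation."""
    rng = np.random.default_rng(14)
    n, L = 500, 20
    f1 = rng.integers(0, 2, L).astype(np.uint8)
    founders = np.vstack([f1, 1 - f1])
    fam = rng.choice(2, size=2 * n, p=[0.6, 0.4])
    haps = founders[fam]
    haps = np.where(rng.random(haps.shape) < 0.05, 1 - haps, haps).astype(np.uint8)
    ph = sc.PhasedLocus(haps, {}, True)
    feat = classify_haplotypes(ph, _locus(L), seed=0)
    truth = fam.reshape(-1, 2).sum(axis=1)
    acc = max(
        np.mean(feat.per_sample_count == truth),
        np.mean((2 - feat.per_sample_count) == truth),
    )
    assert acc >= 0.95
    assert set(np.unique(feat.per_sample_count)) <= {0, 1, 2}


def test_classify_identical_haplotypes_fatal():
    haps = np.ones((20, 4), dtype=np.uint8)
    with pytest.raises(DegenerateLocusError):
        classify_haplotypes(sc.PhasedLocus(haps, {}, True), _locus(4), seed=0)


# ---------------------------------------------------------------------------
# pruning


def _feature(counts, chrom="1", component=0, start=100):
    locus = LocusGroup(component, chrom, np.arange(3), start, start + 10)
    counts = np.asarray(counts, dtype=np.int8)
    return HaplotypeFeature(locus, np.zeros(2 * counts.size, dtype=np.int8), counts, (0.5, 0.5))


def test_prune_duplicate_same_chromosome():
    rng = np.random.default_rng(15)
    c = rng.integers(0, 3, 100)
    kept = prune_correlated([_feature(c, start=100), _feature(c, start=200)])
    assert len(kept) == 1 and kept[0].locus.start_bp == 100


def test_prune_keeps_duplicates_on_different_chromosomes():
    rng = np.random.default_rng(16)
    c = rng.integers(0, 3, 100)
    kept = prune_correlated([_feature(c, chrom="1"), _feature(c, chrom="2")])
    assert len(kept) == 2


def test_prune_idempotent_and_drops_zero_variance():
    rng = np.random.default_rng(17)
    feats = [
        _feature(rng.integers(0, 3, 50), start=100 * (i + 1)) for i in range(4)
    ]
    with pytest.warns(UserWarning, match="zero variance"):
        kept = prune_correlated(feats + [_feature(np.ones(50), start=999)])
    again = prune_correlated(kept)
    assert [f.locus.start_bp for f in again] == [f.locus.start_bp for f in kept]


# ---------------------------------------------------------------------------
# feature matrix assembly


def test_build_feature_matrix_scattered_snps_only():
    rng = np.random.default_rng(18)
    geno = rng.integers(0, 3, size=(50, 4)).astype(np.int8)
    g = make_genotype_data(geno, chrom=["1", "3", "5", "7"], pos=[100] * 4)
    sel = make_selection([(0, [0, 2]), (1, [2, 3])], g.snps)
    fm = build_feature_matrix(g, sel)
    assert list(fm.features["kind"]) == ["snp"] * 3  # snp2 deduplicated
    np.testing.assert_array_equal(fm.values, geno[:, [0, 2, 3]])


def test_build_feature_matrix_locus_plus_scattered():
    rng = np.random.default_rng(19)
    n = 80
    hap_class = rng.integers(0, 2, 2 * n)
    f1 = rng.integers(0, 2, 10).astype(np.uint8)
    pool = np.vstack([f1, 1 - f1])
    haps = pool[hap_class]
    locus_geno = (haps[0::2] + haps[1::2]).astype(np.int8)
    scattered = rng.integers(0, 3, size=(n, 3)).astype(np.int8)
    geno = np.column_stack([locus_geno, scattered])
    chrom = ["2"] * 10 + ["4", "6", "9"]
    pos = [1000 + 50 * j for j in range(10)] + [500, 500, 500]
    g = make_genotype_data(geno, chrom=chrom, pos=pos)
    sel = make_selection([(0, list(range(10)) + [10, 11, 12])], g.snps)
    fm = build_feature_matrix(g, sel, SummarizationParams(seed=0))
    kinds = fm.features["kind"].value_counts().to_dict()
    assert kinds == {"snp": 3, "hap": 1}
    hap_col = fm.values[:, (fm.features["kind"] == "hap").to_numpy()][:, 0]
    truth = hap_class.reshape(-1, 2).sum(axis=1)
    assert (
        np.array_equal(hap_col, truth) or np.array_equal(hap_col, 2 - truth)
    )
    assert set(np.unique(fm.values)) <= {0, 1, 2}


def test_build_feature_matrix_counts_conserved(scene_runs):
    result = scene_runs(1)
    fm = result.features
    assert fm.n_features == len(fm.features)
    assert set(np.unique(fm.values)) <= {0, 1, 2}
    # same-chromosome haplotype features respect the r^2 bound
    haps = fm.features[fm.features["kind"] == "hap"]
    for chrom, sub in haps.groupby("chrom"):
        idx = sub.index.to_numpy()
        for i, a in enumerate(idx):
            for b in idx[i + 1:]:
                r = np.corrcoef(fm.values[:, a].astype(float), fm.values[:, b].astype(float))[0, 1]
                assert r * r <= 0.8 + 1e-12
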