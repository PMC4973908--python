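"""Summarization of physically clustered selected SNPs into haplotype features.

Selected SNPs on one chromosome closer than 1 Mb (strictly) are chained into
loci.  Each locus is phased by a partition–ligation EM: haplotype
frequencies are estimated exhaustively within small windows, then adjacent
segments are ligated by EM over concatenations of each sample's plausible
segment pairs, which keeps the cost linear in the number of SNPs.  The 2n
inferred haplotypes are grouped into two classes by a Gaussian mixture on
their first principal component, and each sample is summarized by its count
(0/1/2) of minor-class haplotypes.  Correlated haplotype features on the
same chromosome are pruned (r² > 0.8).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._gmm import fit_gmm_1d
from .contributor_selection import SelectionResult
from .datatypes import FeatureMatrix, GenotypeData

logger = logging.getLogger(__name__)


class DegenerateLocusError(RuntimeError):
    """All inferred haplotypes identical; the locus carries no class signal."""


@dataclass
class SummarizationParams:
    max_gap_bp: int = 1_000_000
    phase_window: int = 8
    r2_max: float = 0.8
    seed: int = 0


@dataclass
class LocusGroup:
    component: int
    chrom: str
    snp_indices: np.ndarray  # positions into the SNP table, position-sorted
    start_bp: int
    end_bp: int

    @property
    def n_snps(self) -> int:
        return self.snp_indices.size


@dataclass
class PhasedLocus:
    """Rows 2i and 2i+1 are sample i's two inferred haplotypes."""

    haplotypes: np.ndarray  # (2n, L) uint8
    hap_freqs: dict
    converged: bool

    @property
    def n_samples(self) -> int:
        return self.haplotypes.shape[0] // 2


@dataclass
class HaplotypeFeature:
    locus: LocusGroup
    hap_classes: np.ndarray        # (2n,) values in {1, 2}
    per_sample_count: np.ndarray   # (n,) count of class-2 haplotypes
    class_frequencies: tuple       # (freq class 1, freq class 2)


# ---------------------------------------------------------------------------
# locus grouping


def group_loci(
    selected: SelectionResult,
    snps: pd.DataFrame,
    max_gap_bp: int = 1_000_000,
) -> tuple[list[LocusGroup], list[tuple[int, int]]]:
    """Single-linkage chaining of each component's selected SNPs.

    Consecutive position-sorted SNPs on one chromosome join a locus when
    their gap is strictly below ``max_gap_bp``.  Singleton chains are
    returned as leftover ``(component, snp_index)`` pairs.
    """
    chrom_arr = snps["chrom"].to_numpy()
    pos_arr = snps["pos_bp"].to_numpy()
    groups: list[LocusGroup] = []
    leftovers: list[tuple[int, int]] = []
    for comp in selected.per_component:
        if comp.n_selected == 0:
            continue
        idx = comp.snp_indices
        order = np.lexsort((pos_arr[idx], chrom_arr[idx]))
        idx = idx[order]
        chains: list[list[int]] = [[idx[0]]]
        for prev, cur in zip(idx[:-1], idx[1:]):
            same_chrom = chrom_arr[prev] == chrom_arr[cur]
            if same_chrom and pos_arr[cur] - pos_arr[prev] < max_gap_bp:
                chains[-1].append(cur)
            else:
                chains.append([cur])
        for chain in chains:
            if len(chain) == 1:
                leftovers.append((comp.component, chain[0]))
            else:
                arr = np.asarray(chain)
                groups.append(
                    LocusGroup(
                        comp.component,
                        str(chrom_arr[arr[0]]),
                        arr,
                        int(pos_arr[arr[0]]),
                        int(pos_arr[arr[-1]]),
                    )
                )
    return groups, leftovers


# ---------------------------------------------------------------------------
# partition-ligation EM phasing


def _enumerate_pairs(genotype: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """All distinct unordered haplotype pairs compatible with one genotype row."""
    het = np.flatnonzero(genotype == 1)
    base = (genotype // 2).astype(np.uint8)
    if het.size == 0:
        return [(base, base.copy())]
    pairs = []
    # fix the first het site on hap1 to break the mirror symmetry
    for bits in range(1 << (het.size - 1)):
        h1 = base.copy()
        h2 = base.copy()
        h1[het[0]] = 1
        for j, site in enumerate(het[1:]):
            if (bits >> j) & 1:
                h1[site] = 1
            else:
                h2[site] = 1
        pairs.append((h1, h2))
    return pairs


def _em_pairs(
    pair_sample: np.ndarray,
    i1: np.ndarray,
    i2: np.ndarray,
    n_haps: int,
    sample_weight: np.ndarray,
    init_freqs: np.ndarray | None = None,
    kernel: np.ndarray | None = None,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """EM over per-sample compatible haplotype pairs.

    Returns (haplotype frequencies, per-pair posteriors, converged).
    ``sample_weight`` lets callers collapse samples with identical genotypes.
    When ``kernel`` is given — shape (n_sources, n_haps), K[i, j] ∝
    P(observe hap j | source hap i) under independent per-site errors — the
    model becomes mutation-tolerant haplotype copying: each observed
    candidate is a pool (source) haplotype with private errors, so frequency
    sharing survives when long candidate strings are nearly all unique.
    ``init_freqs`` and the returned frequencies then live on the sources,
    and per-candidate weights are the copying likelihoods kernelᵀ·f.
    """
    n_eff = float(sample_weight.sum())
    n_freq = n_haps if kernel is None else kernel.shape[0]
    if init_freqs is None:
        freqs = np.full(n_freq, 1.0 / n_freq)
    else:
        freqs = init_freqs / init_freqs.sum()
    mult = np.where(i1 == i2, 1.0, 2.0)
    converged = False
    post = np.empty_like(mult)
    for _ in range(max_iter):
        g = freqs if kernel is None else kernel.T @ freqs
        w = mult * g[i1] * g[i2]
        denom = np.bincount(pair_sample, weights=w, minlength=int(pair_sample.max()) + 1)
        post = w / np.maximum(denom[pair_sample], 1e-300)
        wp = post * sample_weight[pair_sample]
        obs = np.bincount(i1, weights=wp, minlength=n_haps) + np.bincount(
            i2, weights=wp, minlength=n_haps
        )
        if kernel is None:
            counts = obs
        else:
            # redistribute observed-candidate mass to source haplotypes
            counts = (kernel * freqs[:, None] / np.maximum(g, 1e-300)[None, :]) @ obs
        new = counts / (2.0 * n_eff)
        if np.abs(new - freqs).max() < tol:
            freqs = new
            converged = True
            break
        freqs = new
    return freqs, post, converged


@dataclass
class _Segment:
    haps: np.ndarray        # (n_h, L) uint8
    freqs: np.ndarray       # (n_h,)
    pair_sample: np.ndarray
    pair_i1: np.ndarray
    pair_i2: np.ndarray
    pair_post: np.ndarray
    converged: bool


def _phase_segment(genotypes: np.ndarray) -> _Segment:
    """Exhaustive-enumeration EM within one window (<= ``window`` SNPs)."""
    n = genotypes.shape[0]
    uniq, inverse = np.unique(genotypes, axis=0, return_inverse=True)
    weight = np.bincount(inverse, minlength=uniq.shape[0]).astype(float)
    hap_index: dict[bytes, int] = {}
    haps: list[np.ndarray] = []

    def hap_id(h: np.ndarray) -> int:
        key = h.tobytes()
        if key not in hap_index:
            hap_index[key] = len(haps)
            haps.append(h)
        return hap_index[key]

    ps, p1, p2 = [], [], []
    for u in range(uniq.shape[0]):
        for h1, h2 in _enumerate_pairs(uniq[u]):
            ps.append(u)
            p1.append(hap_id(h1))
            p2.append(hap_id(h2))
    pair_u = np.asarray(ps)
    i1 = np.asarray(p1)
    i2 = np.asarray(p2)
    freqs, post_u, converged = _em_pairs(pair_u, i1, i2, len(haps), weight)
    # expand unique-genotype pairs back to per-sample pairs
    per_u: dict[int, np.ndarray] = {
        u: np.flatnonzero(pair_u == u) for u in range(uniq.shape[0])
    }
    s_list, i1_list, i2_list, post_list = [], [], [], []
    for s in range(n):
        rows = per_u[inverse[s]]
        s_list.append(np.full(rows.size, s))
        i1_list.append(i1[rows])
        i2_list.append(i2[rows])
        post_list.append(post_u[rows])
    return _Segment(
        np.vstack(haps),
        freqs,
        np.concatenate(s_list),
        np.concatenate(i1_list),
        np.concatenate(i2_list),
        np.concatenate(post_list),
        converged,
    )


def _top_pairs(seg: _Segment, n: int, cap: int, min_post: float) -> list[np.ndarray]:
    """Per sample, row indices of its highest-posterior pairs."""
    out: list[np.ndarray] = []
    order = np.argsort(seg.pair_sample, kind="stable")
    bounds = np.searchsorted(seg.pair_sample[order], np.arange(n + 1))
    for s in range(n):
        rows = order[bounds[s]:bounds[s + 1]]
        rows = rows[np.argsort(-seg.pair_post[rows], kind="stable")]
        keep = rows[seg.pair_post[rows] >= min_post][:cap]
        if keep.size == 0:
            keep = rows[:1]
        out.append(keep)
    return out


def _hamming_kernel(sources: np.ndarray, haps: np.ndarray, error_rate: float) -> np.ndarray:
    """K[i, j] = (e/(1-e))^hamming(source i, hap j): per-site-error emission,
    up to a constant common factor that cancels in the EM posteriors."""
    s = sources.astype(np.float32)
    h = haps.astype(np.float32)
    d = s @ (1.0 - h).T + (1.0 - s) @ h.T
    return (error_rate / (1.0 - error_rate)) ** d


def _ligate(
    a: _Segment,
    b: _Segment,
    n: int,
    cap: int = 8,
    min_post: float = 0.01,
    error_rate: float = 0.03,
) -> _Segment:
    """Merge two adjacent segments by EM over concatenated candidate pairs.

    The EM uses the mutation-tolerant emission (see :func:`_em_pairs`):
    concatenated candidates on long segments are nearly all unique, so exact
    string matching would leave the two orientations of a double-heterozygous
    sample unresolved; copying-with-error restores frequency sharing."""
    hap_index: dict[bytes, int] = {}
    haps: list[np.ndarray] = []
    init_weight: list[float] = []

    def hap_id(h: np.ndarray, w: float) -> int:
        key = h.tobytes()
        if key not in hap_index:
            hap_index[key] = len(haps)
            haps.append(h)
            init_weight.append(w)
        return hap_index[key]

    rows_a = _top_pairs(a, n, cap, min_post)
    rows_b = _top_pairs(b, n, cap, min_post)
    ps, p1, p2 = [], [], []
    for s in range(n):
        seen = set()
        for ra in rows_a[s]:
            a1, a2 = a.pair_i1[ra], a.pair_i2[ra]
            for rb in rows_b[s]:
                b1, b2 = b.pair_i1[rb], b.pair_i2[rb]
                for (x1, y1), (x2, y2) in (((a1, b1), (a2, b2)), ((a1, b2), (a2, b1))):
                    h1 = np.concatenate([a.haps[x1], b.haps[y1]])
                    h2 = np.concatenate([a.haps[x2], b.haps[y2]])
                    j1 = hap_id(h1, float(a.freqs[x1] * b.freqs[y1]))
                    j2 = hap_id(h2, float(a.freqs[x2] * b.freqs[y2]))
                    key = (min(j1, j2), max(j1, j2))
                    if key in seen:
                        continue
                    seen.add(key)
                    ps.append(s)
                    p1.append(key[0])
                    p2.append(key[1])
    pair_sample = np.asarray(ps)
    i1 = np.asarray(p1)
    i2 = np.asarray(p2)
    init = np.asarray(init_weight) + 1e-9
    hap_arr = np.vstack(haps)
    if error_rate > 0:
        # EM sources: the most plausible pool haplotypes by product weight
        n_src = min(64, len(haps))
        src = np.sort(np.argsort(-init, kind="stable")[:n_src])
        kernel = _hamming_kernel(hap_arr[src], hap_arr, error_rate)
        src_freqs, post, converged = _em_pairs(
            pair_sample, i1, i2, len(haps), np.ones(n),
            init_freqs=init[src], kernel=kernel, max_iter=200, tol=1e-6,
        )
        # per-candidate plausibility for downstream init products
        g = kernel.T @ src_freqs
        freqs = g / g.sum()
    else:
        freqs, post, converged = _em_pairs(
            pair_sample, i1, i2, len(haps), np.ones(n), init_freqs=init
        )
    return _Segment(
        hap_arr, freqs, pair_sample, i1, i2, post,
        converged and a.converged and b.converged,
    )


def phase_em(
    genotypes: np.ndarray,
    window: int = 8,
    seed: int = 0,
    error_rate: float = 0.03,
) -> PhasedLocus:
    """Phase one locus (samples x SNPs additive genotypes, no missing values).

    Frequencies are estimated exhaustively when the locus fits in one window,
    so small loci reproduce plain EM over all compatible phasings exactly.
    For longer loci, adjacent windows are ligated pairwise (hierarchically),
    keeping the runtime linear in the number of SNPs at fixed window size;
    the ligation EM emits candidate haplotypes from pool haplotypes with an
    independent per-site error (``error_rate``), which keeps frequency
    sharing alive when long haplotypes carry private mutations.
    The output always satisfies haplotype-pair/genotype consistency.
    """
    genotypes = np.asarray(genotypes)
    if (genotypes < 0).any():
        raise ValueError("phase_em requires imputed (no-missing) genotypes")
    n, L = genotypes.shape
    segments = [
        _phase_segment(genotypes[:, a:min(a + window, L)])
        for a in range(0, L, window)
    ]
    while len(segments) > 1:
        merged = []
        for i in range(0, len(segments) - 1, 2):
            merged.append(_ligate(segments[i], segments[i + 1], n, error_rate=error_rate))
        if len(segments) % 2:
            merged.append(segments[-1])
        segments = merged
    seg = segments[0]
    if not seg.converged:
        warnings.warn("phasing EM did not fully converge; keeping best likelihood")
    haplotypes = np.empty((2 * n, L), dtype=np.uint8)
    order = np.argsort(seg.pair_sample, kind="stable")
    bounds = np.searchsorted(seg.pair_sample[order], np.arange(n + 1))
    for s in range(n):
        rows = order[bounds[s]:bounds[s + 1]]
        best = rows[np.argmax(seg.pair_post[rows])]
        haplotypes[2 * s] = seg.haps[seg.pair_i1[best]]
        haplotypes[2 * s + 1] = seg.haps[seg.pair_i2[best]]
    assert (haplotypes[0::2].astype(int) + haplotypes[1::2].astype(int) == genotypes).all(), (
        "phased haplotype pairs must sum to genotypes"
    )
    freqs = {h.tobytes(): float(f) for h, f in zip(seg.haps, seg.freqs) if f > 1e-12}
    return PhasedLocus(haplotypes, freqs, seg.converged)


# ---------------------------------------------------------------------------
# 2-class haplotype grouping


def classify_haplotypes(phased: PhasedLocus, locus: LocusGroup, seed: int = 0) -> HaplotypeFeature:
    """Group the 2n haplotypes into two classes and count class-2 per sample.

    The haplotypes are projected on their own first principal component and a
    2-component Gaussian mixture assigns classes by maximum posterior.
    Class 1 is the more frequent class; on a tie, the class containing the
    lexicographically smallest haplotype.
    """
    H = phased.haplotypes.astype(float)
    if np.ptp(H, axis=0).max() == 0:
        raise DegenerateLocusError("all inferred haplotypes identical")
    Hc = H - H.mean(axis=0)
    u, s, vt = np.linalg.svd(Hc, full_matrices=False)
    proj = u[:, 0] * s[0]
    fit = fit_gmm_1d(proj, 2, seed)
    assigned = fit.posteriors.argmax(axis=1)  # 0/1
    freq1 = float(np.mean(assigned == 0))
    if freq1 > 0.5:
        major = 0
    elif freq1 < 0.5:
        major = 1
    else:  # tie: the class holding the lexicographically smallest haplotype is class 1
        rows = [phased.haplotypes[assigned == c] for c in (0, 1)]
        smallest = [min(r.tobytes() for r in rr) for rr in rows]
        major = 0 if smallest[0] <= smallest[1] else 1
    classes = np.where(assigned == major, 1, 2).astype(np.int8)
    per_sample = (classes.reshape(-1, 2) == 2).sum(axis=1).astype(np.int8)
    freqs = (float(np.mean(classes == 1)), float(np.mean(classes == 2)))
    return HaplotypeFeature(locus, classes, per_sample, freqs)


def prune_correlated(
    features: list[HaplotypeFeature], r2_max: float = 0.8
) -> list[HaplotypeFeature]:
    """Drop a haplotype feature when its count vector has r² strictly above
    ``r2_max`` with a retained feature on the same chromosome.

    Deterministic scan in (component, start_bp) order; zero-variance
    features are dropped with a warning.
    """
    ordered = sorted(features, key=lambda f: (f.locus.component, f.locus.start_bp))
    kept: list[HaplotypeFeature] = []
    for feat in ordered:
        x = feat.per_sample_count.astype(float)
        if x.std() == 0.0:
            warnings.warn(
                f"haplotype feature {feat.locus.chrom}:{feat.locus.start_bp} has zero variance; dropped"
            )
            continue
        redundant = False
        for other in kept:
            if other.locus.chrom != feat.locus.chrom:
                continue
            r = np.corrcoef(x, other.per_sample_count.astype(float))[0, 1]
            if r * r > r2_max:
                redundant = True
                break
        if not redundant:
            kept.append(feat)
    return kept


# ---------------------------------------------------------------------------
# orchestration


def build_feature_matrix(
    g: GenotypeData,
    selected: SelectionResult,
    params: SummarizationParams | None = None,
) -> FeatureMatrix:
    """Loci -> phasing -> 2-class grouping -> pruning -> SNP/haplotype union.

    ``g`` must be the imputed genotype data whose SNP table the selection
    indices refer to.  Per-locus failures demote the locus back to single
    SNPs instead of aborting the run.
    """
    params = params or SummarizationParams()
    if len(g.snps) != len(selected.snps):
        raise ValueError("selection does not match the genotype SNP table")
    groups, leftovers = group_loci(selected, g.snps, params.max_gap_bp)
    features: list[HaplotypeFeature] = []
    for grp in groups:
        sub = g.genotypes[:, grp.snp_indices].astype(np.int64)
        phased = phase_em(sub, window=params.phase_window, seed=params.seed)
        try:
            features.append(classify_haplotypes(phased, grp, seed=params.seed))
        except DegenerateLocusError:
            warnings.warn(
                f"locus {grp.chrom}:{grp.start_bp}-{grp.end_bp} degenerate; demoted to single SNPs"
            )
            leftovers.extend((grp.component, int(i)) for i in grp.snp_indices)
    kept = prune_correlated(features, params.r2_max)
    logger.info(
        "summarization: %d loci -> %d haplotype features (%d pruned), %d leftover SNP picks",
        len(groups), len(kept), len(features) - len(kept), len(leftovers),
    )

    # deduplicate leftover SNPs across components by snp_id, keeping first
    seen: set[str] = set()
    snp_cols: list[int] = []
    snp_comp: list[int] = []
    for comp_index, snp_index in sorted(leftovers, key=lambda t: (t[0], t[1])):
        sid = g.snps["snp_id"].iloc[snp_index]
        if sid in seen:
            continue
        seen.add(sid)
        snp_cols.append(snp_index)
        snp_comp.append(comp_index)

    values = np.empty((g.n_samples, len(snp_cols) + len(kept)), dtype=np.int8)
    records = []
    for out_j, (snp_index, comp_index) in enumerate(zip(snp_cols, snp_comp)):
        values[:, out_j] = g.genotypes[:, snp_index]
        row = g.snps.iloc[snp_index]
        records.append(
            (row["snp_id"], "snp", row["chrom"], row["pos_bp"], row["pos_bp"], comp_index, 1)
        )
    for out_j, feat in enumerate(kept, start=len(snp_cols)):
        values[:, out_j] = feat.per_sample_count
        loc = feat.locus
        records.append(
            (
                f"hap:{loc.chrom}:{loc.start_bp}-{loc.end_bp}:{loc.component}",
                "hap", loc.chrom, loc.start_bp, loc.end_bp, loc.component, loc.n_snps,
            )
        )
    features_df = pd.DataFrame(
        records,
        columns=["feature_id", "kind", "chrom", "start_bp", "end_bp", "component", "n_snps"],
    )
    return FeatureMatrix(values, features_df, g.samples["sample_id"])
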