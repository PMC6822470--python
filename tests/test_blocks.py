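import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phaseblocks as pb
from phaseblocks.blocks import (
    LDClass,
    MonomorphicSiteError,
    _genotype_class_probs,
    genotype_log_likelihood,
    two_locus_table,
)
from phaseblocks.simulate import SimConfig, simulate_truth


# ---------------------------------------------------------------------------
# sliding windows

def brute_force_windows(m, w, step):
    return [(s, s + w) for s in range(0, m - w + 1, step) if (s % step) == 0 and s // step * step == s]


@pytest.mark.parametrize(
    "m,w,step,expected",
    [
        (10, 3, 1, 8),
        (10, 10, 1, 1),
        (10, 5, 1, 6),
        (100, 5, 7, None),  # compare against enumeration
    ],
)
def test_sliding_window_counts(m, w, step, expected):
    bs = pb.sliding_windows(m, w, step)
    starts = [b.start_idx for b in bs]
    brute = [s for s in range(0, m, step) if s + w <= m]
    assert starts == brute
    if expected is not None:
        assert len(bs) == expected
    assert all(b.end_idx - b.start_idx == w for b in bs)


def test_window_wider_than_panel_gives_empty_set():
    assert len(pb.sliding_windows(5, 9)) == 0


@settings(derandomize=True, max_examples=100)
@given(st.integers(1, 200).flatmap(lambda m: st.tuples(st.just(m), st.integers(1, m))))
def test_window_count_law(mw):
    """|blocks| = m - w + 1 for unit step, for all m <= 200."""
    m, w = mw
    assert len(pb.sliding_windows(m, w, 1)) == m - w + 1


# ---------------------------------------------------------------------------
# EM haplotype frequencies

def test_em_without_double_hets_equals_direct_count():
    # 10x (0,0), 6x (1,0), 4x (2,2): haplotypes countable by hand
    table = np.zeros((3, 3), dtype=int)
    table[0, 0], table[1, 0], table[2, 2] = 10, 6, 4
    f00, f01, f10, f11 = pb.em_haplotype_freqs(table)
    n_hap = 40
    assert f00 == pytest.approx(26 / n_hap, abs=1e-9)
    assert f10 == pytest.approx(6 / n_hap, abs=1e-9)
    assert f11 == pytest.approx(8 / n_hap, abs=1e-9)
    assert f01 == pytest.approx(0.0, abs=1e-9)


def test_em_perfect_coupling():
    table = np.zeros((3, 3), dtype=int)
    table[0, 0] = table[2, 2] = 50
    f00, f01, f10, f11 = pb.em_haplotype_freqs(table)
    assert f00 == pytest.approx(0.5, abs=1e-9)
    assert f11 == pytest.approx(0.5, abs=1e-9)
    assert f01 == pytest.approx(0.0, abs=1e-9) and f10 == pytest.approx(0.0, abs=1e-9)


def test_em_frequencies_sum_to_one_and_match_margins(rng):
    for _ in range(20):
        probs = rng.dirichlet(np.ones(4))
        haps = rng.choice(4, size=(200, 2), p=probs)
        g1 = (haps // 2).sum(axis=1)
        g2 = (haps % 2).sum(axis=1)
        table = two_locus_table(g1, g2)
        try:
            f = pb.em_haplotype_freqs(table)
        except MonomorphicSiteError:
            continue
        assert sum(f) == pytest.approx(1.0, abs=1e-8)
        p_hat = f[2] + f[3]
        assert p_hat == pytest.approx(g1.sum() / 400, abs=1e-8)


def test_em_monomorphic_is_signalled():
    table = np.zeros((3, 3), dtype=int)
    table[0, 0] = 7
    with pytest.raises(MonomorphicSiteError):
        pb.em_haplotype_freqs(table)


def test_em_likelihood_dominates_random_feasible_sets(rng):
    """EM's solution has log-likelihood >= 1000 random frequency vectors."""
    for _ in range(10):
        probs = rng.dirichlet(np.ones(4) * 2)
        haps = rng.choice(4, size=(150, 2), p=probs)
        g1 = (haps // 2).sum(axis=1)
        g2 = (haps % 2).sum(axis=1)
        table = two_locus_table(g1, g2)
        try:
            f_em = pb.em_haplotype_freqs(table)
        except MonomorphicSiteError:
            continue
        ll_em = genotype_log_likelihood(table, f_em)
        rand = rng.dirichlet(np.ones(4), size=1000)
        ll_rand = max(genotype_log_likelihood(table, tuple(r)) for r in rand)
        assert ll_em >= ll_rand - 1e-9


# ---------------------------------------------------------------------------
# D' confidence interval

def naive_dprime_ci(x, y, from_phased, grid_step=0.001, coverage=0.90):
    """Independent re-derivation of the grid CI with naive summation."""
    x = np.asarray(x)
    y = np.asarray(y)
    if from_phased:
        n = len(x)
        p = float(np.mean(x))
        q = float(np.mean(y))
        f11_obs = float(np.mean((x == 1) & (y == 1)))
        d_hat = f11_obs - p * q
    else:
        table = two_locus_table(x, y)
        f = pb.em_haplotype_freqs(table)
        p = f[2] + f[3]
        q = f[1] + f[3]
        d_hat = f[3] - p * q
    sign = 1 if d_hat >= 0 else -1
    dmax = min(p * (1 - q), (1 - p) * q) if sign > 0 else min(p * q, (1 - p) * (1 - q))
    grid = [k * grid_step for k in range(int(round(1 / grid_step)) + 1)]
    lls = []
    for dp in grid:
        d = dp * dmax * sign
        f11 = p * q + d
        f10 = p * (1 - q) - d
        f01 = (1 - p) * q - d
        f00 = (1 - p) * (1 - q) + d
        fr = [max(v, 0.0) for v in (f00, f01, f10, f11)]
        ll = 0.0
        if from_phased:
            counts = [
                int(np.sum((x == a) & (y == b))) for a in (0, 1) for b in (0, 1)
            ]  # order f00,f01,f10,f11
            for c, fv in zip(counts, fr):
                if c:
                    ll += c * (math.log(fv) if fv > 0 else -math.inf)
        else:
            P = _genotype_class_probs(*fr)
            for g1 in range(3):
                for g2 in range(3):
                    c = table[g1, g2]
                    if c:
                        pr = float(P[g1, g2])
                        ll += c * (math.log(pr) if pr > 0 else -math.inf)
        lls.append(ll)
    mx = max(l for l in lls if math.isfinite(l))
    ws = [math.exp(l - mx) if math.isfinite(l) else 0.0 for l in lls]
    total = math.fsum(ws)
    cum, lo, hi = 0.0, None, None
    tail = (1 - coverage) / 2
    weights = []
    for g, w in zip(grid, ws):
        cum += w / total
        weights.append(w / total)
        if lo is None and cum > tail:
            lo = g
        if hi is None and cum > 1 - tail:
            hi = g
    return lo, hi if hi is not None else grid[-1], weights


def test_ci_bounds_match_naive_grid_normalisation(rng):
    """Implementation CI bounds equal an independent naive-summation grid
    normalisation, phased and unphased."""
    for trial in range(8):
        probs = rng.dirichlet(np.ones(4) * 1.5)
        haps = rng.choice(4, size=(120, 2), p=probs)
        g1 = (haps // 2).sum(axis=1)
        g2 = (haps % 2).sum(axis=1)
        hap1 = (haps // 2).ravel()
        hap2 = (haps % 2).ravel()
        for from_phased, xx, yy in [(False, g1, g2), (True, hap1, hap2)]:
            try:
                got = pb.dprime_ci(xx, yy, from_phased=from_phased)
            except MonomorphicSiteError:
                continue
            lo, hi, _ = naive_dprime_ci(xx, yy, from_phased)
            assert got.ci_low == pytest.approx(lo, abs=1e-12)
            assert got.ci_high == pytest.approx(hi, abs=1e-12)


def test_perfect_coupling_boundary():
    """100 individuals carrying only ref/ref and alt/alt haplotypes: D' = 1
    and the CI top reaches 1."""
    x = np.array([0] * 100 + [1] * 100)
    y = x.copy()
    got = pb.dprime_ci(x, y, from_phased=True)
    assert got.dprime_hat == pytest.approx(1.0)
    assert got.ci_high == pytest.approx(1.0)
    assert got.cls is LDClass.STRONG_LD


def test_independent_loci_classed_recomb(rng):
    """Two independent common loci at large n are classified RECOMB nearly
    always (checked over replicates)."""
    hits = 0
    n_rep = 60
    for _ in range(n_rep):
        x = rng.integers(0, 2, size=2000)
        y = rng.integers(0, 2, size=2000)
        got = pb.dprime_ci(x, y, from_phased=True)
        hits += got.cls is LDClass.RECOMB
    assert hits >= int(0.9 * n_rep)


def test_dprime_invariant_to_allele_labels_and_locus_swap(rng):
    probs = np.array([0.4, 0.15, 0.1, 0.35])
    haps = rng.choice(4, size=(150, 2), p=probs)
    g1 = (haps // 2).sum(axis=1).astype(np.int8)
    g2 = (haps % 2).sum(axis=1).astype(np.int8)
    base = pb.dprime_ci(g1, g2)
    for xx, yy in [(2 - g1, g2), (g1, 2 - g2), (2 - g1, 2 - g2), (g2, g1)]:
        other = pb.dprime_ci(xx, yy)
        assert other.dprime_hat == pytest.approx(base.dprime_hat, abs=1e-9)
        assert other.ci_low == pytest.approx(base.ci_low, abs=1e-12)
        assert other.ci_high == pytest.approx(base.ci_high, abs=1e-12)


def test_duplicating_sample_never_widens_ci(rng):
    for _ in range(5):
        probs = rng.dirichlet(np.ones(4) * 1.5)
        haps = rng.choice(4, size=(80, 2), p=probs)
        g1 = (haps // 2).sum(axis=1)
        g2 = (haps % 2).sum(axis=1)
        try:
            one = pb.dprime_ci(g1, g2)
            two = pb.dprime_ci(np.tile(g1, 2), np.tile(g2, 2))
        except MonomorphicSiteError:
            continue
        assert (two.ci_high - two.ci_low) <= (one.ci_high - one.ci_low) + 1e-12


# ---------------------------------------------------------------------------
# LD blocks

def test_two_coupled_snps_form_one_block():
    rngl = np.random.default_rng(4)
    picks = rngl.integers(0, 2, size=(100, 2)).astype(np.int8)  # per individual per copy
    alleles = np.repeat(picks[:, None, :], 2, axis=1)  # each copy is (0,0) or (1,1)
    panel = pb.HaplotypePanel(
        [f"s{i}" for i in range(100)],
        pb.VariantMap.default(2, spacing_bp=5000),
        alleles,
    )
    bs = pb.ld_blocks(pb.genotypes_from_haplotypes(panel))
    assert [(b.start_idx, b.end_idx) for b in bs.blocks] == [(0, 2)]


def test_cassette_structure_recovered():
    panel, true_blocks = simulate_truth(SimConfig(n_sites=10, block_snps=5, seed=11))
    bs = pb.ld_blocks(pb.genotypes_from_haplotypes(panel))
    assert [(b.start_idx, b.end_idx) for b in bs.blocks] == [
        (b.start_idx, b.end_idx) for b in true_blocks.blocks
    ]


def test_low_maf_snp_inside_cassette_does_not_change_retained_composition():
    """A rare SNP inserted inside a cassette is MAF-filtered and the block's
    retained SNPs are unchanged."""
    panel, _ = simulate_truth(SimConfig(n_sites=10, block_snps=5, seed=21))
    geno = pb.genotypes_from_haplotypes(panel)
    rare = np.zeros((geno.n_samples, 1), dtype=np.int8)
    rare[0, 0] = 1  # MAF = 1/400
    pos = np.concatenate([geno.variants.pos[:3], [geno.variants.pos[2] + 500],
                          geno.variants.pos[3:]])
    v2 = pb.VariantMap(
        chrom=["1"] * 11, pos=pos, vid=[f"v{i}" for i in range(11)],
        ref=["A"] * 11, alt=["G"] * 11,
    )
    dosage = np.concatenate([geno.dosage[:, :3], rare, geno.dosage[:, 3:]], axis=1)
    geno2 = pb.GenotypePanel(geno.samples, v2, dosage)
    base = pb.ld_blocks(geno)
    with_rare = pb.ld_blocks(geno2)

    def retained_positions(bs, variants):
        out = []
        for b in bs.blocks:
            out.append(tuple(int(p) for p in variants.pos[b.start_idx:b.end_idx]
                             if p != pos[3]))
        return out

    assert retained_positions(with_rare, v2) == retained_positions(base, geno.variants)


def test_ld_blocks_never_overlap_and_respect_distance():
    panel, _ = simulate_truth(SimConfig(n_sites=30, block_snps=6, seed=31))
    bs = pb.ld_blocks(pb.genotypes_from_haplotypes(panel))
    prev_end = -1
    for b in bs.blocks:
        assert b.start_idx >= prev_end
        prev_end = b.end_idx
        assert b.end_bp - b.start_bp <= 200_000


def test_all_sites_filtered_gives_empty_set():
    dosage = np.zeros((50, 4), dtype=np.int8)
    dosage[0, :] = 1  # MAF = 1/100 < 0.05 everywhere
    geno = pb.GenotypePanel([f"s{i}" for i in range(50)], pb.VariantMap.default(4), dosage)
    bs = pb.ld_blocks(geno)
    assert len(bs) == 0
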