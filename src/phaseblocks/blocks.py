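"""Haplotype-block determination.

Two block definitions are provided: a fixed-width sliding window (every
window of ``w`` SNPs, shifted ``step`` SNPs at a time, is a block) and the
D' confidence-interval algorithm of Gabriel et al. as ported by PLINK's
``--blocks``: SNP pairs whose 90% D' CI has lower bound > 0.70 and upper
bound > 0.98 are in strong LD, pairs with CI top < 0.90 show historical
recombination, and maximal spans whose informative pairs are ≥ 95% strong LD
become blocks (longest first, non-overlapping).

LD is computed from unphased genotypes by default, estimating two-locus
haplotype frequencies with an EM under random mating; a ``from_phased`` path
uses haplotypes directly.
"""
from __future__ import annotations

import dataclasses
import enum
import logging
import math
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from .model import MISSING, GenotypePanel, HaplotypePanel, VariantMap

logger = logging.getLogger(__name__)


class MonomorphicSiteError(ValueError):
    """LD is undefined when either locus is monomorphic in the sample."""


@dataclasses.dataclass
class Block:
    """A contiguous run of sites, half-open in 0-based site indices."""

    start_idx: int
    end_idx: int
    chrom: Optional[str] = None
    start_bp: int = 0
    end_bp: int = 0

    def __post_init__(self) -> None:
        if self.end_idx <= self.start_idx:
            raise ValueError("Block requires end_idx > start_idx")

    @property
    def n_snps(self) -> int:
        return self.end_idx - self.start_idx

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclasses.dataclass
class BlockSet:
    """An ordered collection of blocks plus the parameters that produced it."""

    method: str
    parameters: dict
    blocks: list

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def __getitem__(self, i: int) -> Block:
        return self.blocks[i]


class LDClass(enum.Enum):
    STRONG_LD = "strong"
    RECOMB = "recomb"
    UNINFORMATIVE = "uninformative"


@dataclasses.dataclass
class LDPairClass:
    """D' point estimate, 90% CI bounds, and the Gabriel classification of a pair."""

    i: int
    j: int
    dprime_hat: float
    ci_low: float
    ci_high: float
    cls: LDClass


def sliding_windows(
    n_sites: int,
    w: int,
    step: int = 1,
    variants: Optional[VariantMap] = None,
) -> BlockSet:
    """All windows ``[k*step, k*step + w)`` that fit in ``n_sites`` sites.

    With ``step=1`` this yields exactly ``n_sites - w + 1`` blocks.
    """
    if w < 1 or step < 1:
        raise ValueError("w and step must be >= 1")
    blocks = []
    if w > n_sites:
        logger.warning("window width %d exceeds site count %d; empty block set", w, n_sites)
    else:
        k = 0
        while k * step + w <= n_sites:
            s, e = k * step, k * step + w
            if variants is not None:
                blocks.append(
                    Block(s, e, str(variants.chrom[s]), int(variants.pos[s]), int(variants.pos[e - 1]))
                )
            else:
                blocks.append(Block(s, e))
            k += 1
    return BlockSet(method="sliding", parameters={"w": w, "step": step}, blocks=blocks)


# ---------------------------------------------------------------------------
# two-locus EM

def two_locus_table(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 table of joint genotype-dosage counts, missing pairs dropped."""
    ok = (g1 != MISSING) & (g2 != MISSING)
    tab = np.zeros((3, 3), dtype=np.int64)
    np.add.at(tab, (g1[ok].astype(int), g2[ok].astype(int)), 1)
    return tab


def em_haplotype_freqs(
    table: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> Tuple[float, float, float, float]:
    """EM estimates of the four two-locus haplotype frequencies.

    ``table[g1, g2]`` counts individuals with those dosages.  Returns
    ``(f00, f01, f10, f11)`` where ``f_ab`` is the frequency of the
    haplotype carrying ``a`` alt alleles at locus 1 and ``b`` at locus 2.
    The only latent class is the double heterozygote, split between the two
    phase configurations at each E-step.  Raises
    :class:`MonomorphicSiteError` if either locus is monomorphic.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (3, 3):
        raise ValueError("expected a 3x3 genotype count table")
    n = t.sum()
    if n <= 0:
        raise ValueError("empty table")
    # marginal allele counts
    alt1 = t[1].sum() + 2 * t[2].sum()
    alt2 = t[:, 1].sum() + 2 * t[:, 2].sum()
    if alt1 == 0 or alt1 == 2 * n or alt2 == 0 or alt2 == 2 * n:
        raise MonomorphicSiteError("monomorphic locus; LD undefined")

    # fixed haplotype counts from unambiguous genotypes
    base = np.zeros((2, 2))
    for g1 in range(3):
        for g2 in range(3):
            c = t[g1, g2]
            if c == 0 or (g1 == 1 and g2 == 1):
                continue
            # each individual contributes two haplotypes with determined alleles
            a_list = [0, 0] if g1 == 0 else [1, 1] if g1 == 2 else [0, 1]
            b_list = [0, 0] if g2 == 0 else [1, 1] if g2 == 2 else [0, 1]
            if g1 == 1:  # g2 is hom: het locus splits across the two haplotypes
                base[0, b_list[0]] += c
                base[1, b_list[1]] += c
            elif g2 == 1:
                base[a_list[0], 0] += c
                base[a_list[1], 1] += c
            else:
                base[a_list[0], b_list[0]] += c
                base[a_list[1], b_list[1]] += c
    dh = t[1, 1]  # double heterozygotes: cis (00+11) or trans (01+10)

    # start from linkage equilibrium
    p = alt1 / (2 * n)
    q = alt2 / (2 * n)
    f = np.array([[(1 - p) * (1 - q), (1 - p) * q], [p * (1 - q), p * q]])
    for _ in range(max_iter):
        denom = f[0, 0] * f[1, 1] + f[0, 1] * f[1, 0]
        p_cis = 0.5 if denom <= 0 else (f[0, 0] * f[1, 1]) / denom
        new = base.copy()
        new[0, 0] += dh * p_cis
        new[1, 1] += dh * p_cis
        new[0, 1] += dh * (1 - p_cis)
        new[1, 0] += dh * (1 - p_cis)
        new /= 2 * n
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return float(f[0, 0]), float(f[0, 1]), float(f[1, 0]), float(f[1, 1])


def _genotype_class_probs(f00, f01, f10, f11):
    """HWE probabilities of the 9 two-locus genotype classes given haplotype
    frequencies (double het mixes the two phase configurations)."""
    P = np.empty((3, 3) + np.shape(f00))
    P[0, 0] = f00 ** 2
    P[0, 1] = 2 * f00 * f01
    P[0, 2] = f01 ** 2
    P[1, 0] = 2 * f00 * f10
    P[1, 2] = 2 * f01 * f11
    P[2, 0] = f10 ** 2
    P[2, 1] = 2 * f10 * f11
    P[2, 2] = f11 ** 2
    P[1, 1] = 2 * f00 * f11 + 2 * f01 * f10
    return P


def genotype_log_likelihood(table: np.ndarray, freqs) -> float:
    """Multinomial log-likelihood of a 3x3 genotype table under haplotype
    frequencies ``(f00, f01, f10, f11)`` and random mating."""
    P = _genotype_class_probs(*freqs)
    t = np.asarray(table, dtype=float)
    ll = 0.0
    for g1 in range(3):
        for g2 in range(3):
            c = t[g1, g2]
            if c > 0:
                pr = P[g1, g2]
                ll += c * (math.log(pr) if pr > 0 else -math.inf)
    return ll


def _implied_freqs(p: float, q: float, d: np.ndarray):
    """Haplotype frequencies implied by alt-allele frequencies and raw D
    (D = f11 - p*q); negatives are clipped to zero for boundary handling."""
    f11 = p * q + d
    f10 = p * (1 - q) - d
    f01 = (1 - p) * q - d
    f00 = (1 - p) * (1 - q) + d
    clip = lambda x: np.clip(x, 0.0, 1.0)
    return clip(f00), clip(f01), clip(f10), clip(f11)


def _dmax(p: float, q: float, sign: int) -> float:
    if sign >= 0:
        return min(p * (1 - q), (1 - p) * q)
    return min(p * q, (1 - p) * (1 - q))


def dprime_ci(
    x: np.ndarray,
    y: np.ndarray,
    from_phased: bool = False,
    grid_step: float = 0.001,
    coverage: float = 0.90,
    i: int = -1,
    j: int = -1,
    low_thresh: float = 0.70,
    high_thresh: float = 0.98,
    recomb_thresh: float = 0.90,
) -> LDPairClass:
    """D' point estimate, likelihood-based CI, and Gabriel classification.

    ``x`` and ``y`` are per-individual dosages (``from_phased=False``) or
    per-haplotype alleles (``from_phased=True``) at the two loci.  Allele
    frequencies and the sign of D are fixed at their sample MLEs; the
    likelihood of the data is evaluated on the ``|D'|`` grid
    ``{0, grid_step, ..., 1}``, normalised, and the CI bounds are the
    smallest grid values at which the cumulative normalised likelihood
    exceeds each symmetric tail probability.  A grid point implying a
    negative haplotype frequency gets likelihood zero.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if len(x) == 0:
        raise ValueError("no jointly called observations")

    if from_phased:
        counts = np.zeros((2, 2), dtype=np.int64)
        np.add.at(counts, (x.astype(int), y.astype(int)), 1)
        n_hap = counts.sum()
        p = counts[1].sum() / n_hap
        q = counts[:, 1].sum() / n_hap
        if p in (0.0, 1.0) or q in (0.0, 1.0):
            raise MonomorphicSiteError("monomorphic locus; LD undefined")
        d_hat = counts[1, 1] / n_hap - p * q
        table = None
    else:
        table = two_locus_table(x, y)
        f00, f01, f10, f11 = em_haplotype_freqs(table)
        p = f10 + f11
        q = f01 + f11
        d_hat = f11 - p * q
        counts = None

    sign = 1 if d_hat >= 0 else -1
    dmax = _dmax(p, q, sign)
    if dmax <= 0:
        raise MonomorphicSiteError("degenerate allele frequencies; LD undefined")
    dprime_hat = min(abs(d_hat) / dmax, 1.0)

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    d = grid * dmax * sign
    f00g, f01g, f10g, f11g = _implied_freqs(p, q, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        if from_phased:
            logf = [np.log(f00g), np.log(f01g), np.log(f10g), np.log(f11g)]
            cts = [counts[0, 0], counts[0, 1], counts[1, 0], counts[1, 1]]
            ll = np.zeros_like(grid)
            for c, lf in zip(cts, logf):
                if c > 0:
                    ll = ll + c * lf
        else:
            P = _genotype_class_probs(f00g, f01g, f10g, f11g)
            ll = np.zeros_like(grid)
            for g1 in range(3):
                for g2 in range(3):
                    c = table[g1, g2]
                    if c > 0:
                        ll = ll + c * np.log(P[g1, g2])
    ll = np.where(np.isnan(ll), -np.inf, ll)
    finite = np.isfinite(ll)
    if not finite.any():
        raise ValueError("likelihood vanished on the whole D' grid")
    w = np.zeros_like(grid)
    w[finite] = np.exp(ll[finite] - ll[finite].max())
    w /= w.sum()
    cum = np.cumsum(w)
    tail = (1.0 - coverage) / 2.0
    ci_low = float(grid[np.searchsorted(cum, tail, side="right")])
    hi_idx = np.searchsorted(cum, 1.0 - tail, side="right")
    ci_high = float(grid[min(hi_idx, len(grid) - 1)])

    if ci_low > low_thresh and ci_high > high_thresh:
        cls = LDClass.STRONG_LD
    elif ci_high < recomb_thresh:
        cls = LDClass.RECOMB
    else:
        cls = LDClass.UNINFORMATIVE
    return LDPairClass(i=i, j=j, dprime_hat=float(dprime_hat), ci_low=ci_low, ci_high=ci_high, cls=cls)


def ld_blocks(
    panel: Union[GenotypePanel, HaplotypePanel],
    maf_min: float = 0.05,
    max_dist_bp: int = 200_000,
    low_thresh: float = 0.70,
    high_thresh: float = 0.98,
    recomb_thresh: float = 0.90,
    informative_frac: float = 0.95,
    coverage: float = 0.90,
    grid_step: float = 0.001,
    from_phased: bool = False,
) -> BlockSet:
    """Gabriel-style D'-CI haplotype blocks.

    Sites with MAF below ``maf_min`` are dropped; every retained same-
    chromosome pair within ``max_dist_bp`` is classified with
    :func:`dprime_ci`; candidate spans are strong-LD pairs, kept when the
    strong-LD fraction among their informative interior pairs reaches
    ``informative_frac`` (a 2-SNP span needs only its own pair); candidates
    are then accepted greedily by bp length (ties: more SNPs, then leftmost)
    without overlap.  Blocks carry original site indices.
    """
    if isinstance(panel, HaplotypePanel):
        if from_phased:
            hap_panel = panel
            geno = None
        else:
            from .hapio import genotypes_from_haplotypes

            geno = genotypes_from_haplotypes(panel)
            hap_panel = None
    else:
        if from_phased:
            raise ValueError("from_phased requires a HaplotypePanel")
        geno = panel
        hap_panel = None

    variants = panel.variants
    if from_phased:
        alle = hap_panel.alleles
        called = alle[:, :, 0] != MISSING
        alt = np.where(alle == MISSING, 0, alle).sum(axis=(0, 2))
        n_alleles = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pfreq = alt / n_alleles
        maf = np.minimum(pfreq, 1 - pfreq)
    else:
        maf = geno.maf()
    keep = np.nonzero(np.nan_to_num(maf, nan=0.0) >= maf_min)[0]
    params = {
        "maf_min": maf_min, "max_dist_bp": max_dist_bp, "low_thresh": low_thresh,
        "high_thresh": high_thresh, "recomb_thresh": recomb_thresh,
        "informative_frac": informative_frac, "coverage": coverage,
    }
    if len(keep) < 2:
        logger.warning("fewer than two sites pass the MAF filter; empty block set")
        return BlockSet(method="ld", parameters=params, blocks=[])

    r = len(keep)
    # classify retained pairs within distance; matrix over retained indices
    STRONG, RECOMB, OTHER = 2, 1, 0
    cls = np.full((r, r), -1, dtype=np.int8)  # -1 = not evaluated (too far)
    for a in range(r):
        ia = keep[a]
        for b in range(a + 1, r):
            ib = keep[b]
            if variants.chrom[ia] != variants.chrom[ib]:
                continue
            if variants.pos[ib] - variants.pos[ia] > max_dist_bp:
                break  # positions ascending: all further b are too far
            if from_phased:
                xa = hap_panel.alleles[:, ia, :].reshape(-1)
                xb = hap_panel.alleles[:, ib, :].reshape(-1)
            else:
                xa = geno.dosage[:, ia]
                xb = geno.dosage[:, ib]
            try:
                pc = dprime_ci(
                    xa, xb, from_phased=from_phased, grid_step=grid_step,
                    coverage=coverage, i=int(ia), j=int(ib),
                    low_thresh=low_thresh, high_thresh=high_thresh,
                    recomb_thresh=recomb_thresh,
                )
            except MonomorphicSiteError:
                continue
            code = (
                STRONG if pc.cls is LDClass.STRONG_LD
                else RECOMB if pc.cls is LDClass.RECOMB
                else OTHER
            )
            cls[a, b] = cls[b, a] = code

    # candidate spans: strong-LD endpoint pairs
    candidates = []
    for a in range(r):
        for b in range(a + 1, r):
            if cls[a, b] != STRONG:
                continue
            sub = cls[a : b + 1, a : b + 1]
            iu = np.triu_indices(b - a + 1, k=1)
            vals = sub[iu]
            n_strong = int((vals == STRONG).sum())
            n_rec = int((vals == RECOMB).sum())
            informative = n_strong + n_rec
            if b - a == 1:
                valid = True  # the single pair is strong by construction
            else:
                valid = informative > 0 and n_strong / informative >= informative_frac
            if valid:
                ia, ib = int(keep[a]), int(keep[b])
                span = int(variants.pos[ib] - variants.pos[ia])
                candidates.append((span, ib - ia + 1, ia, ib))

    # greedy longest-first, non-overlapping (ties: more SNPs, then leftmost)
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
    chosen = []
    for span, _, ia, ib in candidates:
        if any(not (ib < s or ia > e - 1) for s, e in chosen):
            continue
        chosen.append((ia, ib + 1))
    chosen.sort()
    blocks = [
        Block(
            start_idx=s, end_idx=e, chrom=str(variants.chrom[s]),
            start_bp=int(variants.pos[s]), end_bp=int(variants.pos[e - 1]),
        )
        for s, e in chosen
    ]
    return BlockSet(method="ld", parameters=params, blocks=blocks)
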