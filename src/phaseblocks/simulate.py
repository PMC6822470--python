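"""Synthetic data with known truth for every pipeline stage.

The generator emulates the study conditions the toolkit targets: an
LD-structured population (haplotype cassettes with perfect internal coupling
and independence across cassette boundaries), trio children drawn from
parental haplotypes with recombination, genotype missingness at array-like
rates, and per-"tool" corrupted phasings whose orientation flips follow a
memoryless per-inter-het-interval Bernoulli process with rate ``s`` — the
simplest process consistent with switch-error accounting.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence, Tuple

import numpy as np

from .blocks import Block, BlockSet
from .model import MISSING, GenotypePanel, HaplotypePanel, Pedigree, VariantMap

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SimConfig:
    """Parameters of the population simulator.

    Defaults give ten 5-SNP cassettes (50 sites, 1 kb apart so every pair is
    well inside the 200 kb LD-pairing distance), 200 individuals, ancestral
    cassette frequencies drawn in [0.3, 0.7] (sample MAF comfortably above
    the 0.05 filter), and 0.3% genotype missingness, mirroring array data.
    """

    n_sites: int = 50
    n_individuals: int = 200
    block_snps: int = 5
    freq_bounds: Tuple[float, float] = (0.3, 0.7)
    inter_block_shuffle: float = 1.0  # P(ancestral pick is independent of previous block)
    missing_rate: float = 0.003
    bp_spacing: int = 1000
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("inter_block_shuffle", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.freq_bounds
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("freq_bounds must satisfy 0 < lo <= hi < 1")


def simulate_truth(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[HaplotypePanel, BlockSet]:
    """Draw a phased population panel with known cassette block structure.

    Sites are partitioned into consecutive cassettes of ``block_snps`` SNPs.
    Each cassette carries two complementary ancestral haplotypes; every
    individual's two chromosome copies pick one ancestral haplotype per
    cassette (independently across cassettes with probability
    ``inter_block_shuffle``, otherwise carrying the previous cassette's
    choice forward).  Within a cassette every SNP pair is therefore in
    complete coupling (|D'| = 1); across boundaries, loci are independent
    when ``inter_block_shuffle`` is 1.  Returns the panel and the generating
    cassette boundaries as the true block set.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, m = config.n_individuals, config.n_sites
    starts = list(range(0, m, config.block_snps))
    bounds = [(s, min(s + config.block_snps, m)) for s in starts]
    variants = VariantMap.default(m, chrom=config.chrom, spacing_bp=config.bp_spacing)

    lo, hi = config.freq_bounds
    freqs = rng.uniform(lo, hi, size=len(bounds))
    anc = rng.integers(0, 2, size=m, dtype=np.int8)  # ancestral haplotype "h"; other is 1-h

    alleles = np.empty((n, m, 2), dtype=np.int8)
    for copy in range(2):
        prev_pick = rng.random(n) < freqs[0]
        for b, (s, e) in enumerate(bounds):
            if b == 0:
                pick = prev_pick
            else:
                independent = rng.random(n) < config.inter_block_shuffle
                fresh = rng.random(n) < freqs[b]
                pick = np.where(independent, fresh, prev_pick)
            hap = np.where(pick[:, None], anc[s:e][None, :], 1 - anc[s:e][None, :])
            alleles[:, s:e, copy] = hap
            prev_pick = pick

    samples = [f"ind{i}" for i in range(n)]
    panel = HaplotypePanel(samples, variants, alleles)
    if len(bounds) == 1 and np.isclose(freqs[0], 0.0):
        logger.warning("degenerate simulation: monomorphic panel")
    blocks = [
        Block(s, e, config.chrom, int(variants.pos[s]), int(variants.pos[e - 1]))
        for s, e in bounds
    ]
    true_blocks = BlockSet(
        method="simulated", parameters=dataclasses.asdict(config), blocks=blocks
    )
    return panel, true_blocks


@dataclasses.dataclass
class TrioSimResult:
    """Children's unphased genotypes, their true transmitted haplotypes
    (copy 1 paternal, copy 2 maternal), and the pedigree."""

    child_genotypes: GenotypePanel
    child_truth: HaplotypePanel
    parent_genotypes: GenotypePanel
    pedigree: Pedigree


def _recombinant(pair: np.ndarray, recomb_prob: float, rng: np.random.Generator) -> np.ndarray:
    """One transmitted haplotype: a Markov walk over the parent's two copies."""
    m = pair.shape[0]
    switch = rng.random(m - 1) < recomb_prob if m > 1 else np.empty(0, dtype=bool)
    copy = np.empty(m, dtype=np.intp)
    copy[0] = rng.integers(0, 2)
    if m > 1:
        copy[1:] = copy[0] ^ np.cumsum(switch) % 2
    return pair[np.arange(m), copy]


def simulate_trios(
    parents: HaplotypePanel,
    n_trios: int,
    recomb_prob: float = 0.01,
    missing_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> TrioSimResult:
    """Draw trio children from consecutive parent pairs of ``parents``.

    Each child inherits one recombinant haplotype from each parent
    (orientation switching between the parent's copies with ``recomb_prob``
    per interval).  Child genotypes are masked at ``missing_rate``; the true
    transmitted haplotypes are returned alongside as the gold standard.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if parents.n_samples < 2 * n_trios:
        raise ValueError(
            f"need {2 * n_trios} parents for {n_trios} trios, have {parents.n_samples}"
        )
    m = parents.n_sites
    child_ids, trios = [], []
    truth = np.empty((n_trios, m, 2), dtype=np.int8)
    for k in range(n_trios):
        fa, mo = parents.samples[2 * k], parents.samples[2 * k + 1]
        cid = f"child{k}"
        truth[k, :, 0] = _recombinant(parents.alleles[2 * k], recomb_prob, rng)
        truth[k, :, 1] = _recombinant(parents.alleles[2 * k + 1], recomb_prob, rng)
        child_ids.append(cid)
        trios.append((cid, fa, mo))

    truth_panel = HaplotypePanel(child_ids, parents.variants, truth)
    dosage = truth_panel.dosages()
    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate
        dosage = dosage.copy()
        dosage[mask] = MISSING
    child_geno = GenotypePanel(child_ids, parents.variants, dosage)
    parent_ids = [s for t in trios for s in t[1:]]
    parent_geno = GenotypePanel(
        parent_ids, parents.variants, parents.take_samples(parent_ids).dosages()
    )
    ped = Pedigree(trios=trios, unrelated=list(parents.samples[2 * n_trios :]))
    return TrioSimResult(child_geno, truth_panel, parent_geno, ped)


def inject_genotype_errors(
    panel: GenotypePanel, rate: float, rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> GenotypePanel:
    """Flip called dosages to a uniformly chosen different value at ``rate``
    (used to exercise Mendelian-error detection)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    dosage = panel.dosage.copy()
    hit = (rng.random(dosage.shape) < rate) & (dosage != MISSING)
    shift = rng.integers(1, 3, size=dosage.shape)
    dosage[hit] = ((dosage[hit] + shift[hit]) % 3).astype(np.int8)
    return GenotypePanel(panel.samples, panel.variants, dosage)


def corrupt_phasing(
    truth: HaplotypePanel,
    switch_rate: float,
    missing_rate: float = 0.0,
    imputation_error_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> HaplotypePanel:
    """Emulate one phasing tool's output with a known error process.

    Genotypes are first masked at ``missing_rate`` and "imputed" (wrongly,
    to a uniformly chosen different dosage, with ``imputation_error_rate``).
    The phased output then walks each individual's heterozygous sites left to
    right, flipping the copy orientation with probability ``switch_rate``
    per inter-het interval; heterozygous sites introduced by imputation are
    phased in the walk's current orientation.  Distinct seeds give
    independent corruptions, emulating different tools or repeated runs.
    """
    for name, v in (
        ("switch_rate", switch_rate),
        ("missing_rate", missing_rate),
        ("imputation_error_rate", imputation_error_rate),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    n, m = truth.n_samples, truth.n_sites
    true_dose = truth.dosages()

    dose = true_dose.copy()
    if missing_rate > 0:
        masked = (rng.random((n, m)) < missing_rate) & (dose != MISSING)
        wrong = rng.random((n, m)) < imputation_error_rate
        shift = rng.integers(1, 3, size=(n, m))
        bad = masked & wrong
        dose[bad] = ((dose[bad] + shift[bad]) % 3).astype(np.int8)

    out = np.empty((n, m, 2), dtype=np.int8)
    hom = (dose == 0) | (dose == 2)
    out[:, :, 0] = np.where(hom, dose // 2, MISSING)
    out[:, :, 1] = out[:, :, 0]

    for i in range(n):
        het_sites = np.nonzero(dose[i] == 1)[0]
        h = len(het_sites)
        if h == 0:
            continue
        flips = rng.random(h - 1) < switch_rate if h > 1 else np.empty(0, dtype=bool)
        orient = np.empty(h, dtype=np.intp)
        orient[0] = 0
        if h > 1:
            orient[1:] = np.cumsum(flips) % 2
        for k, j in enumerate(het_sites):
            if true_dose[i, j] == 1:
                a, b = truth.alleles[i, j]
            else:  # imputed-to-het site: arbitrary base orientation
                a, b = 0, 1
            out[i, j] = (a, b) if orient[k] == 0 else (b, a)
    # sites missing in the corrupted genotype stay missing pairs
    out[dose == MISSING] = MISSING
    return HaplotypePanel(list(truth.samples), truth.variants, out)
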