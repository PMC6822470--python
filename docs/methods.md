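# Methods

This note records the models, conventions and numerical choices behind
`phaseblocks`, and what the simulation-based tests do and do not demonstrate.

## Data model and conventions

VCF positions are 1-based; internal site indices are 0-based; every internal
interval (blocks, regions) is half-open `[start, end)`. Only biallelic SNPs
are retained on ingestion (array-style data; skipped records are counted and
logged). Alleles are coded 0/1 with −1 for missing; the two copies of a site
are missing together. A `/`-separated genotype in a phaser's output is
treated as missing *phase* rather than an error, because real tool outputs
are heterogeneous; this costs nothing at homozygous sites (which carry no
phase information) and is conservative at heterozygous ones.

## Trio truth resolution

Phasing by transmission: at each site a child's genotype is resolved against
the parents' —

* child homozygous → trivially phased (`RESOLVED_HOM`), unless a parent is
  homozygous for the opposite allele (`MENDEL_ERROR`);
* child heterozygous → a homozygous parent pins its transmitted allele to
  its copy (`RESOLVED_HET`); both parents heterozygous (or the only
  potentially informative parent missing) leaves `UNRESOLVED_HET`;
* child missing → both parents homozygous deduce genotype and phase
  (`RESOLVED_MISSING`); otherwise `UNRESOLVED_MISSING`.

A missing parent genotype is uninformative, never an error. A child-missing
site with exactly one homozygous parent fixes one transmitted allele but not
the child's genotype; we conservatively leave it unresolved rather than
record partial knowledge, which can only shrink (never bias) the truth set.
The paternal copy is stored as copy 1, but every metric is
orientation-invariant, so nothing depends on which copy is which.
Mendelian-error detection is exactly the set of trio configurations
impossible under inheritance; the tests enumerate all 27 called
configurations (and all missing-augmented ones) against a brute-force
consistency oracle.

## Switch profiles and metrics

The agreement chain of an individual compares the estimate's copy-1 allele
with the truth's copy-1 allele at **comparable sites**: resolved,
heterozygous in truth, and heterozygous in the estimate. Unresolved sites
and Mendelian errors are always excluded. Resolved sites where the estimated
genotype differs from the truth (including wrongly imputed resolved-missing
sites) are excluded from the chain — a copy-wise comparison is undefined
there — but recorded as genotype mismatches. The chain is anchored at its
first site, so a global copy swap produces zero switches; a switch site is a
comparable site whose agreement sign differs from its predecessor's.

* **SE** is the mean over individuals of `switches / H` with `H` the
  comparable-site count. The printed formula convention in the literature
  sometimes uses `H − 1` (the number of possible switch points); both are
  supported (`denominator="H"` is the default because it reproduces the
  standard worked examples, 2/10 = 20% and 20/372 = 5.4%), and per-individual
  tables are always emitted so either aggregation can be recomputed.
* **IHBP**: a block is *unambiguous* (excluded) for an individual when it
  contains fewer than two comparable sites; *incorrect* when a switch occurs
  between two comparable sites inside it, or when any resolved site in it
  carries a genotype mismatch (imputation errors count against blocks even
  though they cannot enter the switch chain); otherwise *correct*.
  IHBP = incorrect / (incorrect + correct) pooled over (block, individual)
  verdicts. This is provably equivalent to re-phasing each block directly —
  "does either orientation of the estimate match the truth across the whole
  block" — and the tests assert that equivalence exhaustively on 10-site
  chains over every switch placement.
* **LCPR** pools maximal switch-free runs over individuals (optionally
  restricted to a region, where the chain is re-anchored) and reports mean
  run length in heterozygous SNPs. For a memoryless per-interval switch
  process at rate *s* run lengths are geometric, so LCPR ≈ 1/s.
* **Error sharing / stability** treat a switch site as the pair
  (individual, site index) on the common variant grid; the sharing histogram
  counts, for each site in the union across tools (or runs), how many tools
  (runs) report it, normalised to percentages.

A locus-5/locus-7 note on the worked example: a "switch at locus 5" is the
transition between comparable sites 4 and 5 (1-based), and a window is
incorrect when it contains **both** endpoints of a transition. That is the
convention under which 4 of 8 3-SNP windows are incorrect; the single-switch
law (an interior switch spoils exactly `w − 1` unit-step windows) follows
and is brute-force verified.

## Consensus estimation

Given K tools' haplotype pairs over identical sites:

1. **Genotype vote.** The consensus genotype at each site is the majority of
   the tools' genotypes (missing calls abstain; ties go to the
   highest-priority tool). Tools therefore also vote on imputed sites.
2. **Alignment.** At the first consensus-heterozygous site *f*, every tool
   heterozygous at *f* is oriented so its copy-1 allele matches the
   highest-priority tool's; a tool not heterozygous at *f* is oriented at
   its next heterozygous site shared with that reference tool.
3. **Scan.** Left to right from *f*, at each consensus-het site the
   consensus copy-1 allele is the majority of the counted tools'
   orientation-applied copy-1 alleles, counting only tools whose genotype
   matches the consensus genotype (ties per priority). Every counted tool
   out-voted at such a site has its orientation flipped for all remaining
   sites. Copy 2 is the genotype complement; sites left of *f* are
   homozygous or missing by construction and copied from the genotype.

Flips are triggered **only at consensus-heterozygous sites**: a flip at a
homozygous site would silently re-phase the remainder on evidence that
carries no phase information. Ties are broken by a fixed priority order
(default: input order) purely for determinism; with the odd K used in
practice ties are rare, and the tests check permutation invariance in their
absence. Because the minority is realigned after every disagreement, each
inter-het interval is memoryless: with three independent tools at
per-interval switch rate *s*, the consensus switches exactly when ≥ 2 tools
switch together, at rate `3s² − 2s³`. The acceptance test verifies this law
at `s = 0.02` over 10⁵ intervals within three binomial standard deviations.

## Block determination

**Sliding windows**: all `⌊(m − w)/step⌋ + 1` windows of `w` SNPs, i.e.
`m − w + 1` at unit step (property-tested for m ≤ 200).

**LD blocks** re-implement the D′ confidence-interval algorithm as ported by
PLINK's `--blocks`: sites with MAF < 0.05 are dropped; same-chromosome pairs
within 200 kb are classified from the 90% D′ CI — strong LD when the lower
bound > 0.70 and upper bound > 0.98, recombination when the upper bound
< 0.90, else uninformative (strict inequalities exactly as stated); a
strong-LD endpoint pair is a candidate block, valid when ≥ 95% of its
informative interior pairs are strong (a 2-SNP span needs only its own
pair); valid candidates are accepted greedily by bp length (ties: more SNPs,
then leftmost) without overlap. The 0.90 / 0.95 / greedy / 2-SNP settings
are that implementation's documented defaults; all are exposed as
parameters. Haploview's distance-graduated CI thresholds for very short
blocks are deliberately **not** implemented — thresholds are uniform — which
is the one known divergence from Haploview proper.

The D′ CI itself: allele frequencies p, q and the sign of D are fixed at
their sample MLEs; for each d′ on the grid {0, 0.001, …, 1} the implied
haplotype frequencies are `f11 = pq + d′·sign·Dmax` etc., and the data
likelihood is multinomial over the 4 haplotype classes (phased input) or the
9 genotype classes with the double heterozygote a mixture of both phase
configurations (unphased input). The grid likelihood is normalised and the
CI bounds are the smallest grid values at which the cumulative mass exceeds
each symmetric 5% tail. Implied negative frequencies get likelihood zero
(boundary handling, never an exception). Unphased inputs go through a
standard two-locus EM under random mating (converged at 1e-10 or 1000
iterations; started from linkage equilibrium); its likelihood is verified to
dominate 1000 random feasible frequency vectors, and the CI bounds are
verified against an independent naive-summation normalisation to 1e-12.

## Simulator

`simulate_truth` plants consecutive cassettes of `block_snps` SNPs; each
cassette carries two complementary ancestral haplotypes at a frequency drawn
from `freq_bounds`, and each individual's two copies pick independently per
cassette (an `inter_block_shuffle < 1` carries picks across boundaries to
create cross-block LD when wanted). Within a cassette every pair has
|D′| = 1; across boundaries loci are independent. Defaults — 10 cassettes of
5 SNPs, 200 individuals, frequencies in [0.3, 0.7], 1 kb spacing, 0.3%
missingness — keep every pair inside the 200 kb window, every MAF safely
above 0.05, and mirror array-like missingness. `simulate_trios` transmits
one recombinant haplotype per parent (Markov copy-switching at
`recomb_prob` per interval, default 1%). `corrupt_phasing` emulates a tool:
mask genotypes at `missing_rate`, "impute" them (wrongly with
`imputation_error_rate`), then flip the copy orientation with probability
`s` per inter-het interval — memoryless by design, the simplest process
consistent with switch-error accounting.

What this simulator does **not** emulate: coalescent realism (recombination
hotspots, demography, allele-frequency spectra), genotyping error in
parents, long-range error clustering, or the HMM-specific error signatures
of particular phasers. Passing tests therefore demonstrate correctness of
the metrics, estimators and algorithms under controlled error processes —
not the real-data error rates of any particular tool, which depend on LD,
SNP density and sample size in ways the cassette model intentionally
simplifies.

## Problem sizes and numerical choices

Stochastic checks use sizes chosen to make their tolerances meaningful:
10⁵ inter-het intervals for the consensus law and rate recovery at three
binomial standard deviations; 20 × 5000 intervals for the LCPR ≈ 1/s check
at 5%; 100 simulator seeds (n = 200) for ≥ 95% exact cassette recovery.
Boundary effects make E[LCPR] = H/(sE[H] + 1) slightly below 1/s, which the
5% band absorbs at these sizes. All randomness flows through
`numpy.random.Generator` seeds; the CLI expands one seed into independent
per-component streams (`SeedSequence.spawn`) so adding a simulated tool does
not perturb the other draws.

## Known limitations

* Duo (single-parent) resolution and probabilistic trio phasing are out of
  scope; the truth set is deterministic or absent.
* LD blocks assume random mating (HWE) for the genotype-likelihood path.
* Uniform CI thresholds (no Haploview short-block graduation), no
  four-gamete or solid-spine block definitions, no r²-based pruning.
* Consensus voting is unweighted; tool posteriors are not consumed.
* Multiallelic sites, indels and structural variants are skipped on input.
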