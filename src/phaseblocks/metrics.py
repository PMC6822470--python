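"""Evaluation metrics for phased haplotypes against trio-resolved truth.

* **Switch error (SE)** — the number of heterozygous sites phased
  inconsistently with their predecessor, over the individual's comparable
  heterozygous sites (H); averaged over individuals.  The alternative H-1
  denominator (possible switch points) is available as an option.
* **IHBP** — the percentage of evaluable haplotype blocks that contain at
  least one phasing error or one wrongly imputed resolved site.  Blocks with
  fewer than two comparable sites are unambiguous and excluded.
* **LCPR** — the mean number of heterozygous SNPs per correctly phased run
  (maximal stretch of comparable sites free of internal switches).

Unresolved sites and Mendelian errors are always excluded from the
comparable set; resolved-missing sites participate when the estimate
reproduces the true (heterozygous) genotype, and otherwise count as
imputation errors against any containing block.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .blocks import Block, BlockSet
from .model import MISSING, HaplotypePanel
from .trio import SiteStatus, TruthPhase

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SwitchProfile:
    """Per-individual agreement chain between an estimate and the truth.

    ``comparable`` holds the ascending site indices entering the chain;
    ``agree`` is +1/-1 per comparable site (estimate copy 1 equals truth
    copy 1 or not); ``switch_sites`` are the comparable sites whose agreement
    differs from their predecessor's.
    """

    individual: str
    comparable: np.ndarray
    agree: np.ndarray
    switch_sites: np.ndarray
    genotype_mismatch_sites: np.ndarray

    @property
    def H(self) -> int:
        return len(self.comparable)

    @property
    def n_switches(self) -> int:
        return len(self.switch_sites)


def switch_profile(truth: TruthPhase, estimate: np.ndarray, individual: str = "") -> SwitchProfile:
    """Build the switch/agreement profile of one estimated haplotype pair.

    ``estimate`` is the ``(n_sites, 2)`` allele matrix.  The agreement chain
    runs over truth-heterozygous resolved sites where the estimate is also
    heterozygous; it is anchored at the first such site, which makes every
    downstream metric invariant to globally swapping either pair's copies.
    """
    est = np.asarray(estimate, dtype=np.int8)
    if est.shape != (truth.n_sites, 2):
        raise ValueError("estimate does not cover the truth's variants")
    est_g = est.sum(axis=1).astype(np.int8)
    est_g[est[:, 0] == MISSING] = MISSING

    truth_g = truth.genotype
    resolved = (
        (truth.status == SiteStatus.RESOLVED_HOM)
        | (truth.status == SiteStatus.RESOLVED_HET)
        | (truth.status == SiteStatus.RESOLVED_MISSING)
    )
    mismatch = resolved & (est_g != truth_g)

    chain = resolved & (truth_g == 1) & (est_g == 1)
    comparable = np.nonzero(chain)[0]
    agree = np.where(est[comparable, 0] == truth.paternal[comparable], 1, -1).astype(np.int8)
    if len(comparable):
        flips = np.nonzero(agree[1:] != agree[:-1])[0] + 1
        switch_sites = comparable[flips]
    else:
        logger.warning("individual %s: no comparable sites", individual or truth.child)
        switch_sites = np.empty(0, dtype=np.intp)
    return SwitchProfile(
        individual=individual or truth.child,
        comparable=comparable,
        agree=agree,
        switch_sites=switch_sites,
        genotype_mismatch_sites=np.nonzero(mismatch)[0],
    )


def panel_profiles(
    truths: Mapping[str, TruthPhase], estimate: HaplotypePanel
) -> List[SwitchProfile]:
    """Profiles for every truth individual present in the estimated panel."""
    profiles = []
    for sid, t in truths.items():
        if sid not in estimate.samples:
            logger.warning("individual %s absent from estimate panel; skipped", sid)
            continue
        profiles.append(switch_profile(t, estimate.pair(sid), individual=sid))
    return profiles


def switch_error(
    profiles: Sequence[SwitchProfile], denominator: str = "H"
) -> Tuple[float, pd.Series]:
    """Pooled and per-individual switch-error rates.

    ``denominator`` is ``"H"`` (comparable het count, the convention matching
    the worked 2/10 and 20/372 examples) or ``"H_minus_1"`` (possible switch
    points).  The pooled value is the mean of per-individual rates;
    individuals without a usable denominator are excluded with a warning.
    """
    if denominator not in ("H", "H_minus_1"):
        raise ValueError("denominator must be 'H' or 'H_minus_1'")
    rates = {}
    for p in profiles:
        denom = p.H if denominator == "H" else p.H - 1
        if denom <= 0:
            logger.warning("individual %s: empty profile excluded from SE", p.individual)
            continue
        rates[p.individual] = p.n_switches / denom
    if not rates:
        raise ValueError("no individual has a non-empty switch profile")
    series = pd.Series(rates, name="switch_error")
    return float(series.mean()), series


@dataclasses.dataclass
class BlockEvaluation:
    """Per-(block, individual) verdicts and the aggregate IHBP.

    ``verdicts`` is a DataFrame (rows = block index, columns = individual)
    with values CORRECT / INCORRECT / UNAMBIGUOUS; IHBP = IB / B over the
    non-UNAMBIGUOUS verdicts.
    """

    verdicts: pd.DataFrame

    @property
    def ib(self) -> int:
        return int((self.verdicts == "INCORRECT").to_numpy().sum())

    @property
    def b(self) -> int:
        return int((self.verdicts != "UNAMBIGUOUS").to_numpy().sum())

    @property
    def ihbp(self) -> float:
        if self.b == 0:
            return float("nan")
        return self.ib / self.b


def evaluate_blocks(
    profiles: Sequence[SwitchProfile], blocks: BlockSet
) -> BlockEvaluation:
    """Judge every block for every individual.

    A block is UNAMBIGUOUS for an individual when it holds fewer than two
    comparable sites; INCORRECT when a switch occurs between two comparable
    sites inside it, or when a resolved site inside it carries a genotype
    (imputation) mismatch; otherwise CORRECT.
    """
    if len(blocks) == 0:
        raise ValueError("empty block set")
    data = {}
    for p in profiles:
        comp = p.comparable
        sw = set(int(s) for s in p.switch_sites)
        gm = p.genotype_mismatch_sites
        col = []
        for blk in blocks:
            lo = np.searchsorted(comp, blk.start_idx, side="left")
            hi = np.searchsorted(comp, blk.end_idx, side="left")
            within = comp[lo:hi]
            if len(within) < 2:
                col.append("UNAMBIGUOUS")
                continue
            bad = any(int(s) in sw for s in within[1:])
            if not bad and len(gm):
                glo = np.searchsorted(gm, blk.start_idx, side="left")
                ghi = np.searchsorted(gm, blk.end_idx, side="left")
                bad = ghi > glo
            col.append("INCORRECT" if bad else "CORRECT")
        data[p.individual] = col
    return BlockEvaluation(verdicts=pd.DataFrame(data))


@dataclasses.dataclass
class RunProfile:
    """Correctly phased runs of one individual: lengths in het-SNP counts."""

    individual: str
    lengths: np.ndarray

    @property
    def n_runs(self) -> int:
        return len(self.lengths)


def run_profile(profile: SwitchProfile, region: Optional[Block] = None) -> RunProfile:
    """Split the agreement chain into maximal switch-free runs.

    With ``region`` the chain is first restricted to ``[start_idx, end_idx)``
    and runs are recomputed within it.
    """
    comp = profile.comparable
    agree = profile.agree
    if region is not None:
        lo = np.searchsorted(comp, region.start_idx, side="left")
        hi = np.searchsorted(comp, region.end_idx, side="left")
        comp = comp[lo:hi]
        agree = agree[lo:hi]
    if len(comp) == 0:
        return RunProfile(profile.individual, np.empty(0, dtype=np.intp))
    breaks = np.nonzero(agree[1:] != agree[:-1])[0] + 1
    bounds = np.concatenate(([0], breaks, [len(comp)]))
    return RunProfile(profile.individual, np.diff(bounds))


def lcpr(profiles: Sequence[SwitchProfile], region: Optional[Block] = None) -> float:
    """Length of correctly phased runs: total comparable het SNPs over the
    number of runs, pooled over individuals (optionally within a region)."""
    total, n_runs = 0, 0
    for p in profiles:
        rp = run_profile(p, region)
        total += int(rp.lengths.sum())
        n_runs += rp.n_runs
    if n_runs == 0:
        raise ValueError("no comparable sites in the requested region")
    return total / n_runs


# ---------------------------------------------------------------------------
# cross-tool error sharing and run-to-run stability

def _pooled_site_sets(per_tool: Sequence) -> List[frozenset]:
    """Normalise either plain site sets or per-tool profile lists into sets of
    (individual, site) units."""
    pooled = []
    for entry in per_tool:
        if isinstance(entry, (set, frozenset)):
            pooled.append(frozenset(entry))
        else:  # sequence of SwitchProfile
            units = set()
            for p in entry:
                units.update((p.individual, int(s)) for s in p.switch_sites)
            pooled.append(frozenset(units))
    return pooled


def error_sharing(per_tool: Sequence) -> pd.Series:
    """Histogram (in %) of how many tools share each observed switch site.

    ``per_tool`` is one entry per tool: either a set of hashable site units
    or a sequence of :class:`SwitchProfile` (pooled as (individual, site)).
    Bin ``k`` holds the percentage of the union's sites reported by exactly
    ``k`` tools.
    """
    sets = _pooled_site_sets(per_tool)
    K = len(sets)
    if K < 2:
        raise ValueError("error sharing requires at least two tools")
    counts = {}
    for s in sets:
        for u in s:
            counts[u] = counts.get(u, 0) + 1
    hist = pd.Series(0.0, index=pd.RangeIndex(1, K + 1, name="n_tools"), name="percent")
    if counts:
        vals, freq = np.unique(np.fromiter(counts.values(), dtype=int), return_counts=True)
        for v, c in zip(vals, freq):
            hist.loc[int(v)] = 100.0 * c / len(counts)
    return hist


def stability_summary(
    per_run: Sequence,
    metrics_per_run: Optional[Mapping[str, Sequence[float]]] = None,
) -> Tuple[pd.Series, Optional[pd.DataFrame]]:
    """Consistency of switch locations across repeated runs of one tool.

    Returns the occurrence histogram (percentage of observed error sites seen
    in exactly ``r`` of the R runs) and, when per-run metric values are
    given, their dispersion (mean/std/min/max) across runs.
    """
    sets = _pooled_site_sets(per_run)
    R = len(sets)
    if R < 2:
        raise ValueError("stability requires at least two runs")
    counts = {}
    for s in sets:
        for u in s:
            counts[u] = counts.get(u, 0) + 1
    occ = pd.Series(0.0, index=pd.RangeIndex(1, R + 1, name="n_runs"), name="percent")
    if counts:
        vals, freq = np.unique(np.fromiter(counts.values(), dtype=int), return_counts=True)
        for v, c in zip(vals, freq):
            occ.loc[int(v)] = 100.0 * c / len(counts)
    disp = None
    if metrics_per_run is not None:
        disp = pd.DataFrame(
            {
                name: {
                    "mean": float(np.mean(vals)),
                    "std": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "min": float(np.min(vals)),
                    "max": float(np.max(vals)),
                }
                for name, vals in metrics_per_run.items()
            }
        ).T
    return occ, disp


@dataclasses.dataclass
class MetricsReport:
    """Bundle of the standard evaluation outputs for one estimated panel."""

    se_pooled: float
    se_per_individual: pd.Series
    block_evaluations: Dict[str, BlockEvaluation]
    lcpr_value: float

    def summary(self) -> dict:
        out = {
            "switch_error_percent": 100.0 * self.se_pooled,
            "lcpr_het_snps": self.lcpr_value,
        }
        for name, ev in self.block_evaluations.items():
            out[f"ihbp_percent[{name}]"] = 100.0 * ev.ihbp
        return out


def evaluate_panel(
    truths: Mapping[str, TruthPhase],
    estimate: HaplotypePanel,
    block_sets: Optional[Mapping[str, BlockSet]] = None,
    denominator: str = "H",
) -> MetricsReport:
    """One-call evaluation: SE, IHBP per block set, and LCPR."""
    profiles = panel_profiles(truths, estimate)
    pooled, per_ind = switch_error(profiles, denominator=denominator)
    evals = {
        name: evaluate_blocks(profiles, bs) for name, bs in (block_sets or {}).items()
    }
    return MetricsReport(
        se_pooled=pooled,
        se_per_individual=per_ind,
        block_evaluations=evals,
        lcpr_value=lcpr(profiles),
    )
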