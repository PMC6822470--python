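"""Consensus haplotype estimation across several phasers' outputs.

The estimator aligns the tools' haplotype pairs at the first heterozygous
site, then scans left to right taking a per-site majority vote over the
tools' (orientation-applied) copy-1 alleles; any tool out-voted at a
heterozygous site has its copy assignment flipped for all remaining sites.
Because the minority is realigned after every disagreement, a consensus
switch occurs only where a majority of tools switch inside the same
inter-het interval — which is what makes the consensus strictly more
accurate than its constituents for independent error processes.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import MISSING, HaplotypePanel

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ConsensusTrace:
    """Per-site record of the vote: consensus genotype, chosen copy-1 allele
    (-1 at non-het sites), each tool's counted vote (-1 when not counted),
    flip events, and the initial per-tool orientations (+1 as-read / -1 swapped)."""

    genotype: np.ndarray
    copy1: np.ndarray
    votes: np.ndarray            # shape (K, n_sites)
    flips: List[Tuple[int, int]]  # (site index, tool index)
    initial_orientation: np.ndarray
    alignment_site: Optional[int]


def _genotype_vector(pair: np.ndarray) -> np.ndarray:
    g = pair.sum(axis=1).astype(np.int8)
    g[pair[:, 0] == MISSING] = MISSING
    return g


def _majority_genotypes(G: np.ndarray, priority: Sequence[int]) -> np.ndarray:
    """Per-site majority over the tools' genotypes; ties go to the
    highest-priority voting tool; all-missing stays missing."""
    K, n = G.shape
    out = np.full(n, MISSING, dtype=np.int8)
    counts = np.zeros((3, n), dtype=np.int32)
    for v in (0, 1, 2):
        counts[v] = (G == v).sum(axis=0)
    total = counts.sum(axis=0)
    best = counts.argmax(axis=0)
    bestc = counts.max(axis=0)
    n_at_max = (counts == bestc).sum(axis=0)
    clear = (total > 0) & (n_at_max == 1)
    out[clear] = best[clear]
    tied = np.nonzero((total > 0) & (n_at_max > 1))[0]
    for j in tied:
        for t in priority:
            if G[t, j] != MISSING and counts[G[t, j], j] == bestc[j]:
                out[j] = G[t, j]
                break
    return out


def consensus_individual(
    estimates: Sequence[np.ndarray],
    priority: Optional[Sequence[int]] = None,
) -> Tuple[np.ndarray, ConsensusTrace]:
    """Consensus of K haplotype pairs (each ``(n_sites, 2)``) for one individual.

    ``priority`` is a tool-index order used to break every tie (genotype
    votes, allele votes, choice of alignment reference); it defaults to the
    order the estimates are given.
    """
    K = len(estimates)
    if K == 0:
        raise ValueError("no estimates supplied")
    n = estimates[0].shape[0]
    for e in estimates:
        if e.shape != (n, 2):
            raise ValueError("estimates do not cover the same sites")
    priority = list(priority) if priority is not None else list(range(K))
    if sorted(priority) != list(range(K)):
        raise ValueError("priority must be a permutation of tool indices")

    A = [np.asarray(e, dtype=np.int8) for e in estimates]
    G = np.stack([_genotype_vector(a) for a in A], axis=0)
    cg = _majority_genotypes(G, priority)

    out = np.full((n, 2), MISSING, dtype=np.int8)
    hom = (cg == 0) | (cg == 2)
    out[hom, 0] = cg[hom] // 2
    out[hom, 1] = cg[hom] // 2

    votes = np.full((K, n), MISSING, dtype=np.int8)
    copy1 = np.full(n, MISSING, dtype=np.int8)
    flips: List[Tuple[int, int]] = []

    het_sites = np.nonzero(cg == 1)[0]
    if len(het_sites) == 0:
        logger.warning("no heterozygous consensus site; consensus is the genotype")
        trace = ConsensusTrace(cg, copy1, votes, flips, np.ones(K, dtype=np.int8), None)
        return out, trace

    f = int(het_sites[0])
    # alignment: reference is the highest-priority tool het at f
    ref = next((t for t in priority if G[t, f] == 1), None)
    orient = np.ones(K, dtype=np.int8)
    if ref is None:
        logger.warning("no tool heterozygous at alignment site %d", f)
    else:
        ref_allele = A[ref][f, 0]
        for t in range(K):
            if t == ref:
                continue
            if G[t, f] == 1:
                orient[t] = 1 if A[t][f, 0] == ref_allele else -1
            else:
                # align at this tool's next het site shared with the reference
                shared = np.nonzero((G[t] == 1) & (G[ref] == 1))[0]
                shared = shared[shared > f]
                if len(shared):
                    j = int(shared[0])
                    orient[t] = 1 if A[t][j, 0] == A[ref][j, 0] else -1
    initial_orientation = orient.copy()

    # left-to-right scan; flips only at sites het in the consensus genotype
    Glist = G  # local alias
    for j in het_sites:
        j = int(j)
        counted = [t for t in range(K) if Glist[t, j] == 1]
        if not counted:  # cannot happen for odd clean votes; defensive
            copy1[j] = 0
            out[j] = (0, 1)
            continue
        ones = 0
        for t in counted:
            v = A[t][j, 0] if orient[t] > 0 else A[t][j, 1]
            votes[t, j] = v
            ones += v
        n_votes = len(counted)
        if 2 * ones > n_votes:
            chosen = 1
        elif 2 * ones < n_votes:
            chosen = 0
        else:  # tie: highest-priority counted tool decides
            chosen = next(int(votes[t, j]) for t in priority if t in counted)
        copy1[j] = chosen
        out[j, 0] = chosen
        out[j, 1] = 1 - chosen
        for t in counted:
            if votes[t, j] != chosen:
                orient[t] = -orient[t]
                flips.append((j, t))

    trace = ConsensusTrace(cg, copy1, votes, flips, initial_orientation, f)
    return out, trace


def build_consensus_panel(
    panels: Sequence[HaplotypePanel],
    priority: Optional[Sequence[int]] = None,
    keep_traces: bool = False,
) -> Tuple[HaplotypePanel, Dict[str, ConsensusTrace]]:
    """Apply :func:`consensus_individual` to every sample of K aligned panels.

    Panels must share samples and variants; sample order is normalised to the
    first panel's.  Deterministic given inputs and priority.
    """
    if len(panels) == 0:
        raise ValueError("no panels supplied")
    first = panels[0]
    norm = [first]
    for p in panels[1:]:
        if set(p.samples) != set(first.samples):
            missing = set(first.samples) ^ set(p.samples)
            raise ValueError(f"sample sets differ between panels: {sorted(missing)}")
        if p.samples != first.samples:
            p = p.take_samples(first.samples)
        if not p.variants.equals(first.variants):
            raise ValueError("panels do not share an identical variant map")
        norm.append(p)

    alleles = np.empty_like(first.alleles)
    traces: Dict[str, ConsensusTrace] = {}
    for i, sid in enumerate(first.samples):
        pair, trace = consensus_individual([p.alleles[i] for p in norm], priority)
        alleles[i] = pair
        if keep_traces:
            traces[sid] = trace
    return HaplotypePanel(first.samples, first.variants, alleles), traces
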