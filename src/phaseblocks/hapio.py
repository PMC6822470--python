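"""Readers and writers for the standard formats the toolkit touches.

Phased haplotypes travel as VCF (read through :mod:`cyvcf2`), pedigrees as
PLINK ``.fam`` files, block sets as BED (0-based half-open) or PLINK
``.blocks``-style variant-ID lists, and metric tables as TSV.
"""
from __future__ import annotations

import logging
import re
import sys
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import MISSING, GenotypePanel, HaplotypePanel, Pedigree, VariantMap

logger = logging.getLogger(__name__)

_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


class VcfFormatError(ValueError):
    """Raised when a VCF violates the reader's contract (e.g. no GT field)."""


class SortedInputError(ValueError):
    """Raised when variant positions are not strictly increasing."""


def _parse_region(region: str) -> tuple[str, int, int]:
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(f"region {region!r} not in chrom:start-end form")
    return m.group(1), int(m.group(2)), int(m.group(3))


def read_phased_vcf(path, region: Optional[str] = None) -> HaplotypePanel:
    """Read a phased, biallelic-SNP VCF into a :class:`HaplotypePanel`.

    ``|``-separated genotypes become ordered allele pairs; ``/``-separated or
    half-missing genotypes become missing pairs (tolerant ingestion of
    heterogeneous phaser outputs).  Multiallelic and non-SNP records are
    skipped with a logged count.  ``region`` is 1-based inclusive
    ``chrom:start-end``.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=False)
    if region is not None:
        want_chrom, want_start, want_end = _parse_region(region)
    samples = list(vcf.samples)

    chroms, poss, vids, refs, alts = [], [], [], [], []
    rows = []
    n_skipped = 0
    n_unphased = 0
    last = {}
    saw_gt = False
    for rec in vcf:
        if region is not None and not (
            rec.CHROM == want_chrom and want_start <= rec.POS <= want_end
        ):
            continue
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        if rec.CHROM in last and rec.POS <= last[rec.CHROM]:
            raise SortedInputError(
                f"positions not strictly increasing at {rec.CHROM}:{rec.POS}"
            )
        last[rec.CHROM] = rec.POS
        gts = rec.genotypes  # per sample: [a0, a1, phased]
        if gts is None:
            raise VcfFormatError(f"record {rec.CHROM}:{rec.POS} has no GT field")
        saw_gt = True
        site = np.empty((len(samples), 2), dtype=np.int8)
        for k, g in enumerate(gts):
            if len(g) < 3:  # haploid call: treat as missing pair
                site[k] = (MISSING, MISSING)
                continue
            a0, a1, phased = g[0], g[1], g[-1]
            if a0 < 0 or a1 < 0 or not phased:
                if a0 >= 0 and a1 >= 0 and not phased:
                    n_unphased += 1
                site[k] = (MISSING, MISSING)
            else:
                site[k] = (a0, a1)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        vids.append(rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}")
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(site)
    vcf.close()
    if rows and not saw_gt:
        raise VcfFormatError(f"{path}: no GT field found")
    if n_skipped:
        logger.info("%s: skipped %d multiallelic/non-SNP records", path, n_skipped)
    if n_unphased:
        logger.info("%s: %d unphased genotype calls treated as missing phase", path, n_unphased)

    variants = VariantMap(chroms, poss, vids, refs, alts)
    alleles = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((len(samples), 0, 2), dtype=np.int8)
    )
    return HaplotypePanel(samples, variants, alleles)


def write_phased_vcf(panel: HaplotypePanel, path) -> None:
    """Write a panel as a phased VCF; missing pairs are emitted as ``.|.``."""
    from . import __version__

    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=phaseblocks {__version__}\n")
        fh.write(f"##phaseblocks_commandline={' '.join(sys.argv)}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(panel.variants.chrom):
            fh.write(f"##contig=<ID={chrom}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += panel.samples
        fh.write("\t".join(header) + "\n")
        v = panel.variants
        for j in range(panel.n_sites):
            fields = [
                str(v.chrom[j]), str(v.pos[j]), str(v.vid[j]),
                str(v.ref[j]), str(v.alt[j]), ".", ".", ".", "GT",
            ]
            col = panel.alleles[:, j, :]
            for k in range(panel.n_samples):
                a0, a1 = int(col[k, 0]), int(col[k, 1])
                fields.append(".|." if a0 == MISSING else f"{a0}|{a1}")
            fh.write("\t".join(fields) + "\n")


def write_genotype_vcf(panel: GenotypePanel, path) -> None:
    """Write an unphased genotype panel as VCF (dosage 1 emitted as ``0/1``)."""
    hap = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    from . import __version__

    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=phaseblocks {__version__}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(panel.variants.chrom):
            fh.write(f"##contig=<ID={chrom}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += panel.samples
        fh.write("\t".join(header) + "\n")
        v = panel.variants
        for j in range(panel.n_sites):
            fields = [
                str(v.chrom[j]), str(v.pos[j]), str(v.vid[j]),
                str(v.ref[j]), str(v.alt[j]), ".", ".", ".", "GT",
            ]
            fields += [hap[int(panel.dosage[k, j])] for k in range(panel.n_samples)]
            fh.write("\t".join(fields) + "\n")


def read_genotype_vcf(path, region: Optional[str] = None) -> GenotypePanel:
    """Read a VCF (phased or not) into genotype dosages; any half-missing
    call becomes MISSING."""
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=False)
    if region is not None:
        want_chrom, want_start, want_end = _parse_region(region)
    samples = list(vcf.samples)
    chroms, poss, vids, refs, alts = [], [], [], [], []
    rows = []
    n_skipped = 0
    last = {}
    for rec in vcf:
        if region is not None and not (
            rec.CHROM == want_chrom and want_start <= rec.POS <= want_end
        ):
            continue
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        if rec.CHROM in last and rec.POS <= last[rec.CHROM]:
            raise SortedInputError(
                f"positions not strictly increasing at {rec.CHROM}:{rec.POS}"
            )
        last[rec.CHROM] = rec.POS
        gts = rec.genotypes
        if gts is None:
            raise VcfFormatError(f"record {rec.CHROM}:{rec.POS} has no GT field")
        site = np.empty(len(samples), dtype=np.int8)
        for k, g in enumerate(gts):
            if len(g) < 3 or g[0] < 0 or g[1] < 0:
                site[k] = MISSING
            else:
                site[k] = g[0] + g[1]
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        vids.append(rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}")
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(site)
    vcf.close()
    if n_skipped:
        logger.info("%s: skipped %d multiallelic/non-SNP records", path, n_skipped)
    variants = VariantMap(chroms, poss, vids, refs, alts)
    dosage = (
        np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypePanel(samples, variants, dosage)


def read_pedigree(path, strict: bool = False) -> Pedigree:
    """Parse a whitespace-delimited 6-column PLINK ``.fam`` file.

    Rows whose PAT and MAT columns are both non-zero become trios; all other
    rows are unrelated.  A child whose parent ID does not appear as an IID in
    the file is demoted to unrelated with a warning (``strict=True`` raises).
    """
    df = pd.read_csv(
        path, sep=r"\s+", header=None, dtype=str,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
    )
    iids = set(df["iid"])
    trios, unrelated = [], []
    for row in df.itertuples(index=False):
        if row.pat != "0" and row.mat != "0":
            absent = [p for p in (row.pat, row.mat) if p not in iids]
            if absent:
                msg = f"child {row.iid}: parent IDs {absent} not present in pedigree"
                if strict:
                    raise ValueError(msg)
                logger.warning("%s; treated as unrelated", msg)
                unrelated.append(row.iid)
            else:
                trios.append((row.iid, row.pat, row.mat))
        else:
            unrelated.append(row.iid)
    return Pedigree(trios=trios, unrelated=unrelated)


def write_pedigree(pedigree: Pedigree, path) -> None:
    with Path(path).open("w") as fh:
        for i, (child, father, mother) in enumerate(pedigree.trios):
            fh.write(f"F{i} {child} {father} {mother} 0 -9\n")
            fh.write(f"F{i} {father} 0 0 1 -9\n")
            fh.write(f"F{i} {mother} 0 0 2 -9\n")
        for k, iid in enumerate(pedigree.unrelated):
            if any(iid in t for t in pedigree.trios):
                continue
            fh.write(f"U{k} {iid} 0 0 0 -9\n")


def genotypes_from_haplotypes(panel: HaplotypePanel) -> GenotypePanel:
    """Collapse a phased panel to dosages (copy1 + copy2; MISSING propagates)."""
    return GenotypePanel(panel.samples, panel.variants, panel.dosages())


# ---------------------------------------------------------------------------
# block-set output

def write_blocks_bed(block_set, variants: VariantMap, path) -> None:
    """BED (0-based half-open) spanning each block's contained variants."""
    with Path(path).open("w") as fh:
        for b in block_set.blocks:
            fh.write(f"{b.chrom}\t{b.start_bp - 1}\t{b.end_bp}\tblock\n")


def write_blocks_text(block_set, variants: VariantMap, path) -> None:
    """PLINK ``.blocks``-style output: one ``*``-prefixed variant-ID list per line."""
    with Path(path).open("w") as fh:
        for b in block_set.blocks:
            vids = variants.vid[b.start_idx : b.end_idx]
            fh.write("* " + " ".join(str(v) for v in vids) + "\n")


def read_blocks_bed(path, variants: VariantMap):
    """Read a BED file back into a BlockSet over ``variants``' site indices."""
    from .blocks import Block, BlockSet

    blocks = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            idx = variants.region_indices(chrom, start0 + 1, end)
            if len(idx) == 0:
                logger.warning("BED block %s:%d-%d contains no panel variants", chrom, start0, end)
                continue
            blocks.append(
                Block(
                    start_idx=int(idx[0]),
                    end_idx=int(idx[-1]) + 1,
                    chrom=chrom,
                    start_bp=int(variants.pos[idx[0]]),
                    end_bp=int(variants.pos[idx[-1]]),
                )
            )
    return BlockSet(method="bed", parameters={"path": str(path)}, blocks=blocks)
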