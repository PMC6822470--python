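"""Core in-memory containers for phased haplotype data.

Conventions used throughout the package:

* VCF positions are 1-based; internal site indices are 0-based.
* All internal block/interval bounds are half-open ``[start, end)``.
* Alleles and genotype dosages are small integers; :data:`MISSING` (-1)
  marks an absent call.  In a :class:`HaplotypePanel` the two copies of a
  site are either both present or both missing.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

#: Sentinel for a missing allele or genotype dosage.
MISSING: int = -1


def _as_object_array(values: Iterable) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values)
    if arr.dtype.kind not in ("U", "O", "S"):
        arr = arr.astype(str)
    return arr


@dataclasses.dataclass
class VariantMap:
    """Ordered biallelic SNP loci underlying a panel.

    Positions must be strictly increasing within each chromosome; only
    biallelic sites are representable (single ref/alt allele strings).
    """

    chrom: np.ndarray
    pos: np.ndarray
    vid: np.ndarray
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = _as_object_array(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.vid = _as_object_array(self.vid)
        self.ref = _as_object_array(self.ref)
        self.alt = _as_object_array(self.alt)
        n = len(self.pos)
        for name in ("chrom", "vid", "ref", "alt"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"VariantMap field {name!r} length mismatch")
        # strictly increasing positions within each chromosome
        for i in range(1, n):
            if self.chrom[i] == self.chrom[i - 1] and self.pos[i] <= self.pos[i - 1]:
                raise ValueError(
                    f"positions not strictly increasing at {self.chrom[i]}:{self.pos[i]}"
                )

    def __len__(self) -> int:
        return len(self.pos)

    def region_indices(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Site indices with ``start <= pos <= end`` (1-based inclusive)."""
        mask = (self.chrom == str(chrom)) & (self.pos >= start) & (self.pos <= end)
        return np.nonzero(mask)[0]

    def take(self, indices: Sequence[int] | np.ndarray) -> "VariantMap":
        idx = np.asarray(indices, dtype=np.intp)
        return VariantMap(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            vid=self.vid[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
        )

    def equals(self, other: "VariantMap") -> bool:
        return (
            len(self) == len(other)
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.pos == other.pos))
            and bool(np.all(self.vid == other.vid))
            and bool(np.all(self.ref == other.ref))
            and bool(np.all(self.alt == other.alt))
        )

    @classmethod
    def default(cls, n_sites: int, chrom: str = "1", spacing_bp: int = 1000) -> "VariantMap":
        """Evenly spaced synthetic A/G SNPs, ``spacing_bp`` apart."""
        pos = np.arange(n_sites, dtype=np.int64) * spacing_bp + 1
        return cls(
            chrom=np.full(n_sites, chrom, dtype=object),
            pos=pos,
            vid=np.array([f"snp{i}" for i in range(n_sites)], dtype=object),
            ref=np.full(n_sites, "A", dtype=object),
            alt=np.full(n_sites, "G", dtype=object),
        )


@dataclasses.dataclass
class HaplotypePanel:
    """Phased alleles: two ordered copies per individual per site.

    ``alleles`` has shape ``(n_samples, n_sites, 2)`` with values in
    ``{0, 1, MISSING}``; both copies at a site are missing together.
    """

    samples: list
    variants: VariantMap
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        expected = (len(self.samples), len(self.variants), 2)
        if self.alleles.shape != expected:
            raise ValueError(
                f"alleles shape {self.alleles.shape} != samples x sites x 2 {expected}"
            )
        half = (self.alleles == MISSING).sum(axis=2)
        if np.any(half == 1):
            raise ValueError("half-missing allele pair; both copies must be missing together")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.variants)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in panel") from None

    def pair(self, sample_id: str) -> np.ndarray:
        """The ``(n_sites, 2)`` allele matrix of one individual."""
        return self.alleles[self.sample_index(sample_id)]

    def dosages(self) -> np.ndarray:
        """Genotype dosage per individual x site; MISSING propagates."""
        dose = self.alleles.sum(axis=2, dtype=np.int8)
        dose[self.alleles[:, :, 0] == MISSING] = MISSING
        return dose

    def take_sites(self, indices: Sequence[int] | np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(indices, dtype=np.intp)
        return HaplotypePanel(self.samples, self.variants.take(idx), self.alleles[:, idx, :])

    def take_samples(self, sample_ids: Sequence[str]) -> "HaplotypePanel":
        idx = [self.sample_index(s) for s in sample_ids]
        return HaplotypePanel(list(sample_ids), self.variants, self.alleles[idx])

    def equals(self, other: "HaplotypePanel") -> bool:
        return (
            self.samples == other.samples
            and self.variants.equals(other.variants)
            and bool(np.array_equal(self.alleles, other.alleles))
        )


@dataclasses.dataclass
class GenotypePanel:
    """Unphased genotype dosages (count of alt alleles), individual x site."""

    samples: list
    variants: VariantMap
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        expected = (len(self.samples), len(self.variants))
        if self.dosage.shape != expected:
            raise ValueError(f"dosage shape {self.dosage.shape} != {expected}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.variants)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in panel") from None

    def row(self, sample_id: str) -> np.ndarray:
        return self.dosage[self.sample_index(sample_id)]

    def maf(self) -> np.ndarray:
        """Minor allele frequency per site over non-missing calls (NaN if none)."""
        called = self.dosage != MISSING
        n_alleles = 2 * called.sum(axis=0)
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / n_alleles
        return np.minimum(p, 1.0 - p)


@dataclasses.dataclass
class Pedigree:
    """Trio structure: (child, father, mother) triples plus unrelated samples."""

    trios: list
    unrelated: list

    def __post_init__(self) -> None:
        self.trios = [tuple(t) for t in self.trios]
        self.unrelated = list(self.unrelated)
        children = [t[0] for t in self.trios]
        if len(set(children)) != len(children):
            raise ValueError("a sample appears as child in more than one trio")

    @property
    def children(self) -> list:
        return [t[0] for t in self.trios]
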