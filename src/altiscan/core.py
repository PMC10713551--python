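"""Shared genomic containers.

All coordinates are 0-based, half-open ``[start, end)`` internally. File
readers/writers in :mod:`altiscan.formats_io` convert at the boundary
(VCF and GFF3 are 1-based on disk, BED is already 0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TE_CLASSES = ("LINE", "SINE", "LTR", "DNA", "RC", "Unknown")
SV_TYPES = ("DEL", "DUP", "INV", "INS")


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 haplotypes over ordered sites.

    alleles has shape ``(n_haplotypes, n_sites)``; ``positions`` are 0-based
    bp coordinates, strictly increasing. ``pop_of_haplotype`` gives one
    population label per haplotype row (two rows per diploid sample).
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    pop_of_haplotype: np.ndarray
    sample_ids: list[str]
    phased: bool = True

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.pop_of_haplotype = np.asarray(self.pop_of_haplotype)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        if self.alleles.shape[1] != self.positions.size:
            raise ValueError("positions / alleles shape mismatch")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("alleles must be 0/1")
        for pop in np.unique(self.pop_of_haplotype):
            if np.count_nonzero(self.pop_of_haplotype == pop) % 2:
                raise ValueError(f"odd haplotype count for population {pop!r}")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def population(self, label: str) -> "HaplotypeMatrix":
        """Sub-matrix of the haplotypes belonging to one population."""
        rows = self.pop_of_haplotype == label
        if not rows.any():
            raise KeyError(f"no haplotypes labeled {label!r}")
        sample_rows = [
            s for s, keep in zip(self.sample_ids, rows[::2]) if keep
        ] if len(self.sample_ids) * 2 == self.n_haplotypes else list(self.sample_ids)
        return HaplotypeMatrix(
            chrom=self.chrom,
            positions=self.positions,
            alleles=self.alleles[rows],
            pop_of_haplotype=self.pop_of_haplotype[rows],
            sample_ids=sample_rows,
            phased=self.phased,
        )


@dataclass(frozen=True)
class TEFeature:
    chrom: str
    start: int
    end: int
    te_class: str
    family: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"TE interval empty: [{self.start},{self.end})")
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown TE class {self.te_class!r}")


@dataclass(frozen=True)
class SVRecord:
    chrom: str
    start: int
    end: int
    sv_type: str
    length: int
    te_match_bases: int | None = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.length < 1:
            raise ValueError("SV length must be >= 1")
        if self.sv_type != "INS" and self.length != self.end - self.start:
            raise ValueError("length must equal end - start for DEL/DUP/INV")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene interval empty: [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic SNP as read from VCF (pos converted to 0-based)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    info_metrics: dict = field(default_factory=dict)
    genotypes: tuple = ()


@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int
    end: int
    n_snps: int = 0
    partial: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty window")

    @property
    def span(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and disjoint."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def overlap_len(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))
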