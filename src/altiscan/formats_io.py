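"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions: internal coordinates are always 0-based half-open.
VCF positions (1-based) and GFF3 intervals (1-based inclusive) are
converted on ingestion and converted back on writing; BED is already
0-based half-open.

SNP ingestion keeps biallelic SNPs only; skipped records (multi-allelic,
non-SNP) are counted, never dropped silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import GeneModel, HaplotypeMatrix, SiteRecord, TEFeature

log = logging.getLogger(__name__)

INFO_METRICS = ("QD", "FS", "MQ", "SOR", "MQRankSum", "ReadPosRankSum")


@dataclass
class VcfIngestStats:
    n_records: int = 0
    n_kept: int = 0
    n_skipped_multiallelic: int = 0
    n_skipped_non_snp: int = 0


def write_snp_vcf(haps: HaplotypeMatrix, path, contig_length: int | None = None,
                  ref_base: str = "A", alt_base: str = "T") -> None:
    """Write a haplotype matrix as minimal VCF 4.2 with phased GT.

    The simulator tracks 0/1 alleles without nucleotide identity, so REF and
    ALT are written as fixed placeholder bases.
    """
    n_samples = len(haps.sample_ids)
    if 2 * n_samples != haps.n_haplotypes:
        raise ValueError("sample_ids do not match haplotype count")
    length = contig_length or (int(haps.positions[-1]) + 1
                               if haps.n_sites else 1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={haps.chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(haps.sample_ids) + "\n")
        for j in range(haps.n_sites):
            col = haps.alleles[:, j]
            gts = "\t".join(f"{col[2*i]}|{col[2*i+1]}"
                            for i in range(n_samples))
            fh.write(f"{haps.chrom}\t{int(haps.positions[j]) + 1}\t.\t"
                     f"{ref_base}\t{alt_base}\t.\tPASS\t.\tGT\t{gts}\n")


def write_populations(haps: HaplotypeMatrix, path) -> None:
    """Two-column sample -> population table (TSV)."""
    pops = haps.pop_of_haplotype[::2]
    pd.DataFrame({"sample": haps.sample_ids, "population": pops}) \
        .to_csv(path, sep="\t", index=False)


def read_populations(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample"], df["population"]))


def read_snp_vcf(path, populations: dict[str, str] | None = None,
                 require_phased: bool = True,
                 ) -> tuple[HaplotypeMatrix, list[SiteRecord], VcfIngestStats]:
    """Read biallelic SNPs from a VCF into a haplotype matrix.

    ``populations`` maps sample id to population label (default: everything
    in one population ``"all"``). Multi-allelic and non-SNP records are
    skipped and counted. Missing GT is an error, as is an unphased
    genotype when ``require_phased`` (the error names the first offending
    record). Positions are converted to 0-based.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples / no GT field")
    pops = populations or {}
    pop_labels = np.repeat([pops.get(s, "all") for s in samples], 2)
    stats = VcfIngestStats()
    positions, columns, site_records = [], [], []
    chrom = None
    for var in vcf:
        stats.n_records += 1
        if len(var.ALT) != 1:
            stats.n_skipped_multiallelic += 1
            continue
        if len(var.REF) != 1 or len(var.ALT[0]) != 1 or \
                var.REF not in "ACGT" or var.ALT[0] not in "ACGT":
            stats.n_skipped_non_snp += 1
            continue
        try:
            gts = np.asarray(var.genotypes)  # (n_samples, 3): a0, a1, phased
        except Exception as exc:
            raise ValueError(f"{path}: record {var.CHROM}:{var.POS} "
                             f"has no usable GT") from exc
        if gts.ndim != 2 or gts.shape[1] < 3:
            raise ValueError(f"{path}: non-diploid GT at {var.CHROM}:{var.POS}")
        if require_phased and not np.all(gts[:, 2] == 1):
            bad = samples[int(np.nonzero(gts[:, 2] != 1)[0][0])]
            raise ValueError(
                f"{path}: unphased genotype at {var.CHROM}:{var.POS} "
                f"(sample {bad})")
        alleles = gts[:, :2].astype(np.int16).ravel()
        col = np.where(alleles < 0, 255, alleles).astype(np.uint8)
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise ValueError("multi-chromosome VCFs are read per chromosome")
        info = {}
        for key in INFO_METRICS:
            val = var.INFO.get(key)
            if val is not None:
                info[key] = float(val)
        positions.append(var.POS - 1)
        columns.append(col)
        site_records.append(SiteRecord(
            chrom=var.CHROM, pos=var.POS - 1, ref=var.REF, alt=var.ALT[0],
            info_metrics=info))
        stats.n_kept += 1
    vcf.close()
    if stats.n_skipped_multiallelic or stats.n_skipped_non_snp:
        log.info("%s: skipped %d multi-allelic and %d non-SNP records",
                 path, stats.n_skipped_multiallelic, stats.n_skipped_non_snp)
    alleles = (np.stack(columns, axis=1) if columns
               else np.zeros((2 * len(samples), 0), dtype=np.uint8))
    pos_arr = np.asarray(positions, dtype=np.int64)
    order = np.argsort(pos_arr, kind="stable")
    haps = HaplotypeMatrix(
        chrom=chrom or "chr1", positions=pos_arr[order],
        alleles=alleles[:, order] if alleles.size else alleles,
        pop_of_haplotype=pop_labels, sample_ids=samples,
        phased=require_phased)
    return haps, [site_records[i] for i in order], stats


def read_intervals(path, fmt: str):
    """Read BED (TE features) or GFF3 (gene models) into interval records.

    BED is 0-based half-open; GFF3 is 1-based inclusive and converted. GFF3
    returns gene rows only, with strand. Malformed lines and empty
    intervals raise errors naming the line number.
    """
    if fmt == "BED":
        return _read_bed(path)
    if fmt == "GFF3":
        return _read_gff3(path)
    raise ValueError(f"unknown interval format {fmt!r}")


def _read_bed(path) -> list[TEFeature]:
    feats = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 BED columns, "
                                 f"got {len(parts)}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{ln}: empty interval [{start},{end})")
            name = parts[3] if len(parts) > 3 else "Unknown"
            te_class = name.split("/")[0] if "/" in name else name
            if te_class not in ("LINE", "SINE", "LTR", "DNA", "RC"):
                te_class = "Unknown"
            feats.append(TEFeature(chrom, start, end, te_class, name))
    feats.sort(key=lambda f: (f.chrom, f.start))
    return feats


def _read_gff3(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 GFF3 columns, "
                                 f"got {len(parts)}")
            if parts[2] != "gene":
                continue
            start = int(parts[3]) - 1           # 1-based inclusive -> 0-based
            end = int(parts[4])
            if end <= start:
                raise ValueError(f"{path}:{ln}: empty interval after "
                                 f"conversion [{start},{end})")
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            gene_id = attrs.get("ID", f"gene_at_{parts[0]}_{start}")
            genes.append(GeneModel(gene_id, parts[0], start, end, parts[6]))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_bed(features: list[TEFeature], path) -> None:
    with open(path, "w") as fh:
        for f in sorted(features, key=lambda f: (f.chrom, f.start, f.end)):
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.family or f.te_class}\n")


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(f"{g.chrom}\taltiscan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")


WINDOW_TABLE_COLUMNS = ("chrom", "start", "end", "n_snps")


def write_window_table(df: pd.DataFrame, path) -> None:
    """Deterministic TSV: fixed column order, floats at 6 significant
    digits, rows sorted by (chrom, start); undefined values rendered NA."""
    lead = [c for c in WINDOW_TABLE_COLUMNS if c in df.columns]
    rest = [c for c in df.columns if c not in lead]
    out = df[lead + rest].sort_values(["chrom", "start"]) \
        if {"chrom", "start"} <= set(df.columns) else df[lead + rest]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g",
               na_rep="NA")


def read_window_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
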