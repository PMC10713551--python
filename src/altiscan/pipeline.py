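"""End-to-end scan orchestration: simulate/ingest -> QC -> window statistics
-> XP-EHH -> sweep candidates -> TE-SV contrasts, reproducible per seed.

One structured config (dict, typically loaded from YAML) drives a run; all
thresholds default to the scan's standard values (20-kb windows / >= 10
SNPs / 1% tails / >= 2 methods / +-20-kb gene extension / 50 bp - 100 kb SV
size / 90% TE-overlap / 10-kb SV windows / +-3-kb flanks). Results land in
a run directory with a fixed layout plus a manifest recording every
parameter, the seed and input checksums.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import formats_io, simdata, sweepcall, tesv, winstats, xpscan
from .core import GeneModel, HaplotypeMatrix
from .variant_qc import apply_hard_filters

SCAN_DEFAULTS = {
    "window_size": 20_000, "min_snps": 10, "fraction": 0.01,
    "min_support": 2, "extend_bp": 20_000,
}
TESV_DEFAULTS = {
    "window_size": 10_000, "min_len": 50, "max_len": 100_000, "flank": 3_000,
}


class ConfigError(ValueError):
    pass


@dataclass
class ScanResult:
    window_table: pd.DataFrame
    candidates: list
    method_windows: dict
    sv_table: pd.DataFrame | None
    tesv_window_table: pd.DataFrame | None
    gene_counts: pd.DataFrame | None
    manifest: dict
    haps: HaplotypeMatrix
    genes: list[GeneModel]
    truth: object | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _validate(config: dict) -> tuple[str, str]:
    pops = config.get("populations") or {}
    for key in ("focal", "ref"):
        if not pops.get(key):
            raise ConfigError(f"config field populations.{key} is required")
    return pops["focal"], pops["ref"]


def run_full_scan(config: dict, outdir) -> ScanResult:
    """Run the full scan described by ``config`` into ``outdir``.

    ``config`` must name either a ``simulate`` block or an ``inputs`` block
    (vcf, populations, genes, optionally te/sv tables), plus a
    ``populations`` block with the focal and reference labels.
    Deterministic for a fixed ``seed``: two runs produce byte-identical
    result files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    focal, ref = _validate(config)
    seed = int(config.get("seed", 0))
    scan_cfg = {**SCAN_DEFAULTS, **(config.get("scan") or {})}
    tesv_cfg = {**TESV_DEFAULTS, **(config.get("tesv") or {})}
    rng = np.random.default_rng(seed)
    input_checksums: dict[str, str] = {}
    truth = None
    te_feats = svs = None

    if "simulate" in config:
        sim_cfg = dict(config["simulate"] or {})
        te_cfg = sim_cfg.pop("te", None)
        sv_cfg = sim_cfg.pop("sv", None)
        params = simdata.SimParams(**{**sim_cfg, "seed": seed})
        haps, truth = simdata.simulate_two_pop(params)
        # simulated populations are labeled ref/focal by construction
        if {focal, ref} != {"focal", "ref"}:
            raise ConfigError(
                "simulated runs use population labels 'focal' and 'ref'; "
                f"config names {focal!r}/{ref!r}")
        genome_length = params.seq_length
        genes = simdata.simulate_gene_models(genome_length)
        formats_io.write_snp_vcf(haps, outdir / "snps.vcf",
                                 contig_length=genome_length)
        formats_io.write_populations(haps, outdir / "populations.tsv")
        formats_io.write_gff3(genes, outdir / "genes.gff3")
        pd.DataFrame({
            "position": truth.positions,
            "count_ref": truth.count_ref,
            "count_focal": truth.count_focal,
        }).to_csv(outdir / "truth.tsv", sep="\t", index=False)
        if te_cfg is not None:
            te_feats = simdata.simulate_te_annotation(
                genome_length, seed=int(rng.integers(0, 2**31 - 1)), **te_cfg)
            formats_io.write_bed(te_feats, outdir / "te.bed")
            if sv_cfg is not None:
                svs, _sv_truth = simdata.simulate_sv_callset(
                    te_feats, genome_length=genome_length,
                    seed=int(rng.integers(0, 2**31 - 1)), **sv_cfg)
    else:
        inputs = config.get("inputs") or {}
        for key in ("vcf", "populations", "genes"):
            if key not in inputs:
                raise ConfigError(f"config field inputs.{key} is required")
        pops_map = formats_io.read_populations(inputs["populations"])
        haps, sites, _ = formats_io.read_snp_vcf(inputs["vcf"], pops_map)
        labels = set(np.unique(haps.pop_of_haplotype))
        if focal not in labels or ref not in labels:
            raise ConfigError(
                f"population labels {sorted(labels)} in the VCF do not "
                f"include focal={focal!r} and ref={ref!r}")
        flags, _ = apply_hard_filters(sites)
        if not flags.all():
            keep = np.nonzero(flags)[0]
            haps = HaplotypeMatrix(haps.chrom, haps.positions[keep],
                                   haps.alleles[:, keep],
                                   haps.pop_of_haplotype, haps.sample_ids)
        genes = formats_io.read_intervals(inputs["genes"], "GFF3")
        genome_length = int(config.get("genome_length")
                            or (haps.positions[-1] + 1 if haps.n_sites else 1))
        if "te" in inputs:
            te_feats = formats_io.read_intervals(inputs["te"], "BED")
        for key, p in inputs.items():
            input_checksums[key] = _sha256(Path(p))

    # relabel to internal focal/ref views
    windows = winstats.make_windows({haps.chrom: genome_length},
                                    size=scan_cfg["window_size"])
    scores = xpscan.xpehh_scan(haps, focal=focal, ref=ref)
    mean_xpehh = xpscan.window_mean_xpehh(scores, haps.positions, windows)
    table = winstats.compute_window_table(haps, windows, focal=focal, ref=ref,
                                          mean_xpehh=mean_xpehh)
    candidates, method_windows = sweepcall.scan_candidates(
        table, genes, fraction=scan_cfg["fraction"],
        min_snps=scan_cfg["min_snps"], extend_bp=scan_cfg["extend_bp"],
        min_support=scan_cfg["min_support"])

    sv_table = tesv_window_table = gene_counts_df = None
    if te_feats is not None and svs is not None:
        svs_f = tesv.filter_svs(svs, tesv_cfg["min_len"], tesv_cfg["max_len"])
        labels = tesv.classify_callset(svs_f, te_feats)
        sv_table = pd.DataFrame({
            "chrom": [s.chrom for s in svs_f],
            "start": [s.start for s in svs_f],
            "end": [s.end for s in svs_f],
            "sv_type": [s.sv_type for s in svs_f],
            "length": [s.length for s in svs_f],
            "label": labels,
        })
        w10 = winstats.make_windows({haps.chrom: genome_length},
                                    size=tesv_cfg["window_size"])
        flags10 = tesv.flag_windows_tesv(w10, svs_f, labels)
        h_ref, h_foc = haps.population(ref), haps.population(focal)
        fst10 = np.array([winstats.window_fst(h_ref, h_foc, w) for w in w10])
        tesv_window_table = pd.DataFrame({
            "chrom": [w.chrom for w in w10],
            "start": [w.start for w in w10],
            "end": [w.end for w in w10],
            "fst": fst10,
            "with_tesv": flags10,
        })
        counts = tesv.count_tesv_gene_regions(
            genes, svs_f, labels, flank=tesv_cfg["flank"],
            chrom_lengths={haps.chrom: genome_length})
        gene_counts_df = pd.DataFrame({
            "gene_id": [g.gene_id for g in genes],
            "upstream": counts[:, 0], "gene_body": counts[:, 1],
            "downstream": counts[:, 2],
        })

    formats_io.write_window_table(table, outdir / "windows.tsv")
    cand_df = pd.DataFrame(
        [{"gene_id": c.gene_id,
          "n_methods": len(c.supporting_methods),
          "methods": ",".join(sorted(c.supporting_methods))}
         for c in candidates],
        columns=["gene_id", "n_methods", "methods"])
    cand_df.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    if sv_table is not None:
        sv_table.to_csv(outdir / "sv_labels.tsv", sep="\t", index=False)
        formats_io.write_window_table(tesv_window_table,
                                      outdir / "tesv_windows.tsv")
        gene_counts_df.to_csv(outdir / "gene_tesv_counts.tsv", sep="\t",
                              index=False)

    manifest = {
        "seed": seed,
        "scan": scan_cfg,
        "tesv": tesv_cfg,
        "populations": {"focal": focal, "ref": ref},
        "simulate": ({k: v for k, v in sorted(config["simulate"].items())
                      if k not in ("te", "sv")}
                     if "simulate" in config else None),
        "xpehh": {"cutoff": xpscan.DEFAULT_CUTOFF,
                  "max_gap_bp": xpscan.DEFAULT_MAX_GAP,
                  "max_extend_bp": xpscan.DEFAULT_MAX_EXTEND},
        "input_checksums": dict(sorted(input_checksums.items())),
        "n_candidates": len(cand_df),
    }
    (outdir / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True))
    return ScanResult(window_table=table, candidates=candidates,
                      method_windows=method_windows, sv_table=sv_table,
                      tesv_window_table=tesv_window_table,
                      gene_counts=gene_counts_df, manifest=manifest,
                      haps=haps, genes=genes, truth=truth)
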