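"""Tail selection, multi-evidence intersection and candidate-gene calling.

The scan keeps, per statistic, the most extreme 1% of eligible 20-kb
windows (eligible = at least 10 SNPs and a defined value), merges the
selected windows of each method into regions, extends each region by 20 kb
on both sides, and assigns genes overlapped by regions from at least two
methods. Tail directions are fixed by what each statistic means for
selection in the focal population:

* ``pi_ratio`` (focal/reference): lower tail - diversity lost in the swept
  population;
* ``fst``: upper tail - elevated differentiation;
* ``xpehh`` (focal vs reference, standardized): upper tail - longer
  haplotype homozygosity in the focal population;
* ``tajima_d`` (focal population): lower tail - excess of rare variants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GeneModel, merge_intervals, overlap_len

TAIL_DIRECTIONS: dict[str, str] = {
    "pi_ratio": "lower",
    "fst": "upper",
    "xpehh": "upper",
    "tajima_d": "lower",
}


@dataclass
class SweepCandidateGene:
    gene_id: str
    supporting_methods: frozenset[str]
    supporting_windows: dict[str, list[tuple[str, int, int]]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        self.supporting_methods = frozenset(self.supporting_methods)


def select_tail_windows(stat_table: pd.DataFrame, statistic: str,
                        tail: str, fraction: float = 0.01,
                        min_snps: int = 10) -> pd.DataFrame:
    """Windows in the extreme ``fraction`` tail of one statistic.

    Windows with fewer than ``min_snps`` SNPs or an undefined statistic are
    excluded before ranking. The threshold is the nearest-rank quantile
    (``ceil(fraction * n)``-th most extreme value, hence always >= 1
    selected window); every window at least as extreme as the threshold is
    included, so ties at the threshold are kept.
    """
    if tail not in ("upper", "lower"):
        raise ValueError(f"bad tail {tail!r}")
    if statistic not in stat_table.columns:
        raise KeyError(f"no column {statistic!r} in the window table")
    eligible = stat_table[(stat_table["n_snps"] >= min_snps)
                          & stat_table[statistic].notna()]
    n = len(eligible)
    if n == 0:
        return eligible
    k = max(1, math.ceil(fraction * n))
    if n < math.ceil(1.0 / fraction):
        warnings.warn(
            f"only {n} eligible windows for a {fraction:.0%} tail of "
            f"{statistic}; ceiling rule keeps {k}", stacklevel=2)
    values = eligible[statistic].to_numpy()
    srt = np.sort(values)
    threshold = srt[n - k] if tail == "upper" else srt[k - 1]
    mask = values >= threshold if tail == "upper" else values <= threshold
    return eligible[mask]


def _windows_to_regions(windows: pd.DataFrame, extend_bp: int,
                        ) -> dict[str, list[tuple[int, int]]]:
    """Merge selected windows per chromosome and extend both sides."""
    regions: dict[str, list[tuple[int, int]]] = {}
    for chrom, grp in windows.groupby("chrom"):
        ivals = [(max(0, int(s) - extend_bp), int(e) + extend_bp)
                 for s, e in zip(grp["start"], grp["end"])]
        regions[str(chrom)] = merge_intervals(ivals)
    return regions


def call_candidate_genes(method_windows: dict[str, pd.DataFrame],
                         genes: list[GeneModel], extend_bp: int = 20_000,
                         min_support: int = 2) -> list[SweepCandidateGene]:
    """Genes overlapped by the extended regions of >= ``min_support`` methods.

    ``method_windows`` maps a method name to its selected-window table
    (columns chrom/start/end). The overlap predicate is >= 1 bp
    intersection of the half-open extended region with the gene body.
    """
    method_regions = {m: _windows_to_regions(w, extend_bp)
                      for m, w in method_windows.items()}
    out: list[SweepCandidateGene] = []
    for gene in genes:
        support: dict[str, list[tuple[str, int, int]]] = {}
        for method, regions in method_regions.items():
            hits = [(gene.chrom, s, e)
                    for s, e in regions.get(gene.chrom, [])
                    if overlap_len(s, e, gene.start, gene.end) > 0]
            if hits:
                support[method] = hits
        if len(support) >= min_support:
            out.append(SweepCandidateGene(
                gene_id=gene.gene_id,
                supporting_methods=frozenset(support),
                supporting_windows=support))
    return out


def scan_candidates(stat_table: pd.DataFrame, genes: list[GeneModel],
                    fraction: float = 0.01, min_snps: int = 10,
                    extend_bp: int = 20_000, min_support: int = 2,
                    statistics: dict[str, str] | None = None,
                    column_map: dict[str, str] | None = None,
                    ) -> tuple[list[SweepCandidateGene],
                               dict[str, pd.DataFrame]]:
    """Full tail-selection + gene-assignment pass over a window table.

    ``statistics`` maps method name to tail direction (defaults to
    :data:`TAIL_DIRECTIONS`); ``column_map`` maps method name to the window
    table column holding it (default: pi_ratio, fst, mean_xpehh,
    tajima_d_focal).
    """
    directions = dict(TAIL_DIRECTIONS if statistics is None else statistics)
    columns = {"pi_ratio": "pi_ratio", "fst": "fst", "xpehh": "mean_xpehh",
               "tajima_d": "tajima_d_focal"}
    if column_map:
        columns.update(column_map)
    method_windows: dict[str, pd.DataFrame] = {}
    for method, tail in directions.items():
        col = columns[method]
        if col not in stat_table.columns:
            continue
        sel = select_tail_windows(stat_table, col, tail, fraction, min_snps)
        method_windows[method] = sel
    candidates = call_candidate_genes(method_windows, genes, extend_bp,
                                      min_support)
    return candidates, method_windows
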