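"""Transposon-mediated structural-variant classification and contrasts.

An SV is size-filtered (50 bp to 100 kb inclusive), then classified by the
fraction of its locus covered by the union of TE annotations: at least 90%
covered = ``TE-SV``, exactly 0 = ``No TE-SV``, anything in between =
``uncertain``. Classified SVs drive 10-kb window differentiation contrasts
(windows with vs without TE-SVs) and per-gene TE-SV counts for the gene
body and its 3-kb flanks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (GeneModel, GenomicWindow, SVRecord, TEFeature,
                   merge_intervals, overlap_len)

TE_SV = "TE-SV"
UNCERTAIN = "uncertain"
NO_TE_SV = "No TE-SV"


def filter_svs(svs: list[SVRecord], min_len: int = 50,
               max_len: int = 100_000) -> list[SVRecord]:
    """Keep SVs with ``min_len <= length <= max_len`` (inclusive bounds)."""
    return [sv for sv in svs if min_len <= sv.length <= max_len]


def te_union(te: list[TEFeature]) -> dict[str, list[tuple[int, int]]]:
    """Per-chromosome merged TE intervals (prevents double counting of
    nested or overlapping repeat annotations)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in te:
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    return {c: merge_intervals(v) for c, v in by_chrom.items()}


def te_overlap_fraction(sv: SVRecord,
                        union: dict[str, list[tuple[int, int]]]) -> float:
    """Fraction of the SV locus covered by the TE union, in [0, 1].

    For INS records carrying ``te_match_bases`` the fraction is
    ``te_match_bases / length`` (the footprint is a point).
    """
    if sv.sv_type == "INS" and sv.te_match_bases is not None:
        return min(1.0, sv.te_match_bases / sv.length)
    span = sv.end - sv.start
    if span == 0:
        raise ValueError("zero-length SV locus")
    runs = union.get(sv.chrom, [])
    ov = sum(overlap_len(s, e, sv.start, sv.end) for s, e in runs)
    return ov / span


def classify_te_sv(fraction: float) -> str:
    """90%/0 rule: >= 0.9 -> TE-SV, == 0 -> No TE-SV, else uncertain."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if fraction >= 0.9:
        return TE_SV
    if fraction == 0:
        return NO_TE_SV
    return UNCERTAIN


def classify_callset(svs: list[SVRecord], te: list[TEFeature]) -> list[str]:
    """Label every SV by its TE-union overlap fraction."""
    union = te_union(te)
    return [classify_te_sv(te_overlap_fraction(sv, union)) for sv in svs]


def flag_windows_tesv(windows: list[GenomicWindow], svs: list[SVRecord],
                      labels: list[str],
                      te_by_class: dict[int, str] | None = None,
                      class_filter: str | None = None,
                      strict_without: bool = False) -> np.ndarray:
    """True per window when >= 1 TE-SV intersects it.

    ``uncertain`` SVs are ignored (a window touched only by uncertain SVs is
    "without"); ``strict_without=True`` additionally drops such windows by
    returning -1 there (with=1, without=0, excluded=-1 as an int array is
    avoided: strict mode marks them via NaN-free int8 of -1).
    ``class_filter`` restricts to TE-SVs of one TE class, using
    ``te_by_class`` (sv index -> dominant TE class).
    """
    flags = np.zeros(len(windows), dtype=np.int8)
    tesv = []
    for i, (sv, lab) in enumerate(zip(svs, labels)):
        if lab != TE_SV:
            continue
        if class_filter is not None:
            if te_by_class is None or te_by_class.get(i) != class_filter:
                continue
        tesv.append(sv)
    for k, w in enumerate(windows):
        for sv in tesv:
            if sv.chrom == w.chrom and overlap_len(sv.start, sv.end,
                                                   w.start, w.end) > 0:
                flags[k] = 1
                break
    if strict_without:
        unc = [sv for sv, lab in zip(svs, labels) if lab == UNCERTAIN]
        for k, w in enumerate(windows):
            if flags[k] == 0 and any(
                    sv.chrom == w.chrom
                    and overlap_len(sv.start, sv.end, w.start, w.end) > 0
                    for sv in unc):
                flags[k] = -1
    return flags


@dataclass
class ContrastResult:
    mean_with: float
    mean_without: float
    ci_with: tuple[float, float]
    ci_without: tuple[float, float]
    p_value: float
    test: str
    n_with: int
    n_without: int


def _boot_ci(values: np.ndarray, n_boot: int, rng: np.random.Generator,
             level: float = 0.95) -> tuple[float, float]:
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    a = (1 - level) / 2
    return (float(np.quantile(means, a)), float(np.quantile(means, 1 - a)))


def contrast_windows(values: np.ndarray, flags: np.ndarray,
                     chroms: np.ndarray | None = None,
                     group_by_chrom: bool = False, n_boot: int = 1000,
                     seed: int = 0) -> ContrastResult:
    """Compare a window statistic between with- and without-TE-SV windows.

    Windows flagged -1 (strict-mode exclusions) or with NaN values are
    dropped. With ``group_by_chrom`` the per-chromosome means of the two
    groups are compared by a paired two-sided Wilcoxon signed-rank test;
    otherwise windows are compared directly by a two-sided Mann-Whitney U
    test. Group means are exact; CIs are seeded percentile bootstraps over
    windows.
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(flags)
    ok = (flags >= 0) & ~np.isnan(values)
    values, flags = values[ok], flags[ok]
    if chroms is not None:
        chroms = np.asarray(chroms)[ok]
    w = values[flags == 1]
    wo = values[flags == 0]
    if w.size == 0 or wo.size == 0:
        raise ValueError("both groups need at least one window")
    rng = np.random.default_rng(seed)
    if group_by_chrom:
        if chroms is None:
            raise ValueError("group_by_chrom requires chromosome labels")
        pairs = []
        for c in np.unique(chroms):
            a = values[(chroms == c) & (flags == 1)]
            b = values[(chroms == c) & (flags == 0)]
            if a.size and b.size:
                pairs.append((a.mean(), b.mean()))
        if len(pairs) < 2:
            raise ValueError("need >= 2 chromosomes with both groups")
        a, b = map(np.asarray, zip(*pairs))
        stat = stats.wilcoxon(a, b, alternative="two-sided")
        test = "wilcoxon_paired_by_chrom"
        p = float(stat.pvalue)
    else:
        stat = stats.mannwhitneyu(w, wo, alternative="two-sided")
        test = "mannwhitneyu"
        p = float(stat.pvalue)
    return ContrastResult(
        mean_with=float(w.mean()), mean_without=float(wo.mean()),
        ci_with=_boot_ci(w, n_boot, rng), ci_without=_boot_ci(wo, n_boot, rng),
        p_value=p, test=test, n_with=int(w.size), n_without=int(wo.size))


def count_tesv_gene_regions(genes: list[GeneModel], svs: list[SVRecord],
                            labels: list[str], flank: int = 3_000,
                            chrom_lengths: dict[str, int] | None = None,
                            ) -> "np.ndarray":
    """Per-gene TE-SV counts for (upstream flank, gene body, downstream flank).

    Upstream/downstream follow gene strand; flanks are half-open and clipped
    at chromosome ends; an SV is counted in every region it intersects.
    Returns an (n_genes, 3) int array ordered like ``genes``.
    """
    tesv = [sv for sv, lab in zip(svs, labels) if lab == TE_SV]
    out = np.zeros((len(genes), 3), dtype=np.int64)
    for gi, gene in enumerate(genes):
        clen = None if chrom_lengths is None else chrom_lengths.get(gene.chrom)
        left = (max(0, gene.start - flank), gene.start)
        right = (gene.end, gene.end + flank if clen is None
                 else min(clen, gene.end + flank))
        if gene.strand == "+":
            regions = [left, (gene.start, gene.end), right]
        else:
            regions = [right, (gene.start, gene.end), left]
        for sv in tesv:
            if sv.chrom != gene.chrom:
                continue
            for ri, (s, e) in enumerate(regions):
                if e > s and overlap_len(sv.start, sv.end, s, e) > 0:
                    out[gi, ri] += 1
    return out
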