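"""Processed-pseudogene classification, NG86 Ka/Ks, expression tiers and
LTR-chimera detection for a ribosomal-protein-like gene family.

Classification of a homology candidate (given its translated coverage of
the intact protein, intron count, promoter flag and protein-domain hit):

* ``discarded`` - no domain hit, or coverage < 70%;
* ``complete``  - coverage >= 95% AND >= 1 intron AND a promoter region;
* ``processed`` - everything else (intronless/promoterless retrocopies).

Ka/Ks is the Nei-Gojobori (1986) estimator with Jukes-Cantor correction.
Conventions shared by the implementation and its documentation: synonymous
and non-synonymous site fractions use a denominator of 3 per codon
position, with single-base changes that create stop codons excluded from
both classes; multi-step codon differences average the synonymous /
non-synonymous step counts over all mutational pathways, excluding
pathways that pass through a stop codon (unless every pathway does).
Site counts are averaged over the two sequences.

Expression tiers on x = log2(TPM + 1): ``normal`` x >= 1,
``low`` 0.1 <= x < 1, ``none`` x < 0.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np

from .genetic_code import CODON_TABLE

BASES = "ACGT"


@dataclass
class ChimeraRecord:
    """An LTR / pseudogene / INTERNAL / LTR layout around a retrocopy."""

    chrom: str
    strand: str
    ltr5_len: int
    ltr3_len: int
    five_prime_shorter: bool
    start: int
    end: int


@dataclass
class PseudogeneCandidate:
    candidate_id: str
    coverage: float
    intron_count: int
    has_promoter: bool
    has_domain_hit: bool
    category: str | None = None
    ka: float | None = None
    ks: float | None = None
    ka_ks: float | None = None
    expression_tier: str | None = None
    chimera: ChimeraRecord | None = None


def classify_candidate(coverage: float, intron_count: int, has_promoter: bool,
                       has_domain_hit: bool, min_coverage: float = 0.70,
                       complete_coverage: float = 0.95) -> str:
    if not 0 <= coverage <= 1:
        raise ValueError("coverage must be in [0, 1]")
    if not has_domain_hit or coverage < min_coverage:
        return "discarded"
    if coverage >= complete_coverage and intron_count >= 1 and has_promoter:
        return "complete"
    return "processed"


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts of one codon."""
    syn = non = 0.0
    aa = CODON_TABLE[codon]
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            alt_aa = CODON_TABLE[alt]
            if alt_aa == "*":
                continue
            if alt_aa == aa:
                syn += 1 / 3
            else:
                non += 1 / 3
    return syn, non


@lru_cache(maxsize=None)
def _codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) differences between two codons,
    averaged over mutational pathways."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for step, i in enumerate(order):
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if CODON_TABLE[nxt] == "*" and step < len(order) - 1:
                blocked = True
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    open_paths = [(s, n) for s, n, b in paths if not b]
    if not open_paths:
        open_paths = [(s, n) for s, n, _ in paths]
    sd = sum(p[0] for p in open_paths) / len(open_paths)
    nd = sum(p[1] for p in open_paths) / len(open_paths)
    return sd, nd


def _check_cds(cds: str, name: str) -> None:
    if len(cds) % 3:
        raise ValueError(f"{name}: length not divisible by 3")
    for i in range(0, len(cds), 3):
        if CODON_TABLE.get(cds[i:i + 3]) == "*":
            raise ValueError(f"{name}: internal stop codon at {i}")
        if cds[i:i + 3] not in CODON_TABLE:
            raise ValueError(f"{name}: non-ACGT codon at {i}")


def ng86_kaks(cds_a: str, cds_b: str) -> tuple[float, float, float]:
    """Nei-Gojobori Ka, Ks and Ka/Ks for two aligned, in-frame CDS.

    Returns (Ka, Ks, Ka/Ks); the ratio is NaN when Ks = 0. A saturated
    proportion (p >= 3/4, where the Jukes-Cantor correction diverges) gives
    an infinite distance, so e.g. a fully synonymous single-codon pair has
    Ks = inf and ratio 0.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences must be aligned to equal length")
    _check_cds(cds_a, "cds_a")
    _check_cds(cds_b, "cds_b")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = _codon_diffs(ca, cb)
        Sd += sd
        Nd += nd

    def _jc(p: float) -> float:
        if p == 0:
            return 0.0
        if p >= 0.75:
            return math.inf
        return -0.75 * math.log(1 - 4 * p / 3)

    ka = _jc(Nd / N) if N > 0 else float("nan")
    ks = _jc(Sd / S) if S > 0 else float("nan")
    ratio = float("nan")
    if not math.isnan(ka) and not math.isnan(ks) and ks > 0:
        with np.errstate(invalid="ignore"):
            ratio = float(np.float64(ka) / np.float64(ks))
    return ka, ks, ratio


# ---------------------------------------------------------------------------
# expression tiers
# ---------------------------------------------------------------------------

def classify_expression(tpm: float) -> str:
    """Tier from log2(TPM + 1): >=1 normal, >=0.1 low, else none."""
    if tpm < 0:
        raise ValueError("TPM must be >= 0")
    x = math.log2(tpm + 1.0)
    if x >= 1.0:
        return "normal"
    if x >= 0.1:
        return "low"
    return "none"


# ---------------------------------------------------------------------------
# chimera detection
# ---------------------------------------------------------------------------

def detect_chimera(segments, gap_tolerance: int = 1_000,
                   strand: str = "+") -> ChimeraRecord | None:
    """Detect a 5'-LTR / pseudogene / INTERNAL / 3'-LTR layout.

    ``segments`` is an iterable of ``(label, start, end)`` or
    ``(label, chrom, start, end)`` tuples with labels in
    {LTR, pseudogene, INTERNAL, other}. The pattern must occur in 5'-to-3'
    order on one chromosome (orientation follows ``strand``), allowing
    interleaved ``other`` segments; consecutive pattern members may be at
    most ``gap_tolerance`` bp apart. Returns None when the pattern is
    incomplete or split across chromosomes.
    """
    norm = []
    for seg in segments:
        if len(seg) == 3:
            label, start, end = seg
            chrom = "chr"
        else:
            label, chrom, start, end = seg
        norm.append((label, chrom, int(start), int(end)))
    if not norm:
        return None
    chroms = {c for _, c, _, _ in norm}
    if len(chroms) > 1:
        return None
    chrom = chroms.pop()
    ordered = sorted(norm, key=lambda s: (s[2], s[3]), reverse=(strand == "-"))
    wanted = ["LTR", "pseudogene", "INTERNAL", "LTR"]
    chosen: list[tuple[str, str, int, int]] = []
    for seg in ordered:
        if len(chosen) == 4:
            break
        if seg[0] != wanted[len(chosen)]:
            continue
        if chosen:
            prev = chosen[-1]
            if strand == "-":
                gap = prev[2] - seg[3]
            else:
                gap = seg[2] - prev[3]
            if gap > gap_tolerance:
                continue
        chosen.append(seg)
    if len(chosen) < 4:
        return None
    ltr5 = chosen[0][3] - chosen[0][2]
    ltr3 = chosen[3][3] - chosen[3][2]
    all_pos = [s for _, _, s, _ in chosen] + [e for _, _, _, e in chosen]
    return ChimeraRecord(chrom=chrom, strand=strand, ltr5_len=ltr5,
                         ltr3_len=ltr3, five_prime_shorter=ltr5 < ltr3,
                         start=min(all_pos), end=max(all_pos))
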