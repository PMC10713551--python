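"""LTR retrotransposon families, solo/complete accounting and dating.

The two LTRs of a complete element are identical at insertion and diverge
with age; the Kimura two-parameter distance k between them converts to an
insertion time T = k / (2 r) with a substitution rate r per site per year
(default 5.6e-9). Solo-LTRs are the footprints of unequal recombination;
the ratio solo / complete is the "unequal recombination rate" proxy for
LTR-removal intensity. Family assignment follows the 80-80-80 rule:
two LTR sequences belong to one family when a pairwise alignment shows
>= 80% identity over an aligned span of >= 80 bp covering >= 80% of the
shorter sequence; families are the connected components of that relation.

CpG columns are not excluded from the K2P counts by default (a masking
option of upstream repeat pipelines); ``exclude_cpg`` enables it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

DEFAULT_SUBSTITUTION_RATE = 5.6e-9   # per site per year

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
GAP_CHARS = {"-", ".", "N", "n"}


@dataclass
class LTRElementRecord:
    """A complete (paired-LTR) or solo LTR element."""

    element_id: str
    kind: str                       # "complete" | "solo"
    ltr5_seq: str | None = None
    ltr3_seq: str | None = None
    solo_seq: str | None = None
    internal_len: int = 0
    family_id: str | None = None
    k: float | None = None
    T: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("complete", "solo"):
            raise ValueError(f"bad element kind {self.kind!r}")
        if self.kind == "complete" and not (self.ltr5_seq and self.ltr3_seq):
            raise ValueError("complete element needs both LTR sequences")
        if self.kind == "solo" and not self.solo_seq:
            raise ValueError("solo element needs solo_seq")

    @property
    def representative_seq(self) -> str:
        return self.solo_seq if self.kind == "solo" else self.ltr5_seq


class SaturationError(ValueError):
    """K2P distance undefined: substitution proportions out of domain."""


def k2p_distance(aligned_a: str, aligned_b: str) -> float:
    """Kimura two-parameter distance between equal-length aligned sequences.

    k = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P and Q the transition
    and transversion proportions over non-gap columns.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    n = ts = tv = 0
    for a, b in zip(aligned_a.upper(), aligned_b.upper()):
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        n += 1
        if a == b:
            continue
        if (a in PURINES) == (b in PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable (non-gap) columns")
    P, Q = ts / n, tv / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"saturated alignment (P={P:.3f}, Q={Q:.3f})")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def make_pairwise_aligner() -> Align.PairwiseAligner:
    """Global Needleman-Wunsch aligner with fixed default scores."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -0.5
    return aligner


def _alignment_identity_span(seq_a: str, seq_b: str,
                             aligner: Align.PairwiseAligner,
                             ) -> tuple[float, int]:
    """(identity over aligned non-gap columns, aligned-column count)."""
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    a, b = aln[0], aln[1]
    matches = span = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        span += 1
        if x == y:
            matches += 1
    return (matches / span if span else 0.0), span


def assign_ltr_families(sequences: dict[str, str],
                        min_identity: float = 0.80, min_span_bp: int = 80,
                        min_span_fraction: float = 0.80,
                        aligner: Align.PairwiseAligner | None = None,
                        ) -> dict[str, str]:
    """80-80-80 single-linkage family labels for LTR sequences.

    Returns id -> family label; family labels are canonicalized by the
    lexicographically smallest member id, so assignment is invariant under
    input order. Singleton families are allowed.
    """
    ids = sorted(sequences)
    if aligner is None:
        aligner = make_pairwise_aligner()
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ident, span = _alignment_identity_span(sequences[a], sequences[b],
                                                   aligner)
            shorter = min(len(sequences[a]), len(sequences[b]))
            if (ident >= min_identity and span >= min_span_bp
                    and span >= min_span_fraction * shorter):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    return {i: f"family_{find(i)}" for i in ids}


def classify_solo_complete(elements: list[LTRElementRecord],
                           ) -> tuple[int, int, float]:
    """(n_complete, n_solo, unequal recombination rate = solo/complete).

    The ratio is NaN when there is no complete element.
    """
    n_complete = sum(1 for e in elements if e.kind == "complete")
    n_solo = sum(1 for e in elements if e.kind == "solo")
    ratio = n_solo / n_complete if n_complete else float("nan")
    return n_complete, n_solo, ratio


def insertion_time(k: float, rate: float = DEFAULT_SUBSTITUTION_RATE) -> float:
    """Insertion time in years: T = k / (2 r)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    return k / (2.0 * rate)


def date_elements(elements: list[LTRElementRecord],
                  rate: float = DEFAULT_SUBSTITUTION_RATE,
                  aligner: Align.PairwiseAligner | None = None,
                  pre_aligned: bool = False) -> pd.DataFrame:
    """K2P distance and insertion time per complete element.

    LTR pairs are aligned with the module aligner unless ``pre_aligned``
    (equal-length inputs). Saturated pairs get NaN k and T. Solo elements
    appear with NaN k/T.
    """
    if aligner is None and not pre_aligned:
        aligner = make_pairwise_aligner()
    rows = []
    for e in elements:
        k = T = float("nan")
        if e.kind == "complete":
            if pre_aligned:
                a, b = e.ltr5_seq, e.ltr3_seq
            else:
                aln = aligner.align(e.ltr5_seq.upper(), e.ltr3_seq.upper())[0]
                a, b = str(aln[0]), str(aln[1])
            try:
                k = k2p_distance(a, b)
                T = insertion_time(k, rate)
            except SaturationError:
                pass
            e.k, e.T = (None if math.isnan(k) else k,
                        None if math.isnan(T) else T)
        rows.append({"element_id": e.element_id, "kind": e.kind,
                     "k": k, "T_years": T})
    return pd.DataFrame(rows)


def divergence_landscape(distances_pct: np.ndarray, base_counts: np.ndarray,
                         bin_width: float = 1.0) -> pd.DataFrame:
    """Sequence-content histogram over divergence bins.

    Each element contributes its masked base count to the bin containing
    its divergence (percent); bins are [0,1), [1,2), ... Total bin content
    equals the total input bases.
    """
    d = np.asarray(distances_pct, dtype=float)
    w = np.asarray(base_counts, dtype=np.int64)
    if d.size != w.size:
        raise ValueError("distances / base_counts mismatch")
    if d.size == 0:
        return pd.DataFrame(columns=["bin_start", "bin_end", "bases"])
    idx = np.floor(d / bin_width).astype(int)
    n_bins = int(idx.max()) + 1
    bases = np.bincount(idx, weights=w, minlength=n_bins).astype(np.int64)
    return pd.DataFrame({
        "bin_start": np.arange(n_bins) * bin_width,
        "bin_end": (np.arange(n_bins) + 1) * bin_width,
        "bases": bases,
    })
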