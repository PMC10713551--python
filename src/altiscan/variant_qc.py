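"""Site-level hard filtering and LD pruning.

Hard filters follow the GATK-style expression
``QD < 2.0 || FS > 60.0 || MQ < 40.0 || SOR > 3.0 || MQRankSum < -12.5 ||
ReadPosRankSum < -8.0``: a site FAILS if any enabled condition holds. A
missing INFO metric leaves that condition unapplied (common hard-filter
semantics); ``strict=True`` fails sites missing a metric instead.

LD pruning operates on diploid genotype dosages (0/1/2) with r-squared
computed as the squared Pearson correlation within physical windows
(default 10 kb window, 10 kb step, threshold 0.5), keeping the
earlier-position site of any offending pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SiteRecord

# (metric, comparison, threshold): fail when metric <cmp> threshold
DEFAULT_HARD_FILTERS: tuple[tuple[str, str, float], ...] = (
    ("QD", "<", 2.0),
    ("FS", ">", 60.0),
    ("MQ", "<", 40.0),
    ("SOR", ">", 3.0),
    ("MQRankSum", "<", -12.5),
    ("ReadPosRankSum", "<", -8.0),
)


@dataclass
class HardFilterSummary:
    n_sites: int
    n_pass: int
    n_fail: int
    fail_counts: dict[str, int]


def apply_hard_filters(sites: list[SiteRecord],
                       thresholds=DEFAULT_HARD_FILTERS,
                       strict: bool = False,
                       ) -> tuple[np.ndarray, HardFilterSummary]:
    """Per-site pass flags (True = pass) plus a summary of failure counts."""
    flags = np.ones(len(sites), dtype=bool)
    fail_counts: dict[str, int] = {m: 0 for m, _, _ in thresholds}
    for i, rec in enumerate(sites):
        for metric, cmp, thr in thresholds:
            val = rec.info_metrics.get(metric)
            if val is None:
                if strict:
                    flags[i] = False
                    fail_counts[metric] += 1
                continue
            fail = val < thr if cmp == "<" else val > thr
            if fail:
                flags[i] = False
                fail_counts[metric] += 1
    n_pass = int(flags.sum())
    summary = HardFilterSummary(n_sites=len(sites), n_pass=n_pass,
                                n_fail=len(sites) - n_pass,
                                fail_counts=fail_counts)
    return flags, summary


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of dosage vectors; 0 when either is
    monomorphic (undefined r2 never prunes a site)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(dosages: np.ndarray, positions: np.ndarray,
             window_bp: int = 10_000, step_bp: int = 10_000,
             r2_max: float = 0.5) -> np.ndarray:
    """Indices of retained sites after windowed r-squared pruning.

    ``dosages`` has shape (n_sites, n_samples) with values 0/1/2;
    ``positions`` are bp coordinates, increasing. Within every window
    ``[k*step, k*step + window)`` sites are scanned left to right and a site
    is dropped when its r2 with any retained site of the window exceeds
    ``r2_max`` (the left-most site of an offending pair is kept).
    """
    dosages = np.asarray(dosages)
    positions = np.asarray(positions)
    if dosages.shape[0] != positions.size:
        raise ValueError("dosages / positions mismatch")
    if positions.size == 0:
        return np.zeros(0, dtype=np.int64)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    removed = np.zeros(positions.size, dtype=bool)
    max_pos = int(positions.max())
    start = 0
    while start <= max_pos:
        lo = np.searchsorted(positions, start, side="left")
        hi = np.searchsorted(positions, start + window_bp, side="left")
        kept_in_window: list[int] = []
        for i in range(lo, hi):
            if removed[i]:
                continue
            for j in kept_in_window:
                if _r2(dosages[j], dosages[i]) > r2_max:
                    removed[i] = True
                    break
            if not removed[i]:
                kept_in_window.append(i)
        start += step_bp
    return np.nonzero(~removed)[0].astype(np.int64)
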