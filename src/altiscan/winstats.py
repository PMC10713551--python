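"""Non-overlapping windows and frequency-based statistics.

Implements per-window nucleotide diversity (pi), the focal/reference pi
ratio, Hudson's FST (Bhatia et al. ratio-of-sums aggregation by default),
and Tajima's D. Windows are 0-based half-open; undefined values are NaN,
never silently zero.

Conventions (documented deviations are configurable):

* pi denominator is the full window span (the windowed-pi convention of
  VCF-based window tools), not the number of callable sites;
* FST windows aggregate as a ratio of sums; per-site averaging is available;
* Tajima's D is computed over sites with complete genotypes, so one sample
  size applies per window; negative FST values are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomicWindow, HaplotypeMatrix

__all__ = [
    "GenomicWindow", "make_windows", "window_pi", "window_fst", "pi_ratio",
    "window_tajimas_d", "compute_window_table", "site_pi", "hudson_components",
]


def make_windows(chrom_lengths: dict[str, int],
                 size: int = 20_000) -> list[GenomicWindow]:
    """Tile each chromosome with half-open windows of ``size`` bp.

    A terminal partial window (shorter than ``size``) is retained and
    flagged ``partial=True``.
    """
    if size < 1:
        raise ValueError("window size must be >= 1")
    out: list[GenomicWindow] = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            end = min(start + size, length)
            out.append(GenomicWindow(chrom, start, end,
                                     partial=(end - start < size)))
            start = end
    return out


def _counts(alleles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (derived count, total non-missing) for a 0/1 matrix with
    optional missing values encoded as 255."""
    valid = alleles != 255
    n = valid.sum(axis=0)
    c1 = np.where(valid, alleles, 0).sum(axis=0, dtype=np.int64)
    return c1, n


def site_pi(c1: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-site heterozygosity c0*c1 / C(n,2); sites with n < 2 give 0."""
    c1 = np.asarray(c1, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = (n - c1) * c1 / (n * (n - 1) / 2.0)
    return np.where(n >= 2, pi, 0.0)


def _window_slice(positions: np.ndarray, window: GenomicWindow) -> slice:
    lo = np.searchsorted(positions, window.start, side="left")
    hi = np.searchsorted(positions, window.end, side="left")
    return slice(lo, hi)


def window_pi(haps: HaplotypeMatrix, window: GenomicWindow) -> float:
    """Average per-bp diversity over the window span."""
    if window.span == 0:
        return float("nan")
    sl = _window_slice(haps.positions, window)
    c1, n = _counts(haps.alleles[:, sl])
    return float(site_pi(c1, n).sum() / window.span)


def hudson_components(c1_a, n_a, c1_b, n_b) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson/Bhatia FST numerator and denominator.

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

    Sites where either population has fewer than 2 sampled alleles are NaN.
    """
    c1_a = np.asarray(c1_a, dtype=np.float64)
    c1_b = np.asarray(c1_b, dtype=np.float64)
    n_a = np.asarray(n_a, dtype=np.float64)
    n_b = np.asarray(n_b, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1, p2 = c1_a / n_a, c1_b / n_b
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / (n_a - 1)
               - p2 * (1 - p2) / (n_b - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    bad = (n_a < 2) | (n_b < 2)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def window_fst(haps_ref: HaplotypeMatrix, haps_focal: HaplotypeMatrix,
               window: GenomicWindow, estimator: str = "hudson",
               aggregation: str = "ratio_of_sums") -> float:
    """Hudson FST for one window (NaN if no usable site).

    ``aggregation`` is ``"ratio_of_sums"`` (sum of numerators over sum of
    denominators, the recommended estimator) or ``"mean_of_ratios"``.
    Negative values are not clamped.
    """
    if estimator != "hudson":
        raise ValueError(f"unknown estimator {estimator!r}")
    if not np.array_equal(haps_ref.positions, haps_focal.positions):
        raise ValueError("populations must share the site list")
    sl = _window_slice(haps_ref.positions, window)
    c1_a, n_a = _counts(haps_ref.alleles[:, sl])
    c1_b, n_b = _counts(haps_focal.alleles[:, sl])
    num, den = hudson_components(c1_a, n_a, c1_b, n_b)
    ok = ~np.isnan(num) & (den > 0)
    if not ok.any():
        return float("nan")
    if aggregation == "ratio_of_sums":
        return float(num[ok].sum() / den[ok].sum())
    if aggregation == "mean_of_ratios":
        return float(np.mean(num[ok] / den[ok]))
    raise ValueError(f"unknown aggregation {aggregation!r}")


def pi_ratio(pi_focal: float, pi_ref: float) -> float:
    """focal/reference diversity ratio; NaN when the reference pi is 0."""
    if pi_ref < 0 or pi_focal < 0:
        raise ValueError("pi must be >= 0")
    if pi_ref == 0:
        return float("nan")
    return pi_focal / pi_ref


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalization constants for n sampled haplotypes."""
    if n < 3:
        raise ValueError("Tajima's D needs n >= 3 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def window_tajimas_d(haps: HaplotypeMatrix, window: GenomicWindow) -> float:
    """Tajima's D over the window's complete-data segregating sites."""
    sl = _window_slice(haps.positions, window)
    A = haps.alleles[:, sl]
    complete = (A != 255).all(axis=0)
    A = A[:, complete]
    n = A.shape[0]
    if n < 3:
        return float("nan")
    c1 = A.sum(axis=0, dtype=np.int64)
    seg = (c1 > 0) & (c1 < n)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    k = tajima_constants(n)
    pi_hat = float(site_pi(c1[seg], np.full(S, n)).sum())
    theta_w = S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return float((pi_hat - theta_w) / np.sqrt(var))


def compute_window_table(haps: HaplotypeMatrix, windows: list[GenomicWindow],
                         focal: str = "focal", ref: str = "ref",
                         mean_xpehh: np.ndarray | None = None) -> pd.DataFrame:
    """Per-window statistic table for a two-population haplotype matrix.

    Columns: chrom, start, end, n_snps, pi_focal, pi_ref, pi_ratio, fst,
    tajima_d_focal, tajima_d_ref and (when supplied) mean_xpehh. ``n_snps``
    counts polymorphic complete-data sites in the combined sample.
    """
    h_ref = haps.population(ref)
    h_foc = haps.population(focal)
    rows = []
    for w in windows:
        sl = _window_slice(haps.positions, w)
        A = haps.alleles[:, sl]
        complete = (A != 255).all(axis=0)
        c1 = np.where(A == 255, 0, A).sum(axis=0, dtype=np.int64)
        n_snps = int((complete & (c1 > 0) & (c1 < A.shape[0])).sum())
        p_f = window_pi(h_foc, w)
        p_r = window_pi(h_ref, w)
        rows.append({
            "chrom": w.chrom, "start": w.start, "end": w.end,
            "n_snps": n_snps,
            "pi_focal": p_f, "pi_ref": p_r,
            "pi_ratio": pi_ratio(p_f, p_r) if p_r >= 0 else float("nan"),
            "fst": window_fst(h_ref, h_foc, w),
            "tajima_d_focal": window_tajimas_d(h_foc, w),
            "tajima_d_ref": window_tajimas_d(h_ref, w),
        })
    df = pd.DataFrame(rows)
    if mean_xpehh is not None:
        df["mean_xpehh"] = np.asarray(mean_xpehh, dtype=float)
    return df
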