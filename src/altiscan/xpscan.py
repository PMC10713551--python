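"""EHH curves, integrated haplotype homozygosity and cross-population XP-EHH.

EHH here follows the cross-population (all-haplotype) convention: at
extension x, EHH is the probability that two distinct haplotypes of one
population, drawn without replacement, are identical at every site from the
core through x. The within-population, core-allele-partitioned variant used
by iHS is out of scope. Distances are physical (bp); no genetic map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenomicWindow, HaplotypeMatrix

DEFAULT_CUTOFF = 0.05
DEFAULT_MAX_GAP = 200_000
DEFAULT_MAX_EXTEND = 1_000_000


@dataclass
class EHHCurve:
    """EHH decay away from a core site in one direction.

    ``points`` is a list of (distance bp from core, EHH) pairs starting at
    (0, 1.0), with strictly increasing distances and non-increasing EHH.
    """

    core_position: int
    direction: str                  # "left" | "right"
    points: list[tuple[int, float]]

    def __post_init__(self) -> None:
        if self.direction not in ("left", "right"):
            raise ValueError(f"bad direction {self.direction!r}")
        if not self.points or self.points[0] != (0, 1.0):
            raise ValueError("EHH curve must start at (0, 1)")
        d = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("distances must be strictly increasing")


def _homozygosity(groups: np.ndarray) -> float:
    """P(two distinct haplotypes share a group), drawn without replacement."""
    n = groups.size
    _, counts = np.unique(groups, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh_curve(haps: HaplotypeMatrix, core_site_index: int, direction: str,
              max_extend_bp: int = DEFAULT_MAX_EXTEND,
              max_gap_bp: int = DEFAULT_MAX_GAP,
              trunc_ehh: float | None = None) -> EHHCurve:
    """EHH decay from a core site over all haplotypes of one population.

    The curve starts at (0, 1); haplotype identity at extension x is over
    all sites from the core (inclusive) through x. Extension stops at the
    chromosome end, at ``max_extend_bp``, at a gap larger than
    ``max_gap_bp`` between consecutive sites, or once EHH reaches 0.
    ``trunc_ehh`` additionally stops extension right after the first point
    below it (the integration cutoff: points past the cutoff crossing never
    contribute to iHH).
    """
    A = haps.alleles
    if A.shape[0] < 2:
        raise ValueError("EHH needs at least 2 haplotypes")
    positions = haps.positions
    core_pos = int(positions[core_site_index])
    step = 1 if direction == "right" else -1 if direction == "left" else None
    if step is None:
        raise ValueError(f"bad direction {direction!r}")
    points: list[tuple[int, float]] = [(0, 1.0)]
    groups = A[:, core_site_index].astype(np.int64)
    ehh = _homozygosity(groups) if A[:, core_site_index].any() else 1.0
    prev_pos = core_pos
    j = core_site_index + step
    while 0 <= j < positions.size:
        pos = int(positions[j])
        dist = abs(pos - core_pos)
        if dist > max_extend_bp or abs(pos - prev_pos) > max_gap_bp:
            break
        col = A[:, j]
        if col.any() and not col.all():     # monomorphic sites do not split
            if groups.max() >= 2**61:
                _, groups = np.unique(groups, return_inverse=True)
            groups = groups * 2 + col
            ehh = _homozygosity(groups)
        points.append((dist, ehh))
        if ehh == 0.0 or (trunc_ehh is not None and ehh < trunc_ehh):
            break
        prev_pos = pos
        j += step
    return EHHCurve(core_position=core_pos, direction=direction, points=points)


def _one_side_area(points: list[tuple[int, float]], cutoff: float) -> float:
    """Trapezoid area of one EHH branch down to the (interpolated) cutoff."""
    area = 0.0
    for (d0, e0), (d1, e1) in zip(points, points[1:]):
        if e1 >= cutoff:
            area += (d1 - d0) * (e0 + e1) / 2.0
        else:
            # linear interpolation of the crossing distance
            dx = (d1 - d0) * (e0 - cutoff) / (e0 - e1)
            area += dx * (e0 + cutoff) / 2.0
            break
    return area


def ihh(curve_left: EHHCurve, curve_right: EHHCurve,
        cutoff: float = DEFAULT_CUTOFF) -> float:
    """Integrated EHH (bp): trapezoid area of both branches, truncated at
    the interpolated crossing of ``cutoff``."""
    for c in (curve_left, curve_right):
        if not c.points or c.points[0] != (0, 1.0):
            raise ValueError("EHH curve must start at (0, 1)")
    if cutoff >= 1.0:
        return 0.0
    return (_one_side_area(curve_left.points, cutoff)
            + _one_side_area(curve_right.points, cutoff))


def xpehh_unstandardized(ihh_focal: float, ihh_ref: float) -> float:
    """ln(iHH_focal / iHH_ref); positive = longer haplotype homozygosity in
    the focal population. NaN when either area is 0."""
    if ihh_focal < 0 or ihh_ref < 0:
        raise ValueError("iHH must be >= 0")
    if ihh_focal == 0 or ihh_ref == 0:
        return float("nan")
    return float(np.log(ihh_focal / ihh_ref))


def standardize_scores(values: np.ndarray) -> np.ndarray:
    """Z-scores over defined (non-NaN) values; NaNs stay NaN.

    Uses the sample standard deviation (ddof=1). A constant or
    nearly-empty defined set is an error.
    """
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 2:
        raise ValueError("need >= 2 defined values")
    sd = np.std(v[ok], ddof=1)
    if sd == 0:
        raise ValueError("zero spread: cannot standardize")
    out = np.full_like(v, np.nan)
    out[ok] = (v[ok] - v[ok].mean()) / sd
    return out


DEFAULT_MIN_MAF = 0.05


def _shared_extent_ihh(A_foc, A_ref, positions, core, cutoff, max_extend_bp,
                       max_gap_bp) -> tuple[float, float]:
    """(iHH_focal, iHH_ref): both integrated over the shared extent where
    the combined-population EHH stays above ``cutoff`` (the convention of
    the cross-population scan tool this module re-implements)."""
    n_f = A_foc.shape[0]
    A = np.concatenate([A_foc, A_ref], axis=0)
    core_pos = int(positions[core])
    area_f = area_r = 0.0
    for step in (-1, 1):
        g = A[:, core].astype(np.int64)     # one pooled partition
        e_f = _homozygosity(g[:n_f])
        e_r = _homozygosity(g[n_f:])
        e_all = _homozygosity(g)
        prev_d = 0
        prev_f, prev_r = e_f, e_r
        prev_pos = core_pos
        j = core + step
        while 0 <= j < positions.size:
            pos = int(positions[j])
            dist = abs(pos - core_pos)
            if dist > max_extend_bp or abs(pos - prev_pos) > max_gap_bp:
                break
            col = A[:, j]
            if col.any() and not col.all():
                if g.max() >= 2**61:
                    _, g = np.unique(g, return_inverse=True)
                g = g * 2 + col
                e_f = _homozygosity(g[:n_f])
                e_r = _homozygosity(g[n_f:])
                e_all = _homozygosity(g)
            area_f += (dist - prev_d) * (prev_f + e_f) / 2.0
            area_r += (dist - prev_d) * (prev_r + e_r) / 2.0
            prev_d, prev_f, prev_r = dist, e_f, e_r
            if e_all < cutoff:
                break
            prev_pos = pos
            j += step
    return area_f, area_r


def xpehh_scan(haps: HaplotypeMatrix, focal: str = "focal", ref: str = "ref",
               cutoff: float = DEFAULT_CUTOFF,
               max_extend_bp: int = DEFAULT_MAX_EXTEND,
               max_gap_bp: int = DEFAULT_MAX_GAP,
               min_maf: float = DEFAULT_MIN_MAF,
               extent: str = "combined",
               standardize: bool = True) -> np.ndarray:
    """Per-site XP-EHH (focal vs reference) over every site of the matrix.

    Returns an array aligned with ``haps.positions``; sites below
    ``min_maf`` (combined-sample minor allele frequency, the usual core-SNP
    filter of haplotype scans) and sites where either population's iHH is 0
    are NaN. Scores are standardized genome-wide in a single bin unless
    ``standardize=False``.

    ``extent="combined"`` integrates both populations over the shared
    extent where the pooled-sample EHH stays above ``cutoff`` (the
    convention of the scan tool re-implemented here);
    ``extent="separate"`` truncates each population's curve at its own
    cutoff crossing via :func:`ehh_curve`/:func:`ihh`.
    """
    if extent not in ("combined", "separate"):
        raise ValueError(f"bad extent mode {extent!r}")
    h_foc = haps.population(focal)
    h_ref = haps.population(ref)
    raw = np.full(haps.n_sites, np.nan)
    daf = haps.alleles.mean(axis=0)
    maf = np.minimum(daf, 1 - daf)
    for i in range(haps.n_sites):
        if maf[i] < min_maf:
            continue
        if extent == "combined":
            ihh_f, ihh_r = _shared_extent_ihh(
                h_foc.alleles, h_ref.alleles, haps.positions, i, cutoff,
                max_extend_bp, max_gap_bp)
        else:
            ihh_f = ihh(ehh_curve(h_foc, i, "left", max_extend_bp, max_gap_bp,
                                  trunc_ehh=cutoff),
                        ehh_curve(h_foc, i, "right", max_extend_bp,
                                  max_gap_bp, trunc_ehh=cutoff),
                        cutoff)
            ihh_r = ihh(ehh_curve(h_ref, i, "left", max_extend_bp, max_gap_bp,
                                  trunc_ehh=cutoff),
                        ehh_curve(h_ref, i, "right", max_extend_bp,
                                  max_gap_bp, trunc_ehh=cutoff),
                        cutoff)
        raw[i] = xpehh_unstandardized(ihh_f, ihh_r) \
            if ihh_f > 0 and ihh_r > 0 else np.nan
    if not standardize:
        return raw
    return standardize_scores(raw)


def window_mean_xpehh(scores: np.ndarray, positions: np.ndarray,
                      windows: list[GenomicWindow]) -> np.ndarray:
    """Mean per-site score per window; NaN for windows with no scored site."""
    scores = np.asarray(scores, dtype=float)
    positions = np.asarray(positions)
    out = np.full(len(windows), np.nan)
    for k, w in enumerate(windows):
        lo = np.searchsorted(positions, w.start, side="left")
        hi = np.searchsorted(positions, w.end, side="left")
        vals = scores[lo:hi]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            out[k] = vals.mean()
    return out
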