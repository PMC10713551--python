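"""EHH / iHH / XP-EHH against pair-enumeration and closed-form oracles."""

import itertools

import numpy as np
import pytest

from altiscan.core import GenomicWindow, HaplotypeMatrix
from altiscan.xpscan import (EHHCurve, ehh_curve, ihh, standardize_scores,
                             window_mean_xpehh, xpehh_scan,
                             xpehh_unstandardized)
from tests.conftest import random_hap_matrix


def _matrix(alleles, positions):
    alleles = np.asarray(alleles, dtype=np.uint8)
    n = alleles.shape[0]
    return HaplotypeMatrix("chr1", np.asarray(positions), alleles,
                           np.array(["all"] * n),
                           [f"s{i}" for i in range(n // 2)])


def ehh_enumeration_oracle(alleles, core, j_end):
    """P(two distinct haplotypes identical over columns core..j_end),
    by explicit enumeration of all pairs."""
    n = alleles.shape[0]
    lo, hi = min(core, j_end), max(core, j_end)
    same = sum(np.array_equal(alleles[i, lo:hi + 1], alleles[j, lo:hi + 1])
               for i, j in itertools.combinations(range(n), 2))
    return same / (n * (n - 1) / 2)


# ---------------------------------------------------------------------------
# EHH curves
# ---------------------------------------------------------------------------

def test_ehh_starts_at_one_even_for_polymorphic_core():
    haps = _matrix([[0, 0], [0, 1], [1, 0], [1, 1]], [100, 200])
    curve = ehh_curve(haps, 0, "right")
    assert curve.points[0] == (0, 1.0)


def test_ehh_two_two_split_at_first_flank():
    """4 haplotypes splitting 2/2 at the first flanking site -> 1/3."""
    haps = _matrix([[0, 0], [0, 0], [0, 1], [0, 1]], [100, 150])
    curve = ehh_curve(haps, 0, "right")
    assert curve.points == [(0, 1.0), (50, pytest.approx(1 / 3))]


def test_ehh_all_distinct_reaches_zero():
    haps = _matrix([[0, 0, 0], [0, 0, 1], [0, 1, 0], [0, 1, 1]],
                   [100, 150, 220])
    curve = ehh_curve(haps, 0, "right")
    assert curve.points[-1][1] == 0.0


def test_ehh_matches_enumeration_on_random_fixtures(rng):
    for _ in range(40):
        n_hap = int(rng.integers(4, 9)) // 2 * 2
        haps = random_hap_matrix(rng, n_hap=n_hap, n_sites=10, span=5000)
        core = int(rng.integers(0, 10))
        for direction, step in (("right", 1), ("left", -1)):
            curve = ehh_curve(haps, core, direction)
            for k, (dist, ehh) in enumerate(curve.points[1:], start=1):
                j = core + step * k
                assert ehh == pytest.approx(
                    ehh_enumeration_oracle(haps.alleles, core, j), abs=1e-12)


def test_ehh_monotone_non_increasing(rng):
    for _ in range(20):
        haps = random_hap_matrix(rng, n_hap=8, n_sites=15)
        curve = ehh_curve(haps, 0, "right")
        vals = [e for _, e in curve.points]
        assert all(b <= a + 1e-15 for a, b in zip(vals, vals[1:]))


def test_ehh_respects_gap_and_extension_limits():
    haps = _matrix(np.array([[0, 1, 0], [0, 0, 1], [1, 1, 1], [1, 0, 0]]),
                   [1000, 1500, 20_000])
    curve = ehh_curve(haps, 0, "right", max_gap_bp=5_000)
    assert [d for d, _ in curve.points] == [0, 500]
    curve2 = ehh_curve(haps, 0, "right", max_extend_bp=300)
    assert curve2.points == [(0, 1.0)]


def test_ehh_requires_two_haplotypes():
    haps = HaplotypeMatrix.__new__(HaplotypeMatrix)
    haps.positions = np.array([5])
    haps.alleles = np.array([[0]], dtype=np.uint8)
    with pytest.raises(ValueError):
        ehh_curve(haps, 0, "right")


# ---------------------------------------------------------------------------
# iHH
# ---------------------------------------------------------------------------

def _curve(direction, points):
    return EHHCurve(core_position=0, direction=direction, points=points)


def test_ihh_rectangle():
    left = _curve("left", [(0, 1.0)])
    right = _curve("right", [(0, 1.0), (1000, 1.0)])
    assert ihh(left, right) == pytest.approx(1000.0)


def test_ihh_cutoff_interpolation():
    """Points (0,1),(1000,0.04) with cutoff 0.05: crossing at 989.583 bp,
    area ~ 519.53."""
    left = _curve("left", [(0, 1.0)])
    right = _curve("right", [(0, 1.0), (1000, 0.04)])
    area = ihh(left, right, cutoff=0.05)
    assert area == pytest.approx(989.583 * (1 + 0.05) / 2, abs=0.01)
    assert area == pytest.approx(519.53, abs=0.01)


def test_ihh_zero_cutoff_full_area():
    left = _curve("left", [(0, 1.0), (500, 0.5)])
    right = _curve("right", [(0, 1.0), (1000, 0.0)])
    assert ihh(left, right, cutoff=0.0) == pytest.approx(
        500 * 0.75 + 1000 * 0.5)


def test_ihh_rejects_bad_curve_start():
    bad = EHHCurve.__new__(EHHCurve)
    bad.core_position = 0
    bad.direction = "left"
    bad.points = [(0, 0.9)]
    good = _curve("right", [(0, 1.0)])
    with pytest.raises(ValueError):
        ihh(bad, good)


# ---------------------------------------------------------------------------
# XP-EHH
# ---------------------------------------------------------------------------

def test_xpehh_unstandardized_values():
    assert xpehh_unstandardized(2.0, 2.0) == 0.0
    assert xpehh_unstandardized(2.0, 1.0) == pytest.approx(np.log(2))
    assert np.isnan(xpehh_unstandardized(0.0, 1.0))


def test_xpehh_antisymmetric_under_population_swap(rng):
    for _ in range(100):
        a, b = rng.uniform(0.1, 100, size=2)
        assert xpehh_unstandardized(a, b) == pytest.approx(
            -xpehh_unstandardized(b, a), abs=1e-12)


def test_xpehh_scan_antisymmetry_on_fixture(rng):
    pops = np.array(["focal"] * 4 + ["ref"] * 4)
    haps = random_hap_matrix(rng, n_hap=8, n_sites=20, pops=pops)
    fwd = xpehh_scan(haps, standardize=False, min_maf=0.0)
    rev = xpehh_scan(haps, focal="ref", ref="focal", standardize=False,
                     min_maf=0.0)
    np.testing.assert_allclose(fwd, -rev, atol=1e-12)


# ---------------------------------------------------------------------------
# standardization and window means
# ---------------------------------------------------------------------------

def test_standardize_simple_and_nan_passthrough():
    out = standardize_scores(np.array([1.0, 2.0, 3.0, np.nan]))
    np.testing.assert_allclose(out[:3], [-1, 0, 1])
    assert np.isnan(out[3])


def test_standardize_constant_errors():
    with pytest.raises(ValueError):
        standardize_scores(np.array([2.0, 2.0, 2.0]))


def test_standardize_moments(rng):
    out = standardize_scores(rng.normal(3, 5, size=200))
    assert out.mean() == pytest.approx(0, abs=1e-12)
    assert out.std(ddof=1) == pytest.approx(1, abs=1e-12)


def test_window_mean_xpehh_rules():
    windows = [GenomicWindow("chr1", 0, 100), GenomicWindow("chr1", 100, 200),
               GenomicWindow("chr1", 200, 300)]
    scores = np.array([1.0, -1.0, np.nan, 0.5])
    positions = np.array([10, 50, 150, 250])
    out = window_mean_xpehh(scores, positions, windows)
    assert out[0] == 0.0
    assert np.isnan(out[1])
    assert out[2] == 0.5
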