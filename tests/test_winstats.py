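"""Window statistics against brute-force oracles and worked examples."""

import itertools

import numpy as np
import pytest

from altiscan.core import GenomicWindow, HaplotypeMatrix
from altiscan.winstats import (make_windows, pi_ratio, tajima_constants,
                               window_fst, window_pi, window_tajimas_d)
from tests.conftest import random_hap_matrix


# ---------------------------------------------------------------------------
# brute-force oracles (pairwise counting / direct formula evaluation)
# ---------------------------------------------------------------------------

def pi_pairwise_oracle(alleles, span):
    """Mean pairwise difference count over all haplotype pairs / span."""
    n = alleles.shape[0]
    total = sum(np.sum(alleles[i] != alleles[j])
                for i, j in itertools.combinations(range(n), 2))
    return total / (n * (n - 1) / 2) / span


def fst_hudson_oracle(a, b):
    """Direct per-site evaluation of the Hudson/Bhatia estimator."""
    n1, n2 = a.shape[0], b.shape[0]
    nums, dens = [], []
    for j in range(a.shape[1]):
        p1, p2 = a[:, j].mean(), b[:, j].mean()
        nums.append((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1)
                    - p2 * (1 - p2) / (n2 - 1))
        dens.append(p1 * (1 - p2) + p2 * (1 - p1))
    nums, dens = np.array(nums), np.array(dens)
    ok = dens > 0
    return nums[ok].sum() / dens[ok].sum()


def tajima_d_oracle(alleles):
    """From-scratch Tajima's D via pairwise-difference counting."""
    n, _ = alleles.shape
    c1 = alleles.sum(axis=0)
    seg = (c1 > 0) & (c1 < n)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    pi_hat = sum(np.sum(alleles[i, seg] != alleles[j, seg])
                 for i, j in itertools.combinations(range(n), 2)) \
        / (n * (n - 1) / 2)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1_ = b1 - 1 / a1
    c2_ = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1_ / a1
    e2 = c2_ / (a1**2 + a2)
    return (pi_hat - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def _matrix(alleles, positions=None, span=10_000):
    alleles = np.asarray(alleles, dtype=np.uint8)
    n_hap, n_sites = alleles.shape
    if positions is None:
        positions = np.linspace(10, span - 10, n_sites).astype(int)
    pops = np.array(["all"] * n_hap)
    return HaplotypeMatrix("chr1", positions, alleles, pops,
                           [f"s{i}" for i in range(n_hap // 2)])


WINDOW = GenomicWindow("chr1", 0, 10_000)


# ---------------------------------------------------------------------------
# make_windows
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("length,size,expected", [
    (100_000, 20_000, [(0, 20000), (20000, 40000), (40000, 60000),
                       (60000, 80000), (80000, 100000)]),
    (50_000, 20_000, [(0, 20000), (20000, 40000), (40000, 50000)]),
    (0, 20_000, []),
])
def test_make_windows_tiling(length, size, expected):
    ws = make_windows({"chr1": length}, size)
    assert [(w.start, w.end) for w in ws] == expected
    for w in ws:
        assert w.partial == (w.span < size)


# ---------------------------------------------------------------------------
# pi
# ---------------------------------------------------------------------------

def test_window_pi_worked_example():
    """One site with allele counts (2, 2) over 4 haplotypes in a 10-kb
    window: site pi = 4/6, window pi = 6.6667e-05."""
    haps = _matrix([[0], [0], [1], [1]], positions=[500])
    assert window_pi(haps, WINDOW) == pytest.approx(4 / 6 / 10_000, rel=1e-9)


def test_window_pi_monomorphic_is_zero():
    haps = _matrix(np.zeros((4, 3)))
    assert window_pi(haps, WINDOW) == 0.0


def test_pi_invariant_under_permutation_and_relabeling(rng):
    haps = random_hap_matrix(rng, n_hap=10, n_sites=15)
    w = GenomicWindow("chr1", 0, 10_000)
    base = window_pi(haps, w)
    perm = rng.permutation(10)
    permuted = HaplotypeMatrix("chr1", haps.positions, haps.alleles[perm],
                               haps.pop_of_haplotype, haps.sample_ids)
    flipped = HaplotypeMatrix("chr1", haps.positions, 1 - haps.alleles,
                              haps.pop_of_haplotype, haps.sample_ids)
    assert window_pi(permuted, w) == pytest.approx(base, abs=1e-15)
    assert window_pi(flipped, w) == pytest.approx(base, abs=1e-15)


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

def test_fst_fixed_difference_is_one():
    a = _matrix(np.zeros((4, 1)))
    b = _matrix(np.ones((4, 1)))
    assert window_fst(a, b, WINDOW) == pytest.approx(1.0)


def test_fst_worked_example():
    """p1=0.5 (n1=20), p2=0.1 (n2=20) at one site -> 0.284211."""
    a = _matrix(np.repeat([[0], [1]], 10, axis=0))
    b = _matrix(np.array([[1]] * 2 + [[0]] * 18))
    assert window_fst(a, b, WINDOW) == pytest.approx(0.284211, abs=1e-6)


def test_fst_antisymmetry_and_oracle(rng):
    for _ in range(50):
        a = random_hap_matrix(rng, n_hap=6, n_sites=8)
        b_alleles = rng.integers(0, 2, size=(8, 8)).astype(np.uint8)
        b = HaplotypeMatrix("chr1", a.positions, b_alleles,
                            np.array(["all"] * 8), [f"t{i}" for i in range(4)])
        f_ab = window_fst(a, b, WINDOW)
        f_ba = window_fst(b, a, WINDOW)
        assert f_ab == pytest.approx(f_ba, abs=1e-12)
        assert f_ab == pytest.approx(
            fst_hudson_oracle(a.alleles, b.alleles), abs=1e-10)


def test_fst_concatenation_between_parts(rng):
    """Ratio-of-sums on two disjoint windows lies between the parts."""
    a = random_hap_matrix(rng, n_hap=8, n_sites=20, span=20_000)
    b_all = rng.integers(0, 2, size=(8, 20)).astype(np.uint8)
    b = HaplotypeMatrix("chr1", a.positions, b_all, np.array(["all"] * 8),
                        [f"t{i}" for i in range(4)])
    w1 = GenomicWindow("chr1", 0, 10_000)
    w2 = GenomicWindow("chr1", 10_000, 20_000)
    w_all = GenomicWindow("chr1", 0, 20_000)
    f1, f2 = window_fst(a, b, w1), window_fst(a, b, w2)
    f_all = window_fst(a, b, w_all)
    assert min(f1, f2) - 1e-12 <= f_all <= max(f1, f2) + 1e-12


# ---------------------------------------------------------------------------
# pi ratio
# ---------------------------------------------------------------------------

def test_pi_ratio_rules():
    assert pi_ratio(1e-3, 1e-3) == 1.0
    assert pi_ratio(0.0, 1e-3) == 0.0
    assert np.isnan(pi_ratio(1e-3, 0.0))


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def test_tajima_worked_example():
    """n=4 haplotypes, two sites with minor-allele counts 1 and 2:
    D ~ 0.5916 with a1 = 11/6, a2 = 49/36."""
    alleles = np.array([[1, 1], [0, 1], [0, 0], [0, 0]], dtype=np.uint8)
    haps = _matrix(alleles)
    k = tajima_constants(4)
    assert k["a1"] == pytest.approx(11 / 6)
    assert k["a2"] == pytest.approx(49 / 36)
    assert window_tajimas_d(haps, WINDOW) == pytest.approx(0.5916, abs=2e-4)


def test_tajima_no_segregating_sites_undefined():
    haps = _matrix(np.zeros((4, 2)))
    assert np.isnan(window_tajimas_d(haps, WINDOW))


def test_pi_and_tajima_match_bruteforce_on_random_matrices(rng):
    """200 random small matrices agree with pairwise-counting oracles."""
    for _ in range(200):
        n_hap = int(rng.integers(4, 12)) // 2 * 2
        n_sites = int(rng.integers(1, 15))
        haps = random_hap_matrix(rng, n_hap=n_hap, n_sites=n_sites)
        w = GenomicWindow("chr1", 0, 10_000)
        assert window_pi(haps, w) == pytest.approx(
            pi_pairwise_oracle(haps.alleles, 10_000), abs=1e-10)
        d = window_tajimas_d(haps, w)
        d_oracle = tajima_d_oracle(haps.alleles)
        if np.isnan(d_oracle):
            assert np.isnan(d)
        else:
            assert d == pytest.approx(d_oracle, abs=1e-10)
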