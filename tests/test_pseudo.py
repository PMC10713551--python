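"""Pseudogene classification truth table, NG86 vs an independent oracle,
expression tiers and chimera detection."""

import itertools
import math

import numpy as np
import pytest

from altiscan import simdata
from altiscan.genetic_code import CODON_TABLE
from altiscan.pseudo import (classify_candidate, classify_expression,
                             detect_chimera, ng86_kaks)


# ---------------------------------------------------------------------------
# classification truth table
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("coverage,introns,promoter,domain,expected", [
    (0.60, 2, True, True, "discarded"),      # coverage < 0.70
    (0.96, 2, True, False, "discarded"),     # no domain hit
    (0.96, 2, True, True, "complete"),
    (0.95, 1, True, True, "complete"),       # boundary coverage inclusive
    (0.96, 0, True, True, "processed"),      # no intron
    (0.96, 2, False, True, "processed"),     # no promoter
    (0.85, 0, False, True, "processed"),
    (0.85, 2, True, True, "processed"),      # coverage < 0.95
    (0.70, 0, False, True, "processed"),     # boundary 0.70 inclusive
    (0.699, 0, False, True, "discarded"),
    (0.94999, 2, True, True, "processed"),
    (1.0, 1, True, True, "complete"),
])
def test_classification_truth_table(coverage, introns, promoter, domain,
                                    expected):
    assert classify_candidate(coverage, introns, promoter, domain) == expected


def test_classification_exhaustive_consistency():
    """Every (coverage bin, intron, promoter, domain) combination maps to
    exactly the documented category."""
    for cov, intr, prom, dom in itertools.product(
            (0.5, 0.8, 0.97), (0, 2), (False, True), (False, True)):
        cat = classify_candidate(cov, intr, prom, dom)
        if not dom or cov < 0.70:
            assert cat == "discarded"
        elif cov >= 0.95 and intr >= 1 and prom:
            assert cat == "complete"
        else:
            assert cat == "processed"


# ---------------------------------------------------------------------------
# NG86 oracle (independent enumeration-style implementation)
# ---------------------------------------------------------------------------

BASES = "ACGT"


def _sites_oracle(codon):
    syn = non = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if CODON_TABLE[alt] == "*":
                continue
            if CODON_TABLE[alt] == CODON_TABLE[codon]:
                syn += 1 / 3
            else:
                non += 1 / 3
    return syn, non


def _paths_oracle(c1, c2):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if CODON_TABLE[nxt] == "*" and step < len(order) - 1:
                ok = False
            sd += CODON_TABLE[nxt] == CODON_TABLE[cur]
            nd += CODON_TABLE[nxt] != CODON_TABLE[cur]
            cur = nxt
        results.append((sd, nd, ok))
    usable = [(s, n) for s, n, ok in results if ok] or \
             [(s, n) for s, n, _ in results]
    return (sum(s for s, _ in usable) / len(usable),
            sum(n for _, n in usable) / len(usable))


def ng86_oracle(a, b):
    S = N = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        sa, na = _sites_oracle(a[i:i + 3])
        sb, nb = _sites_oracle(b[i:i + 3])
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = _paths_oracle(a[i:i + 3], b[i:i + 3])
        Sd, Nd = Sd + sd, Nd + nd
    def jc(p):
        if p == 0:
            return 0.0
        if p >= 0.75:
            return math.inf
        return -0.75 * math.log(1 - 4 * p / 3)
    ka, ks = jc(Nd / N), jc(Sd / S)
    return ka, ks, (ka / ks if ks > 0 else float("nan"))


def test_identical_sequences():
    cds = "ATGGCTAAA"
    ka, ks, ratio = ng86_kaks(cds, cds)
    assert (ka, ks) == (0.0, 0.0)
    assert math.isnan(ratio)


def test_pure_synonymous_single_codon():
    """TTA vs TTG (both Leu): Ka = 0, Ks > 0, ratio 0."""
    ka, ks, ratio = ng86_kaks("TTA", "TTG")
    assert ka == 0.0
    assert ks > 0
    assert ratio == 0.0


def test_thirty_codon_fixture_matches_oracle(rng):
    a = simdata.random_cds(30, rng)
    b = simdata.mutate_cds(a, 0.5, 0.08, rng)
    ka, ks, ratio = ng86_kaks(a, b)
    ko, so, ro = ng86_oracle(a, b)
    assert ka == pytest.approx(ko, abs=1e-6)
    assert ks == pytest.approx(so, abs=1e-6)
    if not math.isnan(ro):
        assert ratio == pytest.approx(ro, abs=1e-6)


def test_random_pairs_match_oracle(rng):
    for _ in range(20):
        a = simdata.random_cds(12, rng)
        b = simdata.mutate_cds(a, 1.0, 0.15, rng)
        ka, ks, _ = ng86_kaks(a, b)
        ko, so, _ = ng86_oracle(a, b)
        assert ka == pytest.approx(ko, abs=1e-9)
        assert ks == pytest.approx(so, abs=1e-9)


def test_invalid_cds_rejected():
    with pytest.raises(ValueError):
        ng86_kaks("ATGA", "ATGA")               # not divisible by 3
    with pytest.raises(ValueError):
        ng86_kaks("ATGTAAAAA", "ATGTAAAAA")     # internal stop
    with pytest.raises(ValueError):
        ng86_kaks("ATG", "ATGATG")              # unequal length


def test_omega_recovery_small():
    """Mean NG86 ratio near the simulated omega (deeper run in acceptance)."""
    fam = simdata.simulate_pseudogene_family(
        12, omega=0.3, n_codons=300, truncation_dist=lambda r: 0.0, seed=9)
    ratios = [ng86_kaks(c["base_aligned"], c["cds"])[2] for c in fam.copies]
    ratios = [r for r in ratios if not math.isnan(r)]
    assert abs(np.mean(ratios) - 0.3) < 0.15


# ---------------------------------------------------------------------------
# expression tiers
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("tpm,tier", [
    (1.0, "normal"),                  # log2(2) = 1, boundary inclusive
    (5.0, "normal"),
    (0.2, "low"),                     # log2(1.2) ~ 0.263
    (0.072, "low"),                   # log2(1.072) ~ 0.1003, just above 0.1
    (0.05, "none"),                   # log2(1.05) ~ 0.070
    (0.0, "none"),
])
def test_expression_tiers(tpm, tier):
    assert classify_expression(tpm) == tier


def test_expression_negative_rejected():
    with pytest.raises(ValueError):
        classify_expression(-0.1)


# ---------------------------------------------------------------------------
# chimera detection
# ---------------------------------------------------------------------------

def test_chimera_detected_with_length_comparison():
    segments = [("LTR", 1000, 1300), ("pseudogene", 1350, 1700),
                ("INTERNAL", 1750, 3750), ("LTR", 3800, 4250)]
    rec = detect_chimera(segments)
    assert rec is not None
    assert (rec.ltr5_len, rec.ltr3_len) == (300, 450)
    assert rec.five_prime_shorter


def test_chimera_missing_internal_is_none():
    segments = [("LTR", 1000, 1300), ("pseudogene", 1350, 1700),
                ("LTR", 3800, 4250)]
    assert detect_chimera(segments) is None


def test_chimera_split_across_chromosomes_is_none():
    segments = [("LTR", "chr1", 1000, 1300),
                ("pseudogene", "chr1", 1350, 1700),
                ("INTERNAL", "chr2", 1750, 3750),
                ("LTR", "chr2", 3800, 4250)]
    assert detect_chimera(segments) is None


def test_chimera_allows_interleaved_other_segments():
    segments = [("LTR", 1000, 1300), ("other", 1310, 1330),
                ("pseudogene", 1350, 1700), ("INTERNAL", 1750, 3750),
                ("other", 3760, 3790), ("LTR", 3800, 4250)]
    assert detect_chimera(segments) is not None


def test_chimera_gap_tolerance():
    segments = [("LTR", 1000, 1300), ("pseudogene", 5000, 5400),
                ("INTERNAL", 5450, 7450), ("LTR", 7500, 7900)]
    assert detect_chimera(segments, gap_tolerance=1000) is None
    assert detect_chimera(segments, gap_tolerance=5000) is not None


def test_chimera_invariant_under_translation_and_mirroring():
    segments = [("LTR", 1000, 1300), ("pseudogene", 1350, 1700),
                ("INTERNAL", 1750, 3750), ("LTR", 3800, 4250)]
    shifted = [(l, s + 10_000, e + 10_000) for l, s, e in segments]
    rec0 = detect_chimera(segments)
    rec1 = detect_chimera(shifted)
    assert (rec0.ltr5_len, rec0.ltr3_len) == (rec1.ltr5_len, rec1.ltr3_len)
    span = 10_000
    mirrored = [(l, span - e, span - s) for l, s, e in segments]
    rec2 = detect_chimera(mirrored, strand="-")
    assert (rec2.ltr5_len, rec2.ltr3_len) == (rec0.ltr5_len, rec0.ltr3_len)
    assert rec2.five_prime_shorter == rec0.five_prime_shorter


def test_simulated_family_truth():
    fam = simdata.simulate_pseudogene_family(30, omega=0.3, seed=17)
    assert fam.base_record["intron_count"] == 2
    for copy, truth in zip(fam.copies, fam.truth):
        assert copy["intron_count"] == 0
        cat = classify_candidate(copy["coverage"], copy["intron_count"],
                                 copy["has_promoter"], copy["has_domain_hit"])
        assert cat in ("processed", "discarded")
        if truth["chimera"]:
            assert detect_chimera(copy["segments"]) is not None
        tpm = float(fam.expression.loc[copy["candidate_id"], "tpm"])
        assert classify_expression(tpm) == truth["tier"]


def test_no_copies_only_base_gene():
    fam = simdata.simulate_pseudogene_family(0, seed=2)
    assert fam.copies == []
    assert fam.base_record["intron_count"] == 2
    assert fam.base_record["has_promoter"]
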