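"""Synthetic-data generators with known ground truth.

The generators emulate a two-population resequencing design: a high-altitude
reference population and a low-altitude focal population that split from a
common ancestor, with an optional bottleneck and an optional hard sweep in
the focal population. Additional generators produce TE annotations, SV
callsets with known TE-overlap classes, LTR retrotransposon sets with known
inter-LTR divergence, and a processed-pseudogene family with known omega and
expression tiers. Every generator is a pure function of its parameters and
seed.

The demographic engine is a discrete-generation Wright-Fisher forward
simulator with recombination and infinite-sites mutation on discrete bp,
seeded at the population split from a neutral coalescent (msprime) sample of
the whole ancestral population, which replaces an explicit >= 4N burn-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np

from .core import TE_CLASSES, GeneModel, HaplotypeMatrix, SVRecord, TEFeature
from .genetic_code import CODON_TABLE

NUCS = np.array(list("ACGT"))
# transition partner of A,C,G,T (A<->G, C<->T)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

STOP_CODONS = ("TAA", "TAG", "TGA")

MAX_SWEEP_RESTARTS = 1000


# ---------------------------------------------------------------------------
# two-population Wright-Fisher forward simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimParams:
    """Demographic and sampling parameters for :func:`simulate_two_pop`.

    Sizes are diploid counts; times are generations before present; rates
    are per site (or per bp) per generation. ``sel_coeff`` is the selection
    coefficient s of the beneficial allele injected at ``sel_start`` at
    position ``sel_position`` in the focal population, with dominance h
    (fitnesses 1, 1+hs, 1+s).
    """

    ancestral_size: int = 200
    size_ref: int = 200
    size_focal: int = 200
    split_time: int = 200
    bottleneck_size: int = 150
    bottleneck_start: int = 195
    bottleneck_duration: int = 30
    seq_length: int = 200_000
    mu: float = 2e-6
    rec_rate: float = 1e-6
    sel_coeff: float = 0.0
    dominance: float = 0.5
    sel_start: int = 170
    sel_position: int = 100_000
    sample_ref: int = 20
    sample_focal: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ancestral_size", "size_ref", "size_focal", "bottleneck_size"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.mu < 0 or self.rec_rate < 0:
            raise ValueError("mu and rec_rate must be >= 0")
        if not 0 <= self.sel_position < self.seq_length:
            raise ValueError("sel_position outside sequence")
        if self.sel_coeff < 0:
            raise ValueError("sel_coeff must be >= 0")
        if not 0 <= self.dominance <= 1:
            raise ValueError("dominance must be in [0, 1]")
        if self.sample_ref > self.size_ref or self.sample_focal > self.size_focal:
            raise ValueError("sample size exceeds population size")
        if self.split_time < 1:
            raise ValueError("split_time must be >= 1")
        if self.sel_coeff > 0 and self.sel_start > self.split_time:
            raise ValueError("sel_start must be <= split_time")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated sample."""

    params: SimParams
    positions: np.ndarray
    count_ref: np.ndarray      # derived-allele counts in the emitted ref sample
    count_focal: np.ndarray
    n_hap_ref: int
    n_hap_focal: int
    sel_position: int | None = None
    sel_final_freq: float | None = None   # in the full focal population
    n_restarts: int = 0

    @property
    def freq_ref(self) -> np.ndarray:
        return self.count_ref / max(self.n_hap_ref, 1)

    @property
    def freq_focal(self) -> np.ndarray:
        return self.count_focal / max(self.n_hap_focal, 1)


class _PopState:
    """Mutable forward-simulation state: one row block per population."""

    __slots__ = ("X", "positions", "occupied", "n_ref", "n_focal")

    def __init__(self, X, positions, occupied, n_ref, n_focal):
        self.X = X                    # (2*n_ref + 2*n_focal, S) uint8
        self.positions = positions    # (S,) int64, arbitrary column order
        self.occupied = occupied      # set of occupied bp
        self.n_ref = n_ref
        self.n_focal = n_focal

    def copy(self) -> "_PopState":
        return _PopState(self.X.copy(), self.positions.copy(),
                         set(self.occupied), self.n_ref, self.n_focal)


def _focal_size_at(p: SimParams, tau: int) -> int:
    """Focal diploid size for the generation living tau generations ago."""
    if p.bottleneck_start >= tau > p.bottleneck_start - p.bottleneck_duration:
        return p.bottleneck_size
    return p.size_focal


def _init_from_coalescent(p: SimParams, rng: np.random.Generator) -> _PopState:
    """Whole ancestral population sampled from a neutral coalescent."""
    ms_seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=p.ancestral_size,
        population_size=p.ancestral_size,
        sequence_length=p.seq_length,
        recombination_rate=p.rec_rate,
        discrete_genome=True,
        random_seed=ms_seed,
    )
    if p.mu > 0:
        mut_seed = int(rng.integers(1, 2**31 - 1))
        ts = msprime.sim_mutations(
            ts, rate=p.mu, model=msprime.BinaryMutationModel(),
            discrete_genome=True, random_seed=mut_seed,
        )
    if ts.num_sites:
        G = ts.genotype_matrix()        # (sites, haplotypes)
        pos = np.array([int(s.position) for s in ts.sites()], dtype=np.int64)
        # collapse recurrent hits to biallelic 0/1 and drop monomorphic sites
        G = (G > 0).astype(np.uint8)
        keep = (G.sum(axis=1) > 0) & (G.sum(axis=1) < G.shape[1])
        # discrete_genome can put two sites on the same bp; keep the first
        _, first = np.unique(pos, return_index=True)
        uniq = np.zeros(pos.size, dtype=bool)
        uniq[first] = True
        keep &= uniq
        G, pos = G[keep], pos[keep]
        anc = G.T.copy()                # (haplotypes, sites)
    else:
        anc = np.zeros((2 * p.ancestral_size, 0), dtype=np.uint8)
        pos = np.zeros(0, dtype=np.int64)

    # found both populations by Wright-Fisher sampling from the ancestral pool
    n_f0 = _focal_size_at(p, p.split_time)
    X = np.empty((2 * p.size_ref + 2 * n_f0, anc.shape[1]), dtype=np.uint8)
    _fill_offspring(X, 0, anc, 0, p.ancestral_size, p.size_ref, None, p, rng,
                    positions=pos)
    _fill_offspring(X, 2 * p.size_ref, anc, 0, p.ancestral_size, n_f0, None, p, rng,
                    positions=pos)
    return _PopState(X, pos, set(int(x) for x in pos), p.size_ref, n_f0)


def _fill_offspring(X_new, row0, X_old, old_row0, n_parents, n_off,
                    weights, p: SimParams, rng, positions=None) -> None:
    """Write 2*n_off offspring gametes of one population into X_new."""
    if positions is None:
        positions = np.zeros(X_old.shape[1], dtype=np.int64)
    n_gam = 2 * n_off
    if weights is None:
        parents = rng.integers(0, n_parents, size=n_gam)
    else:
        parents = rng.choice(n_parents, size=n_gam, p=weights)
    start = rng.integers(0, 2, size=n_gam)
    n_cross = rng.poisson(p.rec_rate * p.seq_length, size=n_gam)
    hap_a = old_row0 + 2 * parents + start
    X_new[row0:row0 + n_gam] = X_old[hap_a]
    for i in np.nonzero(n_cross)[0]:
        bp = np.sort(rng.integers(1, p.seq_length, size=n_cross[i]))
        mask = (np.searchsorted(bp, positions, side="right") % 2).astype(bool)
        hap_b = old_row0 + 2 * parents[i] + 1 - start[i]
        row = X_new[row0 + i]
        row[mask] = X_old[hap_b][mask]


def _diploid_weights(X, row0, n_dip, col, s, h):
    """Fitness-proportional parent-sampling probabilities for one population."""
    alleles = X[row0:row0 + 2 * n_dip, col]
    dosage = alleles[0::2].astype(np.int64) + alleles[1::2]
    w = 1.0 + np.where(dosage == 2, s, np.where(dosage == 1, h * s, 0.0))
    return w / w.sum()


def _add_mutations(state: _PopState, p: SimParams, rng) -> None:
    n_hap = state.X.shape[0]
    n_mut = rng.poisson(n_hap * p.seq_length * p.mu)
    if n_mut == 0:
        return
    new_pos = []
    for _ in range(n_mut):
        for _try in range(100):
            x = int(rng.integers(0, p.seq_length))
            if x not in state.occupied:
                state.occupied.add(x)
                new_pos.append(x)
                break
        # a saturated sequence silently drops the mutation (infinite-sites)
    if not new_pos:
        return
    rows = rng.integers(0, n_hap, size=len(new_pos))
    M = np.zeros((n_hap, len(new_pos)), dtype=np.uint8)
    M[rows, np.arange(len(new_pos))] = 1
    state.X = np.concatenate([state.X, M], axis=1)
    state.positions = np.concatenate(
        [state.positions, np.asarray(new_pos, dtype=np.int64)])


def _prune(state: _PopState, protect_pos: int | None) -> None:
    counts = state.X.sum(axis=0, dtype=np.int64)
    keep = (counts > 0) & (counts < state.X.shape[0])
    if protect_pos is not None:
        keep |= (state.positions == protect_pos) & (counts > 0)
    if keep.all():
        return
    for x in state.positions[~keep]:
        state.occupied.discard(int(x))
    state.X = state.X[:, keep]
    state.positions = state.positions[keep]


def _step(state: _PopState, p: SimParams, tau_next: int, sweep_col: int | None,
          rng) -> _PopState:
    """Advance one generation; offspring generation lives tau_next gens ago."""
    n_f_next = _focal_size_at(p, tau_next)
    X_new = np.empty((2 * p.size_ref + 2 * n_f_next, state.X.shape[1]),
                     dtype=np.uint8)
    _fill_offspring(X_new, 0, state.X, 0, state.n_ref, p.size_ref,
                    None, p, rng, positions=state.positions)
    weights = None
    if sweep_col is not None and p.sel_coeff > 0:
        weights = _diploid_weights(state.X, 2 * state.n_ref, state.n_focal,
                                   sweep_col, p.sel_coeff, p.dominance)
    _fill_offspring(X_new, 2 * p.size_ref, state.X, 2 * state.n_ref,
                    state.n_focal, n_f_next, weights, p, rng,
                    positions=state.positions)
    return _PopState(X_new, state.positions, state.occupied,
                     p.size_ref, n_f_next)


def _sweep_col_index(state: _PopState, p: SimParams) -> int | None:
    idx = np.nonzero(state.positions == p.sel_position)[0]
    return int(idx[0]) if idx.size else None


def _inject_sweep(state: _PopState, p: SimParams, rng) -> None:
    """Place the beneficial allele on one random focal haplotype."""
    col = _sweep_col_index(state, p)
    if col is not None:
        # infinite-sites: displace the neutral mutation occupying the site
        keep = np.ones(state.X.shape[1], dtype=bool)
        keep[col] = False
        state.X = state.X[:, keep]
        state.positions = state.positions[keep]
    n_hap = state.X.shape[0]
    M = np.zeros((n_hap, 1), dtype=np.uint8)
    row = 2 * state.n_ref + int(rng.integers(0, 2 * state.n_focal))
    M[row, 0] = 1
    state.X = np.concatenate([state.X, M], axis=1)
    state.positions = np.concatenate(
        [state.positions, np.asarray([p.sel_position], dtype=np.int64)])
    state.occupied.add(p.sel_position)


def simulate_two_pop(params: SimParams) -> tuple[HaplotypeMatrix, SimTruth]:
    """Forward-simulate the two-population design and sample haplotypes.

    Returns a phased sample matrix (populations labeled ``"ref"`` and
    ``"focal"``) restricted to sites segregating in the combined sample, and
    the ground truth (per-site sample allele counts per population, sweep
    outcome, restart count). Deterministic for a fixed ``params.seed``.

    A beneficial allele injected at ``sel_start`` is conditioned on non-loss
    at present by restarting from the injection state, capped at
    ``MAX_SWEEP_RESTARTS`` restarts.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    state = _init_from_coalescent(p, rng)
    _add_mutations(state, p, rng)
    _prune(state, None)

    sweep_on = p.sel_coeff > 0
    snapshot: _PopState | None = None
    n_restarts = 0
    tau = p.split_time
    while tau > 0:
        if sweep_on and tau == p.sel_start and snapshot is None:
            _inject_sweep(state, p, rng)
            snapshot = state.copy()
        sweep_col = _sweep_col_index(state, p) if sweep_on and tau <= p.sel_start \
            and snapshot is not None else None
        state = _step(state, p, tau - 1, sweep_col, rng)
        _add_mutations(state, p, rng)
        _prune(state, p.sel_position if snapshot is not None else None)
        if snapshot is not None:
            col = _sweep_col_index(state, p)
            lost = col is None or \
                state.X[2 * state.n_ref:, col].sum() == 0
            if lost:
                n_restarts += 1
                if n_restarts > MAX_SWEEP_RESTARTS:
                    raise RuntimeError(
                        "beneficial allele lost in every attempt "
                        f"({MAX_SWEEP_RESTARTS} restarts)")
                state = snapshot.copy()
                tau = p.sel_start
                continue
        tau -= 1

    sel_final_freq = None
    if sweep_on and snapshot is not None:
        col = _sweep_col_index(state, p)
        sel_final_freq = float(state.X[2 * state.n_ref:, col].sum()
                               / (2 * state.n_focal))

    # sample diploids without replacement from each population
    ref_dip = np.sort(rng.choice(state.n_ref, size=p.sample_ref, replace=False))
    foc_dip = np.sort(rng.choice(state.n_focal, size=p.sample_focal,
                                 replace=False))
    rows = np.concatenate([
        np.stack([2 * ref_dip, 2 * ref_dip + 1], axis=1).ravel(),
        2 * state.n_ref
        + np.stack([2 * foc_dip, 2 * foc_dip + 1], axis=1).ravel(),
    ])
    sample = state.X[rows]
    order = np.argsort(state.positions, kind="stable")
    sample = sample[:, order]
    positions = state.positions[order]
    seg = (sample.sum(axis=0) > 0) & (sample.sum(axis=0) < sample.shape[0])
    sample, positions = sample[:, seg], positions[seg]

    n_hr, n_hf = 2 * p.sample_ref, 2 * p.sample_focal
    pop_labels = np.array(["ref"] * n_hr + ["focal"] * n_hf)
    sample_ids = [f"ref_{i:03d}" for i in range(p.sample_ref)] + \
                 [f"focal_{i:03d}" for i in range(p.sample_focal)]
    haps = HaplotypeMatrix(chrom="chr1", positions=positions, alleles=sample,
                           pop_of_haplotype=pop_labels, sample_ids=sample_ids)
    truth = SimTruth(
        params=p,
        positions=positions.copy(),
        count_ref=sample[:n_hr].sum(axis=0, dtype=np.int64),
        count_focal=sample[n_hr:].sum(axis=0, dtype=np.int64),
        n_hap_ref=n_hr,
        n_hap_focal=n_hf,
        sel_position=p.sel_position if sweep_on else None,
        sel_final_freq=sel_final_freq,
        n_restarts=n_restarts,
    )
    return haps, truth


# ---------------------------------------------------------------------------
# TE annotation
# ---------------------------------------------------------------------------

DEFAULT_CLASS_MIX = {
    # LINE-dominated landscape, as in large lepidopteran genomes
    "LINE": 0.55, "LTR": 0.15, "DNA": 0.12, "SINE": 0.08,
    "RC": 0.04, "Unknown": 0.06,
}
_CLASS_LEN = {  # lognormal (mean, sigma) of element length in bp
    "LINE": (7.6, 0.7), "LTR": (7.8, 0.6), "DNA": (6.8, 0.7),
    "SINE": (5.6, 0.4), "RC": (6.9, 0.6), "Unknown": (6.5, 0.8),
}


def simulate_te_annotation(genome_length: int, target_fraction: float = 0.68,
                           class_mix: dict[str, float] | None = None,
                           seed: int = 0) -> list[TEFeature]:
    """Random TE features whose union covers ~``target_fraction`` of the genome."""
    if not 0 <= target_fraction < 1:
        raise ValueError("target_fraction must be in [0, 1)")
    mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix weights must sum to 1")
    for cls in mix:
        if cls not in TE_CLASSES:
            raise ValueError(f"unknown TE class {cls!r}")
    rng = np.random.default_rng(seed)
    classes = list(mix)
    probs = np.array([mix[c] for c in classes])
    covered = np.zeros(genome_length, dtype=bool)
    n_cov = 0
    feats: list[TEFeature] = []
    target = target_fraction * genome_length
    max_len = max(50, genome_length // 100)
    while n_cov < target:
        cls = classes[int(rng.choice(len(classes), p=probs))]
        m, s = _CLASS_LEN[cls]
        length = int(np.clip(rng.lognormal(m, s), 50, max_len))
        length = min(length, genome_length)
        start = int(rng.integers(0, genome_length - length + 1))
        seg = covered[start:start + length]
        n_cov += length - int(seg.sum())
        seg[:] = True
        fam = f"{cls}/fam{int(rng.integers(0, 30)):02d}"
        feats.append(TEFeature("chr1", start, start + length, cls, fam))
    feats.sort(key=lambda f: (f.chrom, f.start, f.end))
    return feats


# ---------------------------------------------------------------------------
# SV callset with known TE-overlap classes
# ---------------------------------------------------------------------------

def _union_runs(te: list[TEFeature], chrom: str) -> list[tuple[int, int]]:
    """Merged TE union on one chromosome (generator-internal arithmetic)."""
    ivals = [(f.start, f.end) for f in te if f.chrom == chrom]
    out: list[list[int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _union_overlap(runs: list[tuple[int, int]], start: int, end: int) -> int:
    return sum(max(0, min(e, end) - max(s, start)) for s, e in runs)


def simulate_sv_callset(te: list[TEFeature], n_sv: int, genome_length: int,
                        size_range: tuple[int, int] = (50, 100_000),
                        overlap_mix: tuple[float, float, float] = (0.5, 0.2, 0.3),
                        seed: int = 0) -> tuple[list[SVRecord], list[dict]]:
    """SV callset whose TE-overlap class is known by construction.

    ``overlap_mix`` gives target shares of (TE-SV, uncertain, No TE-SV).
    Each returned truth record carries the realized overlap fraction and the
    label implied by the 90%/0 rule; the classes include exact-boundary
    fractions (0.90 and 0) when geometry permits.
    """
    if n_sv < 0:
        raise ValueError("n_sv must be >= 0")
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("bad size_range")
    rng = np.random.default_rng(seed)
    runs = _union_runs(te, "chr1")
    gaps = []
    prev = 0
    for s, e in runs + [(genome_length, genome_length)]:
        if s > prev:
            gaps.append((prev, s))
        prev = max(prev, e)
    shares = np.asarray(overlap_mix, dtype=float)
    shares = shares / shares.sum()
    svs: list[SVRecord] = []
    truth: list[dict] = []
    sv_types = ["DEL", "DUP", "INV"]
    for i in range(n_sv):
        want = int(rng.choice(3, p=shares))
        placed = None
        for _try in range(200):
            length = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            length = int(np.clip(length, lo, min(hi, genome_length)))
            if want == 0 and runs:          # TE-SV: >= 90% inside the union
                s0, e0 = runs[int(rng.integers(0, len(runs)))]
                if e0 - s0 < max(1, int(np.ceil(0.9 * length))):
                    continue
                if e0 - s0 >= length:
                    start = int(rng.integers(s0, e0 - length + 1))
                else:
                    start = max(0, e0 - length)
                # an exact 0.90 boundary case every so often
                if length >= 100 and length % 10 == 0 and rng.random() < 0.1:
                    shift = length // 10
                    cand = s0 - shift
                    if cand >= 0 and _union_overlap(runs, cand, cand + length) \
                            == length - shift:
                        start = cand
            elif want == 2 and gaps:        # No TE-SV: zero overlap
                g = [g for g in gaps if g[1] - g[0] >= length]
                if not g:
                    continue
                s0, e0 = g[int(rng.integers(0, len(g)))]
                start = int(rng.integers(s0, e0 - length + 1))
            elif runs:                      # uncertain: straddle a run edge
                s0, e0 = runs[int(rng.integers(0, len(runs)))]
                frac = rng.uniform(0.1, 0.8)
                start = max(0, s0 - int(round((1 - frac) * length)))
            else:
                start = int(rng.integers(0, max(1, genome_length - length)))
            end = min(start + length, genome_length)
            if end - start < lo:
                continue
            ov = _union_overlap(runs, start, end)
            frac = ov / (end - start)
            label = ("TE-SV" if frac >= 0.9
                     else "No TE-SV" if frac == 0 else "uncertain")
            if label == ("TE-SV", "uncertain", "No TE-SV")[want]:
                placed = (start, end, frac, label)
                break
        if placed is None:                  # keep whatever geometry allows
            placed = (start, end, frac, label)
        start, end, frac, label = placed
        sv_type = sv_types[int(rng.integers(0, 3))]
        svs.append(SVRecord("chr1", start, end, sv_type, end - start))
        truth.append({"sv_index": i, "start": start, "end": end,
                      "te_fraction": frac, "label": label})
    return svs, truth


# ---------------------------------------------------------------------------
# nucleotide-evolution helpers (K2P process, codon model)
# ---------------------------------------------------------------------------

def random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(NUCS[rng.integers(0, 4, size=length)])


def evolve_k2p(seq: str, distance: float, kappa: float,
               rng: np.random.Generator) -> str:
    """Evolve ``seq`` for an expected ``distance`` substitutions/site under
    the Kimura two-parameter model (kappa = transition/transversion rate
    ratio, two transversion targets)."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if distance == 0:
        return seq
    alpha = kappa / (kappa + 2.0)
    beta = 1.0 / (kappa + 2.0)
    t = distance
    p_ts = 0.25 + 0.25 * np.exp(-4 * beta * t) - 0.5 * np.exp(-2 * (alpha + beta) * t)
    p_tv = 0.25 - 0.25 * np.exp(-4 * beta * t)   # each of two targets
    out = list(seq)
    u = rng.random(len(out))
    for i, base in enumerate(out):
        if u[i] < p_ts:
            out[i] = _TRANSITION[base]
        elif u[i] < p_ts + 2 * p_tv:
            tvs = [n for n in "ACGT" if n != base and n != _TRANSITION[base]]
            out[i] = tvs[int(u[i] * 1e9) % 2]
    return "".join(out)


def _codon_is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random in-frame, stop-free CDS starting with ATG."""
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = random_seq(3, rng)
        if not _codon_is_stop(c):
            codons.append(c)
    return "".join(codons)


def mutate_cds(cds: str, omega: float, subs_per_site: float,
               rng: np.random.Generator) -> str:
    """Mutate a CDS so the accepted changes have dN/dS ~ ``omega``.

    Proposals are uniform single-base changes; synonymous proposals are
    always accepted, non-synonymous ones with probability ``omega``, and
    changes creating stop codons are rejected.
    """
    seq = list(cds)
    n_target = int(round(subs_per_site * len(cds)))
    accepted = 0
    guard = 0
    while accepted < n_target:
        guard += 1
        if guard > 1000 * max(n_target, 1):
            break
        i = int(rng.integers(0, len(seq)))
        old = seq[i]
        new = "ACGT"[int(rng.integers(0, 4))]
        if new == old:
            continue
        c0 = i - i % 3
        codon_old = "".join(seq[c0:c0 + 3])
        codon_new = codon_old[:i - c0] + new + codon_old[i - c0 + 1:]
        if _codon_is_stop(codon_new):
            continue
        syn = CODON_TABLE[codon_old] == CODON_TABLE[codon_new]
        if syn or rng.random() < omega:
            seq[i] = new
            accepted += 1
    return "".join(seq)


# ---------------------------------------------------------------------------
# LTR retrotransposon set
# ---------------------------------------------------------------------------

def simulate_ltr_set(n_complete: int, n_solo: int, ltr_len: int = 400,
                     internal_len: int = 2000,
                     k_targets: tuple[float, ...] = (0.02,),
                     kappa: float = 2.0, n_families: int = 1,
                     seed: int = 0):
    """LTR element set with known inter-LTR divergence.

    Each complete element is 5'-LTR + internal + 3'-LTR where the two LTR
    copies each evolved k/2 from a common inserted copy (total expected K2P
    distance ``k``). Solo elements are single LTR copies. Returns
    ``(elements, truth)`` where elements are :class:`altiscan.ltrev.
    LTRElementRecord` and truth records ``k_target``, kind and family.
    """
    from .ltrev import LTRElementRecord

    if ltr_len < 80:
        raise ValueError("ltr_len must be >= 80 for the 80-80-80 rule")
    if any(k < 0 for k in k_targets):
        raise ValueError("k_targets must be >= 0")
    if n_complete < 0 or n_solo < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    fam_bases = [random_seq(ltr_len, rng) for _ in range(max(1, n_families))]
    elements: list[LTRElementRecord] = []
    truth: list[dict] = []
    for i in range(n_complete):
        k = float(k_targets[i % len(k_targets)])
        fam = i % len(fam_bases)
        inserted = evolve_k2p(fam_bases[fam], 0.02, kappa, rng)
        elements.append(LTRElementRecord(
            element_id=f"complete_{i:04d}", kind="complete",
            ltr5_seq=evolve_k2p(inserted, k / 2, kappa, rng),
            ltr3_seq=evolve_k2p(inserted, k / 2, kappa, rng),
            internal_len=internal_len,
        ))
        truth.append({"element_id": f"complete_{i:04d}", "kind": "complete",
                      "k_target": k, "family": fam})
    for i in range(n_solo):
        fam = i % len(fam_bases)
        elements.append(LTRElementRecord(
            element_id=f"solo_{i:04d}", kind="solo",
            solo_seq=evolve_k2p(fam_bases[fam], 0.02, kappa, rng),
        ))
        truth.append({"element_id": f"solo_{i:04d}", "kind": "solo",
                      "k_target": None, "family": fam})
    return elements, truth


# ---------------------------------------------------------------------------
# processed-pseudogene family
# ---------------------------------------------------------------------------

@dataclass
class PseudoFamilySim:
    """Output bundle of :func:`simulate_pseudogene_family`."""

    base_cds: str
    base_record: dict
    copies: list[dict]
    expression: "object"      # pandas.DataFrame, copies x samples (TPM)
    truth: list[dict]


def _tier_from_tpm(tpm: float) -> str:
    x = np.log2(tpm + 1.0)
    if x >= 1.0:
        return "normal"
    if x >= 0.1:
        return "low"
    return "none"


def simulate_pseudogene_family(n_copies: int, omega: float = 0.3,
                               truncation_dist=None,
                               chimera_fraction: float = 0.8,
                               tpm_dist=None, n_codons: int = 115,
                               subs_per_site: float = 0.1,
                               seed: int = 0) -> PseudoFamilySim:
    """A ribosomal-protein-like gene family: one intact gene plus processed
    (intronless, promoterless, possibly 5'-truncated) retrocopies mutated
    under a codon model with dN/dS ~ ``omega``, each with a TPM draw and,
    for a fraction, an LTR-chimera segment layout (5'-LTR / pseudogene /
    INTERNAL / 3'-LTR, with the 5'-LTR usually the shorter)."""
    if n_copies < 0:
        raise ValueError("n_copies must be >= 0")
    rng = np.random.default_rng(seed)
    base_cds = random_cds(n_codons, rng)
    base_record = {
        "candidate_id": "base", "coverage": 1.0, "intron_count": 2,
        "has_promoter": True, "has_domain_hit": True, "cds": base_cds,
    }
    if truncation_dist is None:
        def truncation_dist(r):   # 70% intact, else 5'-truncate up to 40%
            return 0.0 if r.random() < 0.7 else float(r.uniform(0.05, 0.4))
    if tpm_dist is None:
        def tpm_dist(r):          # most copies silent, some low, few normal
            u = r.random()
            if u < 0.70:
                return float(r.uniform(0.0, 0.07))
            if u < 0.90:
                return float(r.uniform(0.1, 0.9))
            return float(r.uniform(1.0, 20.0))

    copies: list[dict] = []
    truth: list[dict] = []
    tpms = {}
    for i in range(n_copies):
        cid = f"copy_{i:04d}"
        trunc = float(truncation_dist(rng))
        cut_codons = int(round(trunc * n_codons))
        kept = base_cds[3 * cut_codons:]
        mutated = mutate_cds(kept, omega, subs_per_site, rng)
        coverage = (n_codons - cut_codons) / n_codons
        chimera = bool(rng.random() < chimera_fraction)
        segments = None
        if chimera:
            ltr3 = int(rng.integers(350, 460))
            ltr5 = ltr3 - int(rng.integers(0, 120)) if rng.random() < 0.85 \
                else ltr3 + int(rng.integers(1, 40))
            ltr5 = max(80, ltr5)
            x = int(rng.integers(0, 500_000))
            plen = len(mutated)
            segments = [
                ("LTR", x, x + ltr5),
                ("pseudogene", x + ltr5 + 50, x + ltr5 + 50 + plen),
                ("INTERNAL", x + ltr5 + 100 + plen, x + ltr5 + 100 + plen + 2000),
                ("LTR", x + ltr5 + 2150 + plen, x + ltr5 + 2150 + plen + ltr3),
            ]
        tpm = float(tpm_dist(rng))
        tpms[cid] = tpm
        copies.append({
            "candidate_id": cid, "coverage": coverage, "intron_count": 0,
            "has_promoter": False,
            "has_domain_hit": coverage >= 0.2,
            "cds": mutated, "base_aligned": kept, "segments": segments,
        })
        truth.append({
            "candidate_id": cid, "omega": omega, "truncation": trunc,
            "intron_count": 0, "chimera": chimera,
            "tier": _tier_from_tpm(tpm),
        })
    import pandas as pd
    expression = pd.DataFrame(
        {"tpm": [tpms[c["candidate_id"]] for c in copies]},
        index=[c["candidate_id"] for c in copies],
    )
    return PseudoFamilySim(base_cds=base_cds, base_record=base_record,
                           copies=copies, expression=expression, truth=truth)


# ---------------------------------------------------------------------------
# synthetic gene track
# ---------------------------------------------------------------------------

def simulate_gene_models(genome_length: int, gene_length: int = 21_000,
                         spacing: int = 30_000, offset: int = 4_000,
                         chrom: str = "chr1") -> list[GeneModel]:
    """Deterministic gene track: genes of ``gene_length`` every ``spacing``
    bp (alternating strand), mirroring the genome's ~21-kb mean gene span."""
    genes = []
    i = 0
    start = offset
    while start < genome_length:
        end = min(start + gene_length, genome_length)
        if end - start >= 200:
            genes.append(GeneModel(f"gene_{i:03d}", chrom, start, end,
                                   "+" if i % 2 == 0 else "-"))
        i += 1
        start = offset + i * spacing
    return genes
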