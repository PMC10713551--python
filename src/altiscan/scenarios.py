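"""Benchmark scenarios: the simulated study conditions the package is
validated against, shared by the test suite and ``scripts/acceptance.py``.

The scan scenario is a two-population design on a 200-kb sequence with
N = 200 diploids per population and 20 sampled diploids per population:
the populations split 200 generations ago, the focal population passes
through a modest bottleneck right after the split (150 diploids for 30
generations; the separate bottleneck-direction check uses a 10-fold
bottleneck), and a beneficial allele with s = 0.1 appears at the sequence
midpoint 170 generations ago — fixing, on average, a few tens of
generations before sampling, so that the diversity trough, the
differentiation peak and the haplotype-homozygosity excess are all present
at once. theta = 4*N*mu = 1.6e-3 per site puts per-window SNP counts and
per-site diversity in the range reported for butterfly resequencing data.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import GenomicWindow
from .simdata import SimParams, simulate_gene_models, simulate_two_pop
from .winstats import make_windows, window_pi
from . import pipeline


def scan_params(seed: int, sel_coeff: float = 0.1) -> SimParams:
    """The sweep-scan study conditions (defaults of :class:`SimParams`)."""
    return SimParams(sel_coeff=sel_coeff, seed=seed)


def sweep_target_gene(params: SimParams) -> str:
    """Id of the gene overlapping the selected position."""
    genes = simulate_gene_models(params.seq_length)
    for g in genes:
        if g.start <= params.sel_position < g.end:
            return g.gene_id
    raise RuntimeError("no gene overlaps the selected position")


def run_scan_replicate(seed: int, sel_coeff: float, outdir) -> bool:
    """One end-to-end scan through the pipeline entry point; True when the
    gene overlapping the selected position is called (>= 2 methods)."""
    params = scan_params(seed, sel_coeff)
    config = {
        "seed": seed,
        "populations": {"focal": "focal", "ref": "ref"},
        "simulate": {k: getattr(params, k)
                     for k in params.__dataclass_fields__ if k != "seed"},
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = pipeline.run_full_scan(config, outdir)
    target = sweep_target_gene(params)
    return any(c.gene_id == target for c in result.candidates)


def sweep_recovery_rate(n_reps: int, base_seed: int, sel_coeff: float,
                        workdir) -> float:
    """Fraction of replicates in which the sweep-site gene is called."""
    rng = np.random.default_rng(base_seed)
    seeds = rng.integers(1, 2**31 - 1, size=n_reps)
    hits = 0
    for i, seed in enumerate(seeds):
        hits += run_scan_replicate(int(seed), sel_coeff,
                                   f"{workdir}/rep_{sel_coeff}_{i:02d}")
    return hits / n_reps


def nominal_two_method_rate(n_windows: int = 10, n_supporting: int = 4,
                            k_selected: int = 1,
                            n_methods: int = 4) -> float:
    """Chance level for a >= 2-method call if every method picked its
    windows uniformly at random (hypergeometric per method, binomial
    across methods) — the yardstick for the neutral false-call rate."""
    from math import comb
    p_miss = comb(n_windows - n_supporting, k_selected) / comb(n_windows,
                                                               k_selected)
    p_hit = 1.0 - p_miss
    p0 = (1 - p_hit) ** n_methods
    p1 = n_methods * p_hit * (1 - p_hit) ** (n_methods - 1)
    return 1.0 - p0 - p1


def bottleneck_direction_rate(n_reps: int, base_seed: int,
                              fold: int = 10) -> float:
    """Fraction of neutral replicates with focal pi < reference pi under a
    ``fold``-fold bottleneck in the focal population."""
    rng = np.random.default_rng(base_seed)
    seeds = rng.integers(1, 2**31 - 1, size=n_reps)
    lower = 0
    for seed in seeds:
        base = SimParams()
        p = SimParams(sel_coeff=0.0, seed=int(seed),
                      bottleneck_size=base.size_focal // fold,
                      bottleneck_duration=30)
        haps, _ = simulate_two_pop(p)
        w = GenomicWindow(haps.chrom, 0, p.seq_length)
        pi_f = window_pi(haps.population("focal"), w)
        pi_r = window_pi(haps.population("ref"), w)
        lower += pi_f < pi_r
    return lower / n_reps
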