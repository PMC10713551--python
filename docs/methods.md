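# Methods

`altiscan` implements the computational core of a two-population
resequencing study of local adaptation: windowed selection statistics with
multi-evidence sweep calling, classification of transposon-mediated
structural variants (TE-SVs), LTR retrotransposon accounting and dating,
and processed-pseudogene analysis. Because the real study's data volume is
far beyond desk scale, every analysis is exercised end-to-end on synthetic
data with known ground truth; this note records the models, conventions
and parameter choices, and what the synthetic benchmarks do and do not
demonstrate.

## The demographic simulator

`simdata.simulate_two_pop` is a discrete-generation Wright–Fisher forward
simulator with recombination and infinite-sites mutation on discrete base
pairs. Design choices:

* **Coalescent-seeded initialization.** The whole ancestral population
  (2·`ancestral_size` haplotypes) is drawn from a neutral coalescent
  (msprime) at mutation–drift equilibrium, replacing a ≥ 4N-generation
  burn-in. Forward simulation starts at the population split.
* **Infinite sites on discrete bp.** A new mutation landing on an occupied
  position is redrawn, keeping every site biallelic, as the SNP pipeline
  downstream assumes. Sites lost or fixed in the whole metapopulation are
  pruned each generation.
* **Selection.** A single beneficial allele (fitnesses 1, 1+hs, 1+s;
  additive h = 0.5 by default) is injected into one random focal-population
  haplotype `sel_start` generations before present. The trajectory is
  conditioned on non-loss at sampling time by restarting from the injection
  state, with a hard cap of 1000 restarts (then an error, never silent
  neutral output).
* **Bottleneck.** The focal population's diploid size follows a step
  schedule (`bottleneck_size` between `bottleneck_start` and
  `bottleneck_start − bottleneck_duration` generations before present).
* **Sampling.** `sample_ref`/`sample_focal` diploids are drawn without
  replacement; the emitted matrix keeps sites segregating in the combined
  sample, and the truth record stores per-site allele counts recomputed
  from that same matrix (so conservation is testable), the sweep allele's
  final population frequency, and the restart count.

### Default study conditions

The defaults of `SimParams` define the benchmark scenario used everywhere
(tests and `scripts/acceptance.py`):

| parameter | value | rationale |
|---|---|---|
| N (ancestral, ref, focal) | 200 diploids | desk-scale population size |
| L | 200 kb | ten 20-kb scan windows |
| split time | 200 generations | enough differentiation for FST contrasts without drowning local signals in drift |
| bottleneck | 150 diploids, generations 195–165 | a clear but modest focal bottleneck directly after the split; placing it early lets recombination break up bottleneck haplotypes before sampling, which keeps the haplotype-homozygosity scan informative |
| sweep | s = 0.1, h = 0.5, injected 170 generations ago at 100 kb | with 2Ns = 40 the allele typically fixes a few tens of generations before sampling, so the diversity trough, the differentiation peak, Tajima's D excess of rare variants and the XP-EHH excess coexist at sampling time |
| μ | 2×10⁻⁶ /site/generation | θ = 4Nμ = 1.6×10⁻³: per-site diversity of order 10⁻³, the magnitude seen in butterfly resequencing panels, and ~250 SNPs per 20-kb window (eligibility ≥ 10 is never binding) |
| r | 1×10⁻⁶ /bp/generation | ρ/θ = 0.5; hitchhiking footprint of a few tens of kb, matching the 20-kb window scale |
| samples | 20 diploids per population | desk-scale sequencing panel |

The per-site/per-year substitution rate 5.6×10⁻⁹ with one generation per
year is used where the analysis is a molecular clock (LTR insertion-time
dating), not as the forward-simulation mutation rate: at N = 200 a
realistic per-generation rate would produce essentially no polymorphism on
200 kb. This is the usual small-population rescaling of forward
simulation.

The 10-fold bottleneck check (focal π < reference π) sets
`bottleneck_size = 20` explicitly; the scan scenario keeps the milder
default so that sweep mapping stays informative.

### What the scenario shows and what it does not

Passing the sweep-recovery benchmark shows that the whole chain — VCF
round trip, window construction, four statistics, tail selection with the
ceiling rule, region merging/extension, gene assignment — is wired
correctly and that the statistics rank a genuine hard sweep above neutral
background most of the time at desk scale. It does not calibrate power for
any real dataset: the real study had ~65,000 windows and 1% tails, while
ten windows force the nearest-rank tail to a single window per method, and
drift/bottleneck "pseudo-sweep" genealogies put a physical ceiling
(roughly 70–75% per statistic, ~85–90% for the ≥2-of-4 combination) on
desk-scale identification. The neutral false-call bound is likewise a
chance-level yardstick (a uniform-pick model over eligible windows), not a
false-discovery-rate estimate.

## Window statistics

* **π** per site is c₀c₁/C(n,2); the window value divides by the full
  window span (the convention of VCF-based windowed-π tools), not by
  callable sites; configurable.
* **π ratio** is focal/reference; windows with reference π = 0 are marked
  undefined and excluded from tails rather than treated as infinite.
* **FST** is the Hudson estimator in the Bhatia et al. form, aggregated as
  a ratio of sums over the window's usable sites (per-site averaging is
  available); sites where either population has < 2 sampled alleles are
  skipped; negative values are retained because tail selection operates on
  ranks.
* **Tajima's D** uses the standard 1989 constants; only complete-genotype
  sites enter, so a single sample size applies per window (a documented
  deviation from site-wise n when data are missing; simulated data are
  complete).

## The haplotype scan

EHH follows the cross-population (all-haplotype) convention: at extension
x, EHH is the probability that two distinct haplotypes drawn without
replacement from one population are identical at every site from the core
(inclusive) through x; the curve starts at (0, 1) by definition. iHH is
the trapezoidal integral of EHH against physical distance in both
directions, truncated at the linearly interpolated crossing of the cutoff
(default 0.05). XP-EHH is ln(iHH_focal/iHH_ref), standardized genome-wide
in a single bin and averaged per 20-kb window.

Two integration conventions are implemented. The default (`extent=
"combined"`) integrates both populations over the shared extent at which
the pooled-sample EHH remains above the cutoff — the convention of the
cross-population scan tool this module re-implements — which prevents a
low-diversity (bottlenecked) population from accumulating area simply by
having longer homozygosity everywhere. The per-population alternative
(`extent="separate"`), composing `ehh_curve` and `ihh` directly, is kept
for comparison. Core sites are filtered at combined-sample minor allele
frequency ≥ 0.05 by default (the usual core-SNP filter; configurable),
distances are physical (no genetic map), gaps > 200 kb truncate the curve
and extension is capped at 1 Mb.

## Sweep calling

Eligible windows have ≥ 10 SNPs and a defined statistic. Tail selection is
nearest-rank: the k = ⌈fraction·n⌉ most extreme windows, ties at the
threshold included, hence at least one window even when n < 1/fraction (a
warning is logged). Direction registry: π ratio lower tail, FST upper,
XP-EHH upper (focal-positive), focal-population Tajima's D lower. Selected
windows are merged per method, extended ±20 kb (clipped at 0), and genes
are assigned on ≥ 1 bp overlap with the gene body; candidates need ≥ 2
supporting methods. Whether D is ranked within the focal population alone
was left open upstream; focal-only is implemented and configurable.

## TE-SV analysis

SVs are filtered to 50 bp–100 kb (inclusive). The TE annotation is merged
to a union per chromosome before overlap so nested/overlapping repeats are
not double-counted; the overlap fraction of the SV locus then classifies
it: ≥ 90% TE-SV, exactly 0 No TE-SV, otherwise uncertain. Insertions
carrying a pre-computed matched-base count use `te_match_bases/length`.
For window contrasts a 10-kb window is "with" when ≥ 1 TE-SV intersects
it; windows touched only by uncertain SVs count as "without" by default
(a strict mode excludes them). The contrast reports exact group means,
seeded percentile-bootstrap 95% CIs, and a two-sided test — Mann–Whitney
on windows, or a paired Wilcoxon over per-chromosome means when grouping
by chromosome (the study design compares 29 chromosome pairs; the upstream
test is unnamed, so the choice is documented and configurable). Gene
counts tally TE-SVs intersecting the strand-resolved upstream 3-kb flank,
gene body, and downstream 3-kb flank, counting an SV in every region it
touches.

## LTR retrotransposons

K2P distance uses transition/transversion proportions over non-gap
columns; 1−2P−Q ≤ 0 or 1−2Q ≤ 0 raises a saturation error. CpG columns
are not excluded by default. Insertion time is T = k/(2r) with
r = 5.6×10⁻⁹ /site/year. Family assignment is the 80-80-80 rule — ≥ 80%
identity (matches / aligned non-gap columns) over ≥ 80 aligned bp covering
≥ 80% of the shorter sequence — with single-linkage connected components,
labels canonicalized by smallest member id. Pairwise alignment is a
pluggable global Needleman–Wunsch (Biopython `PairwiseAligner`; match 2,
mismatch −1, gap open −4, extend −0.5); pre-aligned pairs are accepted.
The solo/complete ratio (the unequal-recombination proxy) is NaN when no
complete element exists. The divergence landscape weights each element by
its masked base count in 1%-wide divergence bins.

The simulator builds complete elements by evolving both LTRs k/2 from the
inserted copy under an exact K2P transition-probability process (κ = 2),
so the expected inter-LTR distance is k and the K2P estimator is the
matching inverse; solo elements are single family-derived copies.

## Pseudogenes

Candidates are classified from translated coverage (denominator: the
intact member's complete protein length), intron count, promoter flag and
domain hit: no domain hit or coverage < 70% → discarded; coverage ≥ 95%
with ≥ 1 intron and a promoter → complete; otherwise processed. Promoter
presence is an annotation input, not a motif scan. Ka/Ks is Nei–Gojobori
(1986): site fractions with denominator 3 per codon position, single-base
changes creating stops excluded from both classes; multi-step codon
differences averaged over mutational pathways, excluding pathways through
stop codons unless all are blocked; Jukes–Cantor correction, with a
saturated proportion (p ≥ 3/4) mapped to an infinite distance (so a
purely synonymous saturated pair has ratio 0) and Ka/Ks undefined at
Ks = 0. The generator's codon model accepts synonymous proposals always
and non-synonymous ones with probability ω, rejecting stops, which makes
the NG86 estimate concentrate near ω.

Expression tiers on x = log₂(TPM+1): normal x ≥ 1, low 0.1 ≤ x < 1, none
x < 0.1. Chimera detection looks for the ordered LTR / pseudogene /
INTERNAL / LTR pattern on one chromosome and strand, tolerating
interleaved other segments and gaps up to a configurable tolerance
(default 1 kb — the stand-in for an upstream masking-score cutoff with no
equivalent here); the record compares 5′- and 3′-LTR lengths.

## Pipeline and determinism

`pipeline.run_full_scan` drives simulate/ingest → hard filters → window
statistics → XP-EHH → sweep calling → TE-SV tables from one config; every
stage is a pure function of (config, seed), and the manifest records all
parameters, the seed and input checksums. LD pruning (r² of genotype
dosages in 10-kb windows, threshold 0.5, keep-left tie rule) is applied to
structure-style analyses on request, not to the selection scan, mirroring
the upstream study's usage. Hard-filter conditions with a missing INFO
metric are skipped by default (strict mode available); the filter string's
garbled rank-sum entries upstream are read as the standard
MQRankSum < −12.5 and ReadPosRankSum < −8.0.

## Benchmark sizes

The suite and the acceptance script use 20 replicates for the scan and
bottleneck scenarios, 1000 SVs, 100 LTR elements per divergence level, and
50 pseudogene copies of 500 codons — sizes chosen so each recovery target
has comfortable sampling error on a single CPU.

## Known limitations

* Chromosome-scale realism (gene conversion, migration, variable
  recombination, selection on standing variation) is out of scope; the
  simulator is a desk-scale instrument.
* Ten windows make 1% tails degenerate (ceiling rule → one window per
  method); the end-to-end benchmark is a wiring-and-direction check, not a
  power analysis.
* The NG86 stop-codon conventions follow the package's documented choices;
  other calculators differ in the third decimal on saturated or
  stop-adjacent codons.
* EHH uses physical distance only; with a genetic map the integrals would
  differ in recombination hot/cold regions.
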