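# Methods

This note records the models, parameter choices and numerical decisions
behind each stage, what the synthetic data does and does not emulate,
and the known limitations.

## Hairpin folding and the structure p-value

Candidate precursors are folded with a weighted base-pair maximization
over nested structures (Nussinov-style dynamic programming): pair
weights G-C = 3, A-U = 2, G-U = 1, hairpin loops of at least 3 nt.
This is a deliberate simplification of thermodynamic folding — the
weights track pair stability order, not free energies — chosen because
it admits an exhaustive-enumeration oracle (the test suite checks the
DP against brute force on all random sequences up to length 12) and is
fast enough (numba-compiled) to refold thousands of shuffled sequences.
Traceback ties resolve toward pairing with the smallest admissible
partner, so structures are deterministic.

The structure test mirrors randfold: p = (c + 1)/(n + 1) where c counts
dinucleotide-preserving shuffles (Altschul-Erickson Eulerian-walk
construction: a uniformly chosen last-exit arborescence plus uniform
permutations of remaining out-edges) whose pairing score is at least
the observed score; with the default 99 shuffles the attainable minimum
is 0.01, comfortably below the 0.05 filter.

**Calibration caveat.** Because the pairing score is a small integer
(the shuffle-score SD of a random 70-mer is only ~1.4), the observed
score ties a shuffle's score ~18% of the time, and the `>=` counting
makes those ties conservative. The p-value is therefore super-uniform —
P(p <= t) <= t holds everywhere, which the suite asserts — but its CDF
sits below the diagonal by roughly half the tie mass, so a strict
Kolmogorov-Smirnov uniformity check fails by design. The corresponding
acceptance test is kept, failing, as documentation: the statistic never
overstates significance, it understates it. A continuous folding score
would remove the ties at the cost of the exhaustive oracle.

## Read simulation and the Dicer signature

Planted precursors are arm + loop + reverse-complement(arm) (30 bp
stem, 8 nt loop). True loci receive a mature-arm stack (88% of reads at
the modal 5' end, +/-1 nt jitter otherwise, lengths 21-23) plus a
quarter-depth star stack with a 2-nt 3' overhang; decoys receive the
same depth smeared uniformly with 18-30 nt reads; background reads
arrive as a Poisson process (0.5 reads/kb by default). The signature
score of a locus is (fraction of reads starting within 2 nt of the
mature or star 5' end) x (modal-start fraction within the mature
stack); a clean stack scores 1.0 and a uniform smear rarely exceeds
0.2. The emission cutoff (0.6) and the locus-merge gap (30 nt, chosen
to bridge the uncovered loop between arm stacks) are configurable; the
cutoff has no counterpart value in the source study design and is a
package default.

Not emulated: sequencing errors, adapters, quality scores, isomiR
heterogeneity beyond the 5' jitter, multi-mapping, and minus-strand
loci in the generator (the discovery code is strand-aware; the
generator plants on the forward strand only). Passing tests show the
pipeline recovers planted stacks with these idealizations, not that it
is robust to real-library artifacts.

## Filter cascade

The six steps run in a fixed order and log every transition and
rejection. Decisions the source design left open:

- rRNA/tRNA exclusion is any 1-bp overlap with the provided annotation
  intervals.
- duplicates key on the exact mature sequence, keeping the
  highest-signature locus.
- GC statistics use the mature sequence and the population SD
  (divisor N), single pass.
- the homology screen replaces an external BLASTN binary with
  Smith-Waterman (match +1, mismatch -2, gap -5/-2) plus ungapped
  Karlin-Altschul statistics: lambda solves sum p_i p_j e^(lambda s) = 1
  (uniform bases), and K comes from the lattice-case series; the code
  reproduces the published BLASTN ungapped constants (+1/-2 -> 1.3327,
  0.6210). Using ungapped (lambda, K) with gapped scores is the usual
  conservative approximation at these penalties. Note the screen is
  calibrated by construction: against an unrelated database, a
  candidate still has roughly a 10% chance of E < 0.1 — that is what
  an E-value threshold of 0.1 means, and it is inherited from the
  study design, not a defect of the reimplementation.

Knm IDs serialize the retained set in (chrom, start) order; the
"locus position" part of the original ID format is thus a rank, a
choice the ID string cannot distinguish from a coordinate.

## TMM and expression gates

TMM follows its definition exactly (reference by the 75th-percentile
rule; M/A values over loci nonzero in both samples; 30% M-trim and 5%
A-trim per tail by ranks; weights = inverse delta-method variances;
factors rescaled to geometric mean 1) and agrees with edgeR's
`calcNormFactors` to printed precision on NB fixtures; the suite pins
it to an independent straight-line recomputation at 1e-10 and to edgeR
at 1e-6. Normalized values are TMM-scaled counts per million; the
TMM > 0.1 gates are interpreted on that CPM scale. The 10%-of-samples
gate rounds up (71 samples -> 8).

TMM assumes most features are not differentially expressed. In the
pipeline the factors are therefore anchored on the full quantification
— the novel loci plus a background complement of null features standing
in for the annotated small-RNA profile (300 by default in the study
configurations) — and the novel loci are normalized with those factors.
Normalizing over a small, half-DE novel set alone demonstrably biases
the factors and inflates false positives.

## Differential expression

A paired Student t-test on the normalized values (df = n_pairs - 1),
two-sided; an unpaired Welch variant and a log2 option exist behind
flags. Fold change is the mean over pairs of (tumour + 0.01)/(normal +
0.01); the pseudo-expression guards the near-total-loss loci the study
design highlights. Zero-variance difference vectors give p = NaN
(excluded from the BH m) unless the differences are exactly zero, which
is reported as p = 1. BH adjustment is the standard step-up with a
cumulative minimum, NaN-aware. Clustering is UPGMA on 1 - Pearson.

## Survival

Tertiles: sort descending (ties broken by a stable sort on patient ID),
floor(n/3) to each extreme, remainder to the middle so the compared
groups stay balanced; the default comparison is top vs bottom tertile.
The weighted log-rank statistic uses the hypergeometric variance with
tied event times grouped and n_j = 1 terms dropped; w_j = n_j gives
Gehan-Breslow-Wilcoxon (early-difference emphasis), w_j = 1 the
log-rank. Both match lifelines on shared fixtures and a 20,000-label-
permutation null within Monte-Carlo error. Survival simulation is
exponential with an independent exponential censoring time (rate set
so the null censoring fraction equals `censor_rate`) and a 10-year
administrative horizon. With 71 pairs and a planted hazard ratio of 3
on the top tertile, the test's power is moderate (roughly 50-85%
depending on censoring draws), so the planted-locus p-value reported by
the acceptance script is legitimately variable across seeds.

## Target prediction and duplex energy

The aligner is a Smith-Waterman local DP on complementarity, miRNA
antiparallel to the UTR, affine gaps, with pair scores at miRNA seed
positions 2-8 multiplied by 4; non-overlapping hits are extracted
best-first by masking. A perfect 22-nt complementary site scores
15x5 + 7x20 = 215 against the fixed acceptance thresholds of score
>= 140 and energy <= -20 kcal/mol; only those two thresholds come from
the study design, the scoring constants are package defaults in the
classic miRanda style.

Duplex energy sums Turner 2004 nearest-neighbor stacking terms over
contiguous pair steps, +4.09 kcal/mol initiation, and a flat +3.0 per
interior loop or bulge — a deliberately coarse surrogate for full
duplex thermodynamics. The shipped stack table carries the published
values; note that wobble-on-wobble steps (GU/UG +1.3, UG/UG +0.3) are
genuinely destabilizing, so "adding a pair never raises the energy"
holds only for steps involving a Watson-Crick pair, and the tests
assert exactly that.

The scramble null permutes the miRNA uniformly (five scrambles by
default, seeded); any gene also predicted for a scramble discards the
true prediction (gene-level overlap; a coordinate-level mode exists).
Chance hits just past the thresholds (~0.65% per miRNA-UTR pair at
realistic UTR lengths of 400-1200 nt) survive this null by design,
since they are independent of the scrambles. Aggregation keeps genes
hit by at least ceil(10% x n_mirnas) distinct miRNAs; for the
aggregation-plus-enrichment endpoint to measure anything, the generator
must plant shared targets, hence the hub-gene option (sites drawn from
a shared pool of hub genes; 2 sites per miRNA over 12 hubs in the study
configuration).

## Enrichment

Upper-tail hypergeometric per pathway against a gene universe
(default: the union of pathway genes; the study configuration uses all
UTR-bearing genes), BH-corrected, significant at adjusted p <= 0.05.
The synthetic pathway file contains one set collecting the planted
target genes plus random sets.

## Problem sizes and determinism

The bundled demo (24 + 24 loci, 30 pairs, depth 50, 99 shuffles,
150 UTRs) and the study configuration (30 + 30 loci, 71 pairs,
200 UTRs, 300 background features) both run in well under a minute on
one CPU after numba compilation. Every stochastic stage takes one seed
(simulation, discovery shuffles, target scrambles), all flowing through
`numpy.random.Generator`; identical configuration and seeds reproduce
every output file byte for byte, which the acceptance suite checks by
rerunning the demo and comparing bytes.

## Known limitations

- The folding surrogate has no stacking, loop-length or dangling-end
  energetics; its randfold-style p-value is conservative (see above).
- The homology E-value uses ungapped statistics with gapped scores and
  uniform base composition.
- Survival analysis is two-group weighted log-rank only (no Cox model,
  no covariates).
- The paired t-test on CPM values is the study's choice; it is mildly
  sensitive to NB skewness at small n and is not a count-model test.
- Target energies ignore intramolecular structure and accessibility;
  no conservation filtering.
- The synthetic genome is single-chromosome and repeat-free, so the
  homology screen and Knm chromosome labels are exercised trivially.
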