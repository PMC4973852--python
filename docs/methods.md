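# Methods

## The model

`chromstate` segments a genome into chromatin states from binarized
histone-mark presence calls. A hidden state `z_t` is attached to every
150-bp bin `t` and follows a first-order Markov chain; conditional on the
state, the nine marks are independent Bernoulli draws:

    P(x_t | z_t = k) = prod_m  p[k, m]^x_tm (1 - p[k, m])^(1 - x_tm)

so a state is exactly a recurring combination of marks, and the emission
matrix `p` (states x marks) is the object of scientific interest: each cell
is the probability that a mark participates in that state. One state is
expected to be a "zero state" with near-zero emissions, covering unmarked
genome. Chromosomes are treated as independent observation sequences that
share all parameters, including the initial distribution.

Upstream of the HMM, replicate peak calls are consolidated per mark with
three filters applied in order: peaks with fold change **strictly greater
than 4** are kept, each replicate is truncated to its **top 100 000** peaks
by score (ties broken by coordinate for determinism), and merged intervals
(overlapping or book-ended, BEDtools-merge semantics) must be contributed to
by **at least two distinct replicates**. A merged peak's score is the mean
of its contributing peak scores. Downstream, states are relating to
annotation by fold enrichment

    fold(state s, feature f) = P(bin in f | bin in s) / P(bin in f),

whose state-probability-weighted average is identically 1 per feature — an
exact conservation law asserted in the tests at 1e-9.

Differential gene expression between the two tissues is rank-based: each
tissue's RPKM values are ranked ascending (ties mid-ranked) and divided by
the gene count; DGE = |rank fraction(root) − rank fraction(leaf)| in [0, 1),
binned at 0.2 intervals into five classes (0.8 and above falls in the top
bin). The statistic is invariant under any strictly monotone transform of
either tissue's expression scale, which the suite checks property-based.

## Fitting: Baum-Welch with small-EM starts and split-merge refinement

Parameters are estimated by EM. The forward-backward recursions run in
scaled linear space with a per-frame log-offset (the per-frame emission
likelihoods are normalized by their maximum before exponentiation), so
log-likelihoods of million-bin sequences are computed without underflow.
Within the M-step, emissions are floored at 1e-6 to keep the likelihood
finite; `K = 1` bypasses EM entirely because its maximum is closed-form
(emission row = column means, exactly).

The likelihood surface at K = 11 has a characteristic family of local
optima: two states with similar emission vectors collapse into a single
mixed state while a spare state duplicates the abundant zero state. Plain
random-restart EM found the global optimum in only ~10% of starts on 1e5-bin
instances. Two standard remedies are layered on top of the restart scheme:

1. **Small-EM starts.** Each restart draws 8 random initializations
   (emissions ~ Uniform(0.1, 0.9), transition/initial rows ~ symmetric
   Dirichlet), advances each by 8 EM iterations, and continues full EM only
   from the best.
2. **Split-merge refinement** (after the best restart): a proposal merges
   the most correlated pair of emission rows and splits the state with the
   largest posterior-weighted *excess* top eigenvalue of its within-state
   covariance over the product-Bernoulli prediction `diag(p(1-p))` — that
   excess is identically zero for a pure state and large for a state
   absorbing a mixture, so the diagnostic points directly at the collapsed
   state. The split displaces emissions along the excess principal
   direction, and crucially the proposal also remaps Markov mass (the merged
   slot absorbs both incoming transition flows; the split halves share the
   split state's transition profile) — without this the half placed in the
   vacated slot starves and EM undoes the split. Proposals are re-optimized
   by EM and accepted only on a log-likelihood gain > 2; the proposal
   neighbourhood widens once after a fully rejected round. With this
   refinement every tested fit seed reached the same best likelihood on the
   recovery benchmark.

Convergence is declared when the absolute log-likelihood gain falls below
`tol` (default 1e-4), capped at `max_iter = 200` iterations. Decoding is
per-bin posterior argmax by default (ChromHMM's segmentation semantics);
Viterbi is available. Model size is chosen as the smallest K whose fitted
model has, for *every* state of the largest reference model, some state with
emission-vector Pearson correlation above 0.7; a mean-correlation variant is
exposed as an option since the published criterion does not state which
aggregation was used.

A caveat on validating selection with synthetic data: the criterion
presumes that an over-capacity reference spends its spare states on
*duplicates* of real states, as large reference models do on real
epigenomes (where the data always carry more structure than the model).
When data are generated from a pure K-state product-Bernoulli HMM the
opposite happens — the reference slices homogeneous states along
single-mark noise spikes, producing reference states that no smaller
honest model correlates with. The selection benchmark therefore plants
four well-separated state *families* of two highly correlated sub-states
each, giving the reference real sub-structure to absorb; selection then
operates in its intended regime and recovers the family count.

## The synthetic epigenome

The generator emulates the study conditions at desk scale: 2 chromosomes x
30 Mbp by default (4e5 bins at 150 bp), 9 marks with the study's names,
11 planted states (10 marked + zero state), 3 replicates. Each chromosome
is partitioned TP / GRI / LR-PC / GRI / TP with the telomere-proximal
compartments at 10% of the chromosome per end and gene-rich-interior flanks
at 20% each, leaving a 40% pericentromeric core — fractions chosen once as a
plausible miniature of a large cereal chromosome (where the low-recombining
core is half the genome or more) and not revisited.

Within a compartment the hidden chain is `T = a I + (1 - a) 1 pi^T` with
`a = 1 - 1/persistence` (default persistence 8 bins = 1.2 kb), whose
stationary distribution is exactly the compartment's target state profile;
profiles put the H3K27me3 states at high frequency in TP, active genic
states and moderate heterochromatin in GRI, and H3K27me1/H3K9me2 states in
LR-PC. When annotations are overlaid, the chain's renewal distribution is
conditioned on local context (genic states over gene bodies, repressive
states over retroelements) and renews at annotation boundaries, so realized
compartment frequencies blend the genic and intergenic conditionals.

Gene densities default to 18 / 14 / 2 per Mbp in TP / GRI / LR-PC and LTR
retrotransposons to 3 / 10 / 30 per Mbp — the qualitative density contrast
of a large cereal genome at a desk-scale absolute level. Genes are 2–6 kb,
2–5 exons, non-overlapping; retroelements 5–12 kb, placed after genes.
Peak fold changes are log-normal with median 9 (sd 0.5 in log space) so
that most peaks survive the fold-change > 4 filter and default runs are
non-degenerate. Replicates are degraded copies of a master track: whole
intervals drop with probability 1 − concordance (default 0.8 — a free
parameter; the study does not quantify replicate concordance), mimicking
replicate-level peak-calling variability that the ≥2-replicate rule is
designed to absorb. Expression is two-tissue log-normal driven by each
gene's dominant planted state: H3K36me3 states get high balanced
expression, the H3K27me3 genic state gets a large tissue-divergence effect
(3.5 in log2), and 3.5% of genes are unexpressed in both tissues (the
study's unexpressed fraction, 774/21 965).

What the generator does *not* emulate: read-level noise, mappability and
copy-number artifacts of a 75%-repetitive genome, peak-caller boundary
error, correlated replicate failure, or sequence content of any kind.
Passing recovery tests therefore demonstrates correctness of the estimator
under its own model class and robustness of the surrounding bookkeeping —
not peak-calling accuracy on real ChIP-seq.

**Parameter recovery uses observations drawn directly from the planted
emission matrix.** The full peak path (emission → replicate dropout → fold-
change filter → consolidation → binarization) attenuates mark presence by a
factor of roughly 0.9 x 0.95 by construction, so emissions learned through
it estimate the attenuated probabilities — a property of the pipeline, not
a defect of the learner. The peak path is exercised end-to-end by the
pipeline tests and judged qualitatively.

## Zone classification

Chromosome-scale structure is tabulated in 1-Mbp bins (peaks, genes and
retroelements counted once at their midpoint; state bp-fractions exact).
The TP / GRI / LR-PC classifier is an explicit operationalization of zones
that the source material reads visually from density plots: per bin,
genome-pooled z-scores of (a) facultative-heterochromatin state density,
(b) constitutive-heterochromatin state density and (c) gene density are
computed; TP requires `z_a > 0.5` and `z_a > z_b`; LR-PC requires
`z_b > 0.5` and `z_c < -0.5`; everything else is GRI, followed by a 3-bin
majority smoothing. All thresholds are configuration, a known LR-PC mask
can bypass rules (b)/(c), and change-point methods remain an open
alternative. On the default scenario the classifier recovers planted
boundaries within 2 Mbp (2 bins).

## Numerical and procedural choices

- Coordinates are 0-based half-open everywhere; GFF3 converts at the I/O
  boundary. The last genomic bin is truncated, conserving genome length in
  density denominators.
- Metagene profiles exclude introns: the mature transcript is divided into
  100 equal bins by exact integer arithmetic (base `p` of `L` maps to bin
  `(p * 100) // L`), flanks of 1 kb into 100 bins each, TSS always on the
  left. Uncovered bases contribute fold change 0 by default (`uncovered=
  "skip"` averages covered bases only); bins with no bases (mature length
  < 100) are undefined (NaN) and skipped in cross-gene averaging. Only
  transcripts with ≥1 assigned peak contribute; multi-transcript genes are
  represented by their longest mature transcript.
- Expression groups: zero-RPKM genes apart, the rest sort ascending (ties
  by gene id) and split into three groups of sizes `q + (r >= 1)`, `q`,
  `q + (r >= 2)` where `n = 3q + r` — low and high absorb the remainder.
- Consolidation tie-breaks in the top-N truncation are (score desc, chrom,
  start); replicate support counts replicates contributing ≥1 bp to the
  merged interval.
- Peak-sharing correlation is the phi coefficient of 150-bp occupancy
  vectors (one consistent discretization across the package); marks with
  constant occupancy yield NaN with a warning, never 0.
- DGE rank direction is ascending; the statistic is invariant to the common
  choice applied to both tissues, so the direction is immaterial.
- Rolling DGE is a two-pass centered moving average (25 then 250 genes)
  with shrinking windows at chromosome edges; chromosomes with fewer genes
  than the window are skipped with a warning.
- A gene's state is the state with the largest bin-count footprint over the
  gene body; ties break toward the more active state in the reporting
  order. States are reported in descending mean emission over the active
  marks (H3K4me3, H3K56ac, H3K4me2, H3K36me3).
- One global seed expands into per-stage sub-seeds via
  `SeedSequence(seed).generate_state(...) % 2**31`; every simulated object
  is a pure function of (parameters, seed), and the pipeline manifest
  records a SHA-256 per output so re-runs are verifiably bit-identical.

## Problem sizes

The test suite and the acceptance script run the recovery benchmark on a
2 x 7.5 Mbp scenario (1e5 150-bp bins) — the model-recovery problem is
scale-free once each state holds a few thousand bins, and this size keeps a
5-restart fit around five minutes on one CPU. Zone recovery runs on the
full 2 x 30 Mbp default (it needs no EM), model selection on 12 000-bin
instances with 10 seeded repetitions, and the end-to-end determinism check
on a 2 x 1.5 Mbp scenario with K = 6.

## Known limitations

- The Bernoulli HMM ignores peak scores after binarization; fold-change
  information enters only the gene-level analyses.
- The split-merge refinement is greedy and accepts the first improving
  proposal; it is a heuristic against one failure family, not a global
  optimizer.
- The zone classifier assumes both chromosome ends are telomere-proximal
  and was not designed for acrocentric or translocated architectures.
- The synthetic generator's regional chain is piecewise-homogeneous; real
  chromosomes show gradients, not step changes, in state composition.
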