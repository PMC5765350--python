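# Methods

This note records the models, conventions and numerical choices behind
`motifbench`, and what the synthetic-data generator does and does not
emulate.

## Motif model and scoring

A motif is a position weight matrix (PWM): one probability distribution
over A, C, G, T per position, rows validated to sum to 1 within 1e-6
(file rows off by ≤ 1e-3 are renormalized on read; larger deviations are
rejected with the motif name and row index).

**Log-odds scanning.** The scoring matrix is

    S[i][b] = log2( (p[i][b] + c·q[b]) / ((1 + c)·q[b]) )

with background `q` (uniform by default) and pseudocount `c = 0.01`
distributed proportionally to the background, so a uniform PWM maps to the
all-zero matrix for every pseudocount. A sequence's score is the maximum
window sum over both strands (ChIP peaks are strandless, so both-strand
scanning is the default everywhere). `N` bases contribute 0 — the
background-equivalent value. These internals (base-2, uniform background,
c = 0.01, both strands) are this package's conventions; they are the
standard reading of "maximum PWM match" scoring and are all configurable.

**Affinity scoring.** The affinity of a sequence is the sum over all
windows on both strands of the product of per-position base probabilities
(`N` counts 0.25). Raw summed probabilities are used rather than their
logarithm: this preserves occupancy semantics and makes the uniform-motif
closed form exact (2·(l−w+1)·0.25^w). A `log_affinity` toggle exists for
heavy-tail damping and is off by default.

## Sequence nulls

**Dinucleotide shuffle** follows the Altschul–Erickson Euler-path
construction: for each vertex except the final character a random last
out-edge is drawn until the last-edge graph reaches the sink from every
source, remaining edges are randomly ordered, and the Eulerian path is
walked. This preserves the exact overlapping-dinucleotide multiset, the
endpoints and the length. Runs of non-ACGT characters are frozen in place
and the ACGT segments between them shuffled independently, preserving
masked-region structure without inventing bases. One shuffle per positive
sequence (1:1) is the default negative set for AUROC; within an evaluation
grid the shuffles are generated once per peak set so every motif is
compared on identical negatives.

**Random backgrounds** are i.i.d. uniform ACGT, seeded; the similarity
background defaults to n = 100,000 sequences of length 100, shared across
all pairs of a matrix so values are comparable.

## Peaks and ERE profiles

Coordinates are 0-based half-open (BED convention); summits are absolute
positions. Peaks within 50 bp are merged before any top-N statistic; the
merged peak takes the maximum member score and that member's summit (score
ties break to the leftmost start). Top-N (N = 500) selects by score with
(chrom, start) tie-breaks for determinism. A summit window is
[summit − 250, summit + 251), 501 bases unclipped.

"Overlap within ±250 bp of the summits" is read as *window intersection*
(summit distance ≤ 500 bp), matching how the scored sequences themselves
are defined; the stricter summit-in-window reading (≤ 250 bp) is available
behind a flag. Overlap is directional and counts each query peak at most
once.

An ERE profile is the per-class fraction of top-N summit windows
intersecting at least one instance of the class; one window can count
toward several classes, so fractions may sum to more than 1. Correlations
between profiles use the full class vector including zeros; a constant
vector yields a missing value (NaN), never an arbitrary number. In the
matched/unmatched decomposition all 2k profiles are pooled:
k matched pairs and C(2k,2) − k unmatched pairs, *including* within-dataset
different-protein pairs — the pooled census is the only reading consistent
with 2,964 unmatched comparisons at k = 39. "Above a threshold" is strict,
and the best-separation rule maximizes (matched fraction − unmatched
fraction) over observed correlation values, ties to the lowest threshold.
Whether a fixed or best-separation threshold is appropriate depends on the
question; both are provided.

## AUROC

Computed exactly via midranks (`scipy.stats.rankdata`); no normal
approximation and no p-values. Midrank ties are what make an all-tied
comparison exactly 0.5 (e.g. a uniform motif, whose scores are constant).
Windows shorter than a motif are dropped from positives and negatives
symmetrically; a motif wider than every window is recorded as missing.

## Selection rules

Rules are evaluated strictly in order A → F on per-candidate scores:
"test score" = maximum AUROC over non-training peak sets (aggregation by
maximum; configurable to mean), "train score" = AUROC on the training set.
Boundary semantics are literal: class A requires a margin ≥ 0.1, class B a
gap < 0.1, class E the closed interval [0.01, 0.09] — so margins in
(0.09, 0.1) fall through to F. Within-class ties break by higher test
score, then RCADE over MEME over external, then motif name. Class C picks
the highest-test-score recognition-code candidate (train score as fallback
when no test set exists). Class F reports all remaining candidates as
co-equal. Disagreement flags use strict inequalities (ERE r < 0.3, motif
r < 0.2); missing values raise no flag.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:

- ERE classes as random consensus sequences whose genomic copies diverge by
  per-base substitution (`copy_mutation_rate` = 0.10) — the common-descent
  confound, without indels so coordinates stay simple;
- per-protein information-rich motifs (dominant base 0.85 per column,
  width 12) planted at a pool of 200 sites, 60% inside the protein's 1–3
  assigned ERE classes and 40% at non-repeat loci;
- two peak sets per protein, each drawing 70% of its 150 peaks from the
  shared pool without replacement (30% false peaks at uniform non-site
  positions), summits jittered with clipped Gaussian noise (sd 20 bp),
  scores Gaussian with true peaks higher on average
  (means 10 vs 8, sd 1) — so cross-dataset peak sharing follows the
  hypergeometric expectation and overlap is partial by construction;
- candidate motifs per protein: the true PWM (recognition-code supported),
  a copy with 60% of columns replaced by uniform (the corruption level at
  which decoys trail the true motif by the intended AUROC margin of
  ≥ 0.15 while remaining sequence-related), an unrelated protein's PWM,
  and optionally a Dirichlet-perturbed "in vitro" motif (off by default —
  a near-true in vitro candidate deliberately creates class-B ties and is
  a scenario knob, not a default condition).

Default scale is desk-sized — a 2 Mb single-chromosome genome, 10 proteins,
10 ERE classes × 40 copies — chosen so AUROCs are stable while the full
pipeline runs in seconds. What passing tests on this generator shows is
that the statistics recover planted structure under the stated noise model;
what they cannot show is robustness to properties of real data the
generator omits: indel-diverged and nested repeats, GC and mappability
biases, non-uniform genomic background, fragment-size effects on summit
accuracy, indirect (tethered) binding, and motif discovery itself (motifs
enter as inputs; the RCADE flag is metadata, not a re-derivation).

## Determinism and degenerate inputs

Every stochastic operation takes an integer seed or numpy Generator;
stage-level child seeds are spawned from one master seed so adding a stage
never perturbs earlier ones, and identical seeds give byte-identical
outputs (manifest checksums are reproducible). Degenerate cases are
contracts, not accidents: empty motif files parse to empty lists; empty
peak sets make overlap and profiles *errors*; constant vectors make
correlations *missing*; sequences shorter than a motif are errors in direct
scoring but symmetric drops in grid evaluation; length-1 and
single-letter sequences are their own shuffles.
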