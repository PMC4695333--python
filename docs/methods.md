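# Methods

This note documents the models, parameter choices, numerical details and
known limitations of `deducemeth`. The package analyzes RRBS data without a
reference genome; every quantitative claim below is computed by the test
suite or by `scripts/acceptance.py`, not asserted from memory.

## Read trimming

Quality trimming uses the BWA running-sum rule: scanning from the 3' end,
accumulate (cutoff − q) and cut at the leftmost maximum of the running sum
when it is positive. We use a full scan rather than the early-break variant
so the operation is provably idempotent. Adapter removal matches the
longest read suffix against an adapter prefix (or a fully contained
adapter) at ≤ 10% mismatches with minimum overlap 1 — deliberately
aggressive, as is standard for RRBS where short inserts make adapter
read-through common. Because adapter removal can expose a new low-quality
tail (and vice versa), the two trimmers alternate until a joint fixpoint;
this guarantees trim(trim(r)) == trim(r), which single-pass trimming does
not satisfy. Defaults: Phred+33, quality cutoff 20 (below this, bisulfite
miscalls start to dominate C/T discrimination), minimum length 16 (shorter
reads seed unreliably), TruSeq single-end adapter. N bases pass through
trimming untouched; downstream, reads containing N are excluded from genome
building but still aligned.

## The RRBS simulator

The simulator is the package's ground-truth generator, not a test fixture:
it emulates the parts of the assay the analysis depends on and nothing
else.

* **Genome.** A first-order chain with configurable GC fraction (default
  0.5) in which the C→G transition probability is multiplied by a CpG
  enrichment factor (default 8). This produces the CpG-island-like
  clustering of MspI sites that gives RRBS its short-fragment peak; with
  these defaults the mean MspI fragment is ≈ 200 bp, so a 40–220 bp size
  window retains a realistic fraction of the digest.
* **Digest and library.** In-silico digestion cuts at every CCGG (cut after
  the first C; TaqI T^CGA selectable); fragments tile the genome exactly.
  Library molecules model the staggered cut plus end-repair fill-in: an
  internal fragment [i, j) yields the molecule genome[i : j+2], which
  starts CGG and ends CCG on both strands — the termini that strand merging
  keys on. Chromosome-terminal fragments lack a ligatable MspI end and
  yield no molecules.
* **Methylation and conversion.** Per (duplex, CpG), methylation is drawn
  Bernoulli(m) from the per-group truth and shared by both strands of that
  duplex. A methylated C survives conversion except with probability
  `overconversion_rate`; an unmethylated C converts with probability
  `conversion_rate`; non-CpG Cs are always unmethylated. By default each
  read samples a fresh duplex on a random strand — after bisulfite
  conversion the two strands are independent library molecules, so
  re-observing a duplex is rare at realistic depth — giving `depth`
  independent observations per fragment. `paired_strands=True` instead
  emits one read per strand per duplex, which makes the shared Bernoulli
  states observable and is what the strand-merging reconstruction tests
  use. Sequencing errors are uniform per base after conversion.
* **Spike-ins.** Fully methylated / fully unmethylated control oligos
  (synthetic sequences defined in `simulate.py`) at a default 0.1% mass
  fraction measure under- and over-conversion independently of the genome.
* **Not modeled:** PCR duplicates, adapter read-through chimeras,
  position-dependent quality profiles, end-repair fill-in cytosines
  (positions are emitted from the genomic strand directly). Consequently,
  passing tests demonstrate correctness of the algorithms under clean
  molecular assumptions, not robustness to every wet-lab artifact.

## Deduced-genome construction

The six-step builder follows the printed thresholds exactly, all
user-overridable via `BuilderParams`:

| parameter | default | boundary semantics |
|---|---|---|
| min_multiplicity | 2 | keep keys with ≥ 2 representatives |
| c_call_threshold | 0.05 | C restored at fraction ≥ 0.05 |
| merge_threshold | 0.08 | merge at mismatch ratio < 0.08 |
| refine_threshold | 0.05 | split at mismatch ratio > 0.05 |
| spacer_length | 50 | exactly 50 Ns between fragments |

Design choices where the procedure was genuinely open:

* **Multiplicity counting.** "Occurs at least twice across samples" is
  implemented as: deduplicate exactly identical reads within each sample,
  then count (sample, distinct unconverted sequence) representatives per
  converted key. Copy counts survive as weights for the 5% C-restoration
  rule, which therefore counts read copies, not distinct sequences.
* **Similarity model.** Mismatch ratios are ungapped, anchored at position
  0 (both sequences start at an MspI cut) and use the shorter length as
  denominator, so a read that is a strict prefix of a longer fragment can
  join its cluster. This mirrors the double-counting tolerance of partially
  overlapping fragments; the bias is bounded by the cluster sizes involved.
* **Tie-breaking.** Clustering processes pre-consensus sequences in
  descending member count (ties: lexicographic converted key) and joins the
  largest eligible group (ties: lexicographically smallest seed). All ties
  are deterministic, so the builder is a pure function of its input multiset.
* **Group consensus length** is the longest member's length; each position
  is decided by the members covering it (weighted majority on the converted
  frame, then C restoration).
* **Canonical orientation.** A strand-merged fragment represents both
  strands, so its orientation is arbitrary; we emit the lexicographically
  smaller of the merged sequence and its reverse complement. This makes the
  builder idempotent: rebuilding from reads generated off its own output
  reproduces the same fragment set byte for byte, which no orientation
  convention tied to the greedy merge order can guarantee.
* **Refinement termination** is guaranteed by a 100-iteration cap with
  diagnostics; in practice convergence takes one or two passes because each
  split strictly shrinks a group.

A consequence worth knowing: a genomic cytosine unmethylated in every
sample is represented as T unless an opposite-strand read covers it (the
complementary G is conversion-proof and strand merging restores the C).
Fragments short enough to be spanned by reads from both strands therefore
come back with their full cytosine complement; longer fragments lose
all-sample-unmethylated Cs in their single-strand regions.

## Bisulfite alignment

Exact 16-mer seeds are taken at every read offset on the two converted
frames (C→T for forward, G→A applied to the reverse complement for
reverse hits), fragments are indexed individually (alignments can never
cross a spacer), and every candidate diagonal is verified with the
asymmetric rule: genomic C matches read T for free, genomic T read as C is
an error; mirrored on the other strand. Ungapped alignment is appropriate
because reads and deduced fragments derive from the same molecules — an
indel in one is an indel in both. The mismatch ceiling defaults to 8%
(≤ 4 mismatches in a 50-mer). Ambiguous best hits follow
`multimap_policy`: `random-best` (default) picks uniformly with the seeded
generator, mimicking random single-hit assignment in repetitive families;
`best-unique` reports nothing. The seeded choice makes alignment
reproducible; `mapq_proxy` (second-best minus best mismatch count) lets
downstream users filter ambiguous placements. With ≤ 4 mismatches and
seeds at all 35 offsets of a 50-mer, at least one seed is clean whenever
the mismatches leave any 16-mer untouched; in the error regimes simulated
(≤ 1%) missed alignments are not observed.

## Methylation calling

One site per CpG: forward reads contribute C/T at the cytosine, reverse
reads contribute G/A at the paired guanine, any other base is ambiguous and
counts toward neither tally. Duplicate reads are not removed — RRBS
fragments legitimately share MspI-defined start positions, so
deduplication would discard real coverage. Non-CpG contexts (CHG/CHH) are
callable from forward-strand evidence; note that on a deduced genome,
non-CpG "methylation levels" at retained Cs reflect conversion failure,
because ubiquitously unmethylated Cs are simply absent from the deduced
sequence — non-CpG rates on a deduced genome are not a valid conversion
control, which is exactly what the spike-ins are for. Coverage filtering
keeps sites with 8–200 reads inclusive; below 8 the binomial noise on β
dominates, above 200 the site is suspect (collapsed repeats, spike-in
carry-over).

## Differential methylation

The site test is a two-group linear model with empirical-Bayes variance
moderation. Hyperparameters (d₀, s₀²) are estimated by moment matching on
log variances: with e = log s² − ψ(d/2) + log(d/2), solve
ψ′(d₀/2) = var(e) − mean(ψ′(d/2)) by Newton inversion of the trigamma
function, and s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). When the observed
dispersion does not exceed sampling noise, d₀ = ∞ and s₀² is the arithmetic
mean variance; total degrees of freedom are capped at the pooled residual
df. The implementation agrees with the Bioconductor limma reference to
~1e-15 on both branches (asserted in the test suite via Rscript), and with
d₀ forced to 0 it reduces exactly to the textbook pooled t.

Moderated-t p-values on β values at 4+4 samples are approximate (β is a
bounded proportion, not Gaussian), but the all-null calibration test shows
the type-I error within 3 binomial SEs of nominal at coverage 30.

Fragment p-values combine the BH-adjusted site p-values with
K = Σ wᵢ(−2 ln pᵢ), weights proportional to site coverage and normalized;
the null is a scaled χ² matched to mean 2 and variance 4 Σ wᵢ² (equal
weights recover Fisher's statistic exactly). Zero p-values are clamped to
the smallest positive float. Ranking is competition-style ("1, 2, 2, 4")
per measure — p ascending, |log₂ fold change| descending (ε = 0.01 guards
log 0), |Δβ| descending — and the fragment's rank is the worst of the
three, so a fragment must do well on significance *and* both effect-size
scales. Final ties break by combined p then fragment id. Ranking uses the
combined p computed from adjusted site p-values, matching the stated order
of operations (adjust sites first, then combine).

## Motif enrichment

Average-odds scoring multiplies position odds (motif frequency /
background frequency) over motif positions and averages over all offsets
of both strands; N bases contribute a neutral factor 1, sequences shorter
than the motif are excluded. The odds background is the order-0
composition of the union of both input sets. The rank-sum test is exact
for tie-free samples up to n = 20 per side, else the tie-corrected normal
approximation (they agree within 0.02 at the crossover, asserted).

The shuffle control fits order-0 and order-1 Markov models to each set
(order-1 contexts never observed fall back to uniform) and regenerates
matched sets — matched in count and in each sequence's length — for 50
iterations per order, pooled (100 runs) when applying the thresholds:
artifact if significant in > 60% of shuffled-vs-shuffled runs, shared
enrichment if significant against the foreground's own shuffles in ≥ 95%
of runs (the least significant p across iterations is reported). Both
thresholds are exposed in `ShuffleParams`. One calibration fact the tests
make explicit: under a true null the familywise BH hit rate per rerun is
~5%, so "zero significant motifs" holds in ~95% of reruns by construction
— the null-calibration check therefore allows 3 binomial SEs around that
95% rather than demanding it of every finite sample.

## Pipeline, determinism, problem sizes

The orchestrator writes every stage's outputs as plain text with a JSON
manifest of config and per-stage input checksums; with `resume`, a stage
whose checksum matches reloads its outputs instead of recomputing, so
changing the coverage filter re-executes only call-onward stages.
All randomness derives from the single config seed; alignment may be
partitioned across threads by sample, and results are merged in sample
order, so serial and parallel runs are byte-identical — asserted, along
with rerun determinism, in the test suite.

Tests and the acceptance script run at desk scale, chosen so the full
suite completes in about a minute while every statistical check retains
power: 60–100 kb genomes (a few hundred MspI fragments; reconstruction and
recovery checks use a 30–50 bp size window so reads span whole fragments
from both strands), depth 30, 4 samples per group, 1000 sites/fragments
for the calibration and planted-signal checks, 100-sequence motif sets
with 4-motif libraries. At these sizes the methylation-recovery
correlation is r ≈ 0.97 (the binomial expectation at 30 independent
observations per site against a Uniform(0,1) truth), planted-DMR recall is
100/50 planted at Δβ = 0.4, and the GC-skew construction reproduces the
composition-artifact flagging.

## Known limitations

* No de novo assembly: partially overlapping fragments may double-count a
  CpG; highly similar repeats collapse into one consensus (by design — the
  consensus view of a repeat family is often preferable to random
  multi-mapping, but it changes the interpretation of those fragments).
* Two-group designs only; no covariates, paired designs or beta-binomial
  count models.
* Gaussian moderated t on proportions is approximate at very low coverage
  or extreme β; the coverage filter is the guard.
* Single-end reads; no BAM/SAM emission (internal alignment tables are
  written as TSV).
* Motif analysis reports enrichment, not binding: a differential motif is
  a hypothesis about the factor, nothing more.
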