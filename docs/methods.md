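# Methods

This note records the models, parameter choices and numerical decisions
behind seqclip, and what the synthetic benchmark does and does not show.

## Alignment model

Adapter detection is ungapped semiglobal alignment: every relative
placement (diagonal) of the two sequences is scored with +1 per matching
base, −1 per mismatch and 0 at positions where either base is N. N
positions count toward the aligned length but never toward the mismatch
tally, and since they contribute no score they cannot by themselves
drive a placement past the positive-score acceptance rule. Gaps are not
modelled; indels are far rarer than substitutions in Illumina data, and
an ungapped scan keeps every placement independently scoreable.

Mismatch allowance as a function of aligned length *L*:

| *L* | allowance |
|-----|-----------|
| ≤ 5 | 0 |
| 6–10 | 1 |
| > 10 | ⌊rate · *L*⌋, rate 0.33 (single-end) / 0.15 (paired-end) |

The fraction is floored (a conservative reading consistent with the
perfect-match rule at the 5-nt boundary, and monotone in *L*). A small
epsilon (1e−9) guards the floor against binary representation of the
rate. Acceptance requires, beyond the allowance, a strictly positive
score: a non-positive score means mismatches plus Ns outweigh matches,
i.e. no evidence. Ties between accepted placements prefer the higher
score, then the longer aligned length (equal score over a longer overlap
means proportionally consistent evidence and less residual adapter),
then the smaller offset (more conservative toward removing
contamination). Reported offsets are read coordinates: the position of
the second sequence's first base relative to the first sequence's first
base, negative values reaching before its start.

All diagonals are scored at once by cross-correlating one-hot base
indicators (four base channels plus a non-N channel), which is the
banded dynamic-programming matrix evaluated as a handful of vectorised
passes. The normative contract is exact equivalence with brute-force
offset enumeration under the scoring scheme; the test suite verifies
this against an independent oracle on 10^4 random instances.

### Single-end

The adapter's first base is placed at read positions `-S … len(read)-1`
(default shift `S = 2`); adapter bases falling before the read start are
ignored, since they were never sequenced. On acceptance the read is cut
at the placement start. Single-end evidence is weak for short fragments
— a terminal base matching the adapter's first base is a valid length-1
alignment — so single-end trimming inevitably trades false positives
for sensitivity; this trade-off is intrinsic to the model, not a tuning
artifact, and is quantified by the benchmark.

### Paired-end

Read 1 is aligned against the reverse complement of read 2. Two passes
are made:

1. **Adapter-context pass.** The reverse complement of adapter 2 is
   prepended to read 1 and adapter 1 is appended to the reverse
   complement of read 2. At the true placement of a contaminated pair
   each mate's adapter fragment then aligns against the known adapter
   sequence, so the aligned length is roughly `L_I + 2·L_A` (truncated
   by the adapter lengths): a single contaminating base is detected with
   an entire read's worth of support, and a placement that would falsely
   imply contamination must survive the 15 % allowance over ~75+
   positions of unrelated sequence — chance acceptance is effectively
   impossible. Placements down to an implied insert length of zero
   (pure-adapter pairs) are admitted.
2. **Plain pass.** The rigid context junction breaks when a mate lost
   bases from its 5' end (the context lands a few positions early and
   the adapter compared against itself at a small lag floods the
   allowance). A plain read-vs-read pass covers this case. Because
   unrelated 75-nt reads routinely share chance micro-overlaps (a
   single matching terminal base has probability 1/4), the plain pass
   only accepts placements of at least `plain_min_overlap` (default 20)
   aligned bases, putting chance acceptance near 10^−6 per pair.

The better accepted placement of the two passes — by score, then
aligned length, then smaller offset — wins. An accepted placement fixes
the insert length `L_I = len(read2) + offset`; if `L_I` is shorter than
a read, both mates are cut to `L_I` (contamination is symmetric across a
pair absent indels); otherwise the mates merely overlap and may be
collapsed.

## Trimming chain

Per read or pair: optional 5' adapter removal, 3' adapter
identification, optional collapse, N-trimming, quality-trimming,
filters. Adapter location is defined on raw read coordinates, so end
trimming never precedes it. Each output is a contiguous substring of the
input with identically sliced qualities; every step is deterministic.

* 5' adapters are expected in near-full length: for each slip
  `k = 0 … 2` the adapter minus its first `k` bases is compared against
  the read prefix (slipped bases do not count as mismatches); the first
  comparison with ≤ 1 mismatch wins. The remaining adapter must fit
  entirely within the read.
* N- and quality-trimming remove maximal terminal runs (quality
  threshold default 2, i.e. scores ≤ 2 go); interior positions are kept,
  and each runs once (both operations are idempotent).
* Filters: optional maximum N count (off by default — deferred to the
  user), then minimum length (default 15). Zero-length reads are valid
  intermediates and always fail the length filter.

## Pair merging

The overlap is treated as a position-specific scoring matrix. A base
call with quality *Q* becomes a distribution assigning `1 − Pe` to the
called base and `Pe/3` to each alternative (`Pe = 10^(−Q/10)`); an N is
the uniform distribution (and so the multiplicative identity). Per
overlap position the two distributions are multiplied and renormalised —
the standard likelihood combination — the argmax becomes the consensus,
and its posterior error `1 − p_max` is converted back to a Phred score,
rounded half-up.

Numerical and policy choices:

* Re-estimated qualities are capped at 41. Two agreeing Q40 bases imply
  an uncapped score near 80, which downstream tools neither expect nor
  can encode in common Phred+33 conventions.
* Exact posterior ties (equal qualities, different bases; or two Ns)
  emit N with quality 0 — there is no principled basis to prefer either
  observation. Ties are detected with a 1e−9 relative tolerance.
* Merging is refused below 11 doubly-observed positions (`min_overlap`,
  counting only the re-estimated overlap, not singly-covered flanks);
  refusal is a normal outcome and the pair is emitted as ordinary
  trimmed reads. A consensus that would fail the post-merge filters is
  likewise treated as a refusal, keeping the read accounting exact.
* The consensus spans exactly the inferred insert: singly-covered flanks
  are copied verbatim, positions read past the insert (adapter bases)
  are dropped. Merged reads carry mate 1's identifier behind an `M_`
  prefix.
* The agreement property — combining two identical calls never increases
  the error probability — holds for input qualities ≥ 2 (the Illumina
  floor). Below that the model itself degenerates: `Pe > 3/4` makes the
  called base less likely than each alternative, so a Q0/Q1 "agreement"
  is, under the model, evidence against the call. The float combination
  matches a 60-digit decimal oracle to 1e−9 before rounding.

## Pipeline

Processing is streaming — one read or pair in memory at a time — and
deterministic: identical inputs and flags give byte-identical outputs.
Surviving pairs keep their input order across the mate-1/mate-2 files;
if exactly one mate survives the filters it becomes a singleton, kept
because half a pair is still useful data. Every run satisfies
`reads_in = mate1 + mate2 + singleton + discarded + 2·collapsed_pairs`.
Only strict 4-line FASTQ is accepted (wrapped FASTQ does not occur in
modern sequencer output); bases outside ACGTN are normalised to N with a
warning rather than rejected, since real files contain stray characters;
gzip is detected by magic bytes. Output quality encoding follows the
input encoding.

## Synthetic benchmark

The simulator emulates the construction of a truth-annotated 75-nt
paired-end test set. Per pair an insert length is drawn uniformly on the
closed interval [0, 200] (expected contaminated fraction 75/201) and the
pair is built by three rules: unchanged when `L_I ≥ 150`; for
`75 ≤ L_I < 150` the overlapping subsequence is copied from read 1 into
read 2's 3' end (reverse-complemented) and the newly written bases are
mutated per read 2's qualities; for `L_I < 75` both mates get the insert
plus adapter sequence from two different adapters, and the whole
rebuilt reads are mutated per their qualities. Substitution probability
per base is `Pe = 10^(−Q/10)` with a uniform choice among the three
other bases; no indels are simulated.

Base reads are uniform random sequence; qualities come from a
per-position Gaussian model whose mean declines from 38 at the first
cycle to 25 at the last along a mildly convex curve (sd 5, clamped to
[2, 41]), emulating the familiar 3' degradation of Illumina quality.
Real base reads were derived from a genuine bacterial sequencing run;
the synthetic stand-in preserves what that data contributed to the
benchmark — read length, random-sequence inserts, and a realistic
error-rate profile — but not the genome's composition or the empirical
quality distribution. Absolute benchmark rates under the synthetic
model are therefore cleaner than published ones (paired-end sensitivity
here approaches 1.0 versus 0.93 on the noisier real-quality data);
structural results — zero over-trimming, near-zero false positives in
paired mode, exact recovery without errors — carry over and are what
the acceptance checks assert. Where the insert-plus-adapter construct
is shorter than the read, the remainder is filled with random
off-template bases (a sequencer reading past the construct); the fill
counts as contamination in the truth and the alignment geometry keeps it
outside every true overlap.

Outcomes are classified per mate by bases removed versus the true
adapter length (exact / more / less / missed / clean-trimmed /
clean-untouched) and mapped to TP/FP/FN/TN as: TP = exact,
FP = clean-trimmed + more, FN = less + missed, TN = clean-untouched.
PPV, sensitivity, specificity and MCC follow; zero-denominator metrics
are reported as undefined rather than forced to a number. Matching the
published protocol, benchmark runs trim adapters only (no N/quality
trimming or length filtering). Headline counts are reported for mate 1,
with mate-2 counts also available, since tools may treat mates
asymmetrically.

Problem sizes: the acceptance checks use 10^6 draws for the composition
check, 50,000 pairs for the paired benchmark, 4,000 error-free pairs for
the recovery property and 10^4 instances for oracle equivalence — sizes
at which the binomial error bands quoted in the tests are meaningful on
a single CPU.

## Known limitations

* One adapter per end; no adapter lists or mixed-library demultiplexing.
* No gapped alignment: an indel inside the insert breaks the symmetric
  trimming assumption (such pairs usually fail the allowance and are
  left untrimmed rather than mis-trimmed).
* Single-end mode's false-positive/sensitivity trade-off is inherent to
  aligning against a short 3' fragment; quality-aware scoring might
  improve it and is out of scope.
* The quality model is Gaussian per position with fixed parameters; real
  instruments show batch effects, cycle spikes and quality-sequence
  correlations it does not attempt to mimic.
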