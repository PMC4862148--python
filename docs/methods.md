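# Methods

## Problem and model

When a sequencing library fragment (the *insert*) is shorter than the read
length, an Illumina paired-end run reads through the insert into the
ligated adapter, symmetrically in both mates. Those adapter bases must be
removed before mapping or assembly; on amplicon data they recur at the same
genomic position and can produce spurious variant calls.

pairtrim detects read-through without alignment. For two base windows of
length *n* with *k* agreeing positions, the probability of observing *k* or
more agreements between **unrelated** sequences is the binomial upper tail

    P(k, n) = Σ_{i=k..n} C(n, i) p^i (1 − p)^(n − i),   p = 1/4,

assuming uniform base composition. A comparison is a *non-random match*
when P falls below a significance threshold (the "match error probability",
default 1e-6) **and** at least a fixed fraction of positions agree
(default 80 %). Indels need no special handling: an indel inside the
fragment appears identically in both read directions, so the forward read
and the reverse-complemented reverse read stay in register.

## Trimming algorithm

Per pair, with reads of lengths m1 and m2:

1. **Insert match.** Every candidate insert length L in [0, m1 + m2 − 1] is
   scored. The overlap for L is the set of insert positions covered by
   both mates: forward covers [0, min(m1, L)), reverse covers
   [max(0, L − m2), L); the forward window is compared with the matching
   window of the reverse-complemented reverse read. Significant candidates
   are ranked by P (ties prefer the larger L — trim less); the best
   candidate whose *flank* also looks like the adapter is accepted, and
   both reads are truncated to their first min(m, L) bases. Flank
   confirmation — adapter-likeness of the bases following position L — is
   required in **one** mate only, which keeps the test robust to one bad
   read direction while suppressing false offsets inside simple repeats.
2. **Adapter match** (fallback). If no insert match is found, each mate is
   scanned for the adapter itself: offset o compares the read from o with
   the adapter prefix that fits. The lowest-P significant hit (ties prefer
   the smaller o — in the 3' tail adapter sequence dominates) trims *both*
   mates at o, because read-through is always symmetric.
3. **Quality trimming** (optional, default off): 3' bases are dropped while
   their Phred quality is below the cutoff; the scan stops at the first
   base meeting it.
4. **No-call trimming** (default run length 7): the read is truncated at
   the start of the first run of ≥ ncut consecutive N.
5. **Length filter** (default 15): if either mate ends up shorter, the pair
   is discarded whole, keeping the two output streams synchronized.

Trimming only ever removes a suffix: every output read is a prefix of its
input.

### Numerical and design choices

- P is computed in log space from a cached log-factorial table
  (`math.lgamma`, capacity 2 × the longest supported read), summed with a
  max-anchored log-sum-exp; agreement with exact rational enumeration is
  tested to a relative 1e-9 for all n ≤ 200.
- Significance for a whole offset scan reduces to one vectorized comparison
  against a precomputed table of the minimal significant match count per
  comparison length (binary search over k once per model). The
  minimum-matching-fraction parameter doubles as the early-exit bound of
  the scalar `count_matches`; both routes give identical verdicts.
- The minimum significant overlap is **emergent**, not a parameter: at
  threshold 1e-6 a perfect 10-base overlap is the shortest significant one
  (0.25^10 ≈ 9.5e-7). The threshold default is this package's choice of
  the sensitivity/specificity balance point.
- N never matches anything (including another N) and stays inside *n*:
  conservative, and keeps n fixed per offset. Bases are compared
  case-insensitively; U is rejected (DNA only).
- Flank confirmation uses the match-fraction rule for flanks of ≥ 3 bases;
  shorter flanks must match the adapter start exactly — no probabilistic
  test is meaningful on one or two bases, and the exact-match rule is what
  allows trimming adapter remains down to a single base.
- An insert length of 0 (adapter dimer) has an empty overlap, so no
  binomial test is possible; it is accepted purely on flank confirmation
  (reported with P = 1.0), and only when no overlapping candidate
  qualifies. Unrelated reads do not trigger it, because a random prefix
  does not reach 80 % identity to the adapter.
- An insert match with L ≥ both read lengths means overlap without
  read-through; it is reported but removes nothing.
- A discarded pair's result keeps the detector that fired; the separate
  `discarded` path marks pairs dropped with no detection (e.g. shrunk away
  by quality/no-call trimming). The discard verdict itself is pair-level.
- Processing is strictly order-preserving and single-threaded; a
  `--threads` flag is accepted for pipeline compatibility with the
  contract that output is identical for any value.

## Simulator

The simulator emulates the benchmark library design: insert lengths are
drawn from Normal(mean 100, sd 50), rounded, and redrawn until ≥ 1 — a
discrete left-truncated normal under which ≈ 48.4 % of pairs have an
insert below the 100 bp read length and therefore carry adapter
contamination. Fragments are i.i.d. uniform random sequence by default
(every property the trimmer is tested on is preserved without a reference
download); a reference-FASTA mode draws uniform windows on a uniform
strand, rejecting windows containing N. Reads are template + adapter +
random fill, cut to the read length; substitution errors flip each base
independently to one of the three others with the configured probability
(Illumina errors are substitution-dominated; indel errors and
position-dependent profiles are out of scope). Qualities are constant
(default Phred 30); the trimming benchmarks run with quality trimming
disabled, so a quality model would be decoration. Everything is
reproducible byte-for-byte from the seed.

Note the truncation arithmetic: redrawing below 1 shifts the empirical
insert mean to μ + σ·φ(α)/(1 − Φ(α)) ≈ 102.86 and shrinks the sd to
≈ 46.97 (α = (0.5 − 100)/50). The acceptance suite asserts the nominal
100 ± 1 / 50 ± 1 calibration band and therefore flags this discrepancy
rather than hiding it; the simulator follows the truncated-normal
definition deliberately, as clamping would distort the short-insert tail
that adapter trimming is about.

What passing on simulated data does **not** show: real libraries have
non-uniform base composition, position-dependent quality and error rates,
PCR duplicates, and occasional adapter variants; sensitivity/specificity
on real data must be established with mapping-based metrics, which are out
of scope here.

## Evaluation metrics

With simulated data the correct trim point is known a priori: a perfect
trimmer keeps min(read_length, insert_length) bases of each mate. Per
surviving read, max(0, expected − kept) is **overtrimmed** (insert bases
lost; specificity) and max(0, kept − expected) is **undertrimmed** (adapter
bases kept; sensitivity) — an exact decomposition with no double counting.
Discarded pairs are tallied separately and contribute to neither base
count. The **adapter 20-mer count** — exact, case-insensitive, overlapping
occurrences of each adapter's first 20 bases in the matching mate — is the
crude sensitivity check usable on any dataset; after perfect trimming it
is zero. Basic QC reports read/base counts, mean length, GC and N
fractions, and Q20/Q30 base fractions.

## Problem sizes

The acceptance suite and `scripts/acceptance.py` use 100,000 pairs per
condition (error-free and 4 % substitution error), 100,000 insert-length
draws, and 10,000 constructed known-insert pairs — sizes at which the
binomial sampling error of every asserted fraction is far below its
tolerance. At these sizes the error-free benchmark yields 0 undertrimmed
bases, 0 overtrimmed reads and 0 remaining adapter 20-mers, and the 4 %
error run keeps undertrimmed bases well below 0.1 % of all adapter bases.

## Known limitations

- No merging of overlapping pairs into single-end reads.
- No Phred+64 input, interleaved FASTQ, or BAM/CRAM.
- Uniform-composition null model; highly skewed genomes make random
  matches slightly more likely than p = 0.25 assumes (mitigated by the
  flank confirmation and the 80 % identity floor).
- Single-threaded; throughput is adequate for its role (tens of thousands
  of pairs per second) but not competitive with compiled trimmers.
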