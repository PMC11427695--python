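# Methods

## Matching model

A read's observed indices are compared with the expected sample indices by
hamming distance — substitution errors only, no indels, no use of base
qualities. This mirrors the behaviour of the standard vendor demultiplexers:
conservative, exact, and order-independent. Indels are excluded on purpose;
an indel inside the barcode region would shift the frame of every following
segment, so positional matching is the model, not an approximation of it.

Budgets are per index: `m7` mismatches allowed in i7 and `m5` in i5
(defaults 1 and 1 — index error rates on these platforms are low, and
raising the budget degrades separability faster than it recovers reads).
The verdict for a read is:

- **sample** — a unique sample attains the minimal total distance d7 + d5
  with d7 ≤ m7 and d5 ≤ m5;
- **ambiguous** — two or more samples tie at that minimal total distance
  (the tie is on the total; the (d7, d5) decomposition is not compared);
- **undetermined** — no sample is within budget.

An `N` in the observed index is an ordinary mismatch character: it costs one
unit of budget against any expected base. Expected indices themselves must
be over {A,C,G,T}.

## The lookup table

For each sample-sheet index the full hamming ball of radius `m` is
enumerated: each of the C(L,k) position subsets, each position substituted
by one of the 4 characters of {A,C,G,T,N} it is not, giving
Σ_{k≤m} C(L,k)·4^k variants. Dual-index keys are the concatenation of an i7
variant and an i5 variant, so one dictionary fetch resolves both indices.
Collisions across samples keep only the minimal-total-distance sample(s);
an equal-distance collision is stored as an ambiguous entry.

Two non-obvious choices:

- **Index diversity.** A sample may appear under several index pairs. A key
  equidistant from two index pairs *of the same sample* is not an ambiguity
  — the table collapses tied records to one per distinct sample id, so the
  read still routes to its sample.
- **Memory guard.** The expansion is exponential in `m`. Building refuses
  when the predicted key count exceeds a cap (default 5·10⁷) with an error
  suggesting a smaller budget, rather than exhausting memory silently.

The table is validated two independent ways in the test suite: exhaustively
(every string over {A,C,G,T,N}⁴ against a small sheet, compared with a
naive per-record minimum-distance scan) and statistically (10,000 simulated
noisy reads at m ∈ {0,1,2} against the same naive oracle).

## Barcode templates and auto-detection

A template is an ordered list of segments (i7 / i5 / umi), each with a
length and, for index segments, a reverse-complement flag; the barcode
region is the last `barcode_length` bases of the barcode-bearing read
(R2 for paired-end, R1 for single-end). Spec strings look like
`i5rc.8:i7.8:um.8`.

Detection enumerates all candidates consistent with the index lengths and
the barcode length: both index orders, all 2–4 reverse-complement
combinations, and — when the barcode exceeds the summed index lengths — a
single contiguous UMI occupying the whole remainder in any gap (before,
between, or after the indices). Multi-gap UMIs are not modelled; the single
contiguous UMI covers all layout families seen in practice. Candidates are
scored by **exact** (0-mismatch) matches of the extracted (i7, i5) against
the sample sheet over the first `limit` reads (default 5,000 — ample signal
at trivial cost), ranked by matches with ties broken by the lexicographic
order of the spec string, all ties reported. Exact-only scoring is the
conservative reading of "maximum matches": allowing mismatches during
detection would blur layouts that differ by a few positions. A warning is
issued when even the best candidate matches under half of the sampled reads.

The barcode-region length comes from, in order: the read length minus a
declared biological read length; an explicit `--barcode-length`; else the
summed sample-sheet index lengths (no UMI assumed).

Mixed libraries: per-record `template` overrides in the sample sheet
partition it into template groups, each with its own extraction and lookup
table. A read is claimed by the unique group returning a sample verdict;
sample verdicts from two or more groups make it ambiguous; otherwise it is
ambiguous if any group said ambiguous, else undetermined.

## Output dialects

- **Illumina**: files `<sample>_S<n>_L<lane:03d>_R<mate>_001.fastq.gz`
  (`Undetermined` is S0), headers
  `@<fc>:1:<fc>:<lane>:<tile>:<x>:<y>[:<umi>] <mate>:N:0:<i7>[+<i5>]` with
  tile = column·1000 + row, x = serial, y = 1 — a deterministic, invertible
  mapping from the MGI coordinates; downstream tools need only the
  syntactic form.
- **MGI**: files `<fc>_L<lane:02d>_<sample>_<mate>.fq.gz`, original headers
  kept verbatim; a UMI is appended to the read id after `#`.

The barcode is trimmed from the barcode-bearing mate only; the UMI is
written into both mates' headers (verdicts and UMIs are properties of the
fragment, not of one mate). Ambiguous reads are written to the Undetermined
files by default but counted separately; `--separate-ambiguous` routes them
to their own files. Input order is preserved in every output file. Output
is buffered and flushed in compressed chunks (default 8 MiB buffer);
outputs are byte-valid gzip regardless of flush points, with a pinned gzip
mtime so identical content gives identical bytes. Phred+33 throughout.

Lane handling: the lane is read from the MGI headers; a file mixing lanes
is rejected unless `--lane` forces a label, because reports are per-lane.

## Reports

Per lane and sample: read count, a histogram of total index mismatches
(0..m7+m5), and Q30 / total base counts over the **trimmed biological**
bases only. Per lane: undetermined and ambiguous counts, a tally of
undetermined barcodes (top 50 written to TSV, count-descending, ties
lexicographic), and per-cycle mean Phred per mate. The quality metric set
(Q30%, per-cycle means, mismatch histogram) is this package's chosen
schema. Percentages are rounded to two decimals in files; full precision is
kept internally.

Serialization is two TSVs plus one JSON; the JSON carries the complete
accumulators (full undetermined tally, per-cycle quality sums and base
counts), which makes file-based merging lossless: counts add as integers
and per-cycle means recombine as base-count-weighted averages. Merging is
associative and commutative on all counters and rejects inputs whose sample
sets differ.

## Simulator

The simulator emulates what matters to demultiplexing: MGI headers
(shared grammar with the parser), any template layout, per-index
substitution errors, random UMIs, decoy reads with fully random barcodes,
multiple lanes, and a truth table (serial → true sample, injected d7/d5,
UMI). Defaults: 4 samples, 8 bp dual index drawn at pairwise distance ≥ 3,
8 bp UMI, 1,000 reads per sample, 100 bp biological reads, no errors.

Error model: per index segment the number of substituted positions is
Binomial(L, rate), optionally capped by `max_errors_per_index` (the cap
expresses "at most one error per index" study conditions exactly);
substituted bases are uniform over the four alternatives including N. The
injected counts are recorded in the truth table and equal the hamming
distance between emitted and true index by construction (verified by
recomputation in the tests). UMI bases are uniform random, so substitution
there would be distribution-equivalent and is not modelled. Biological
bases are uniform random — content is irrelevant to demultiplexing — and
qualities come from a two-state Q40/Q12 mixture (85% Q40) so Q30 statistics
are non-degenerate.

What the simulator does **not** emulate, and hence what passing tests do
not show about real data: cycle-dependent error profiles, indels, quality
correlation with errors, optical/PCR duplicates, adapter read-through, and
real index-set designs. The validation demonstrates correctness of the
matching and bookkeeping machinery, not robustness to error modes outside
the hamming model.

## Numerical / degenerate-input choices

- Index comparison is case-insensitive (indices upper-cased on parse).
- A read exactly as long as the barcode trims to an empty biological
  sequence; that is legal and the empty record is still written.
- Distance-0 keys can never be ambiguous (duplicate (i7, i5) pairs within a
  template group are rejected at parse time).
- Ambiguous entries report the lexicographically smallest (d7, d5)
  decomposition of the shared total distance.
- Determinism: the only randomness in the package is the simulator's,
  driven by one integer seed through a single generator.

## Problem sizes used in validation

The bundled validation runs use 10,000 reads for the lookup-vs-brute-force
comparison, 4 × 5,000 paired reads for ground-truth recovery, 1,000 reads
per layout for template detection, and two 1,500-read lanes for merge
consistency — sizes chosen to exercise every code path with comfortable
statistical margin while keeping the suite quick to run.
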