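# Methods

## Model

A read architecture is an ordered list of segments; exactly one is the
variable-length mappable read.  Compilation to the global scoring model
proceeds per segment:

* **Fixed-sequence segments** (spacers, barcodes, fingerprints, adapters)
  become linear chains of match states between a silent entry and exit
  state.  A match state for base `X` emits `X` with probability
  `1 − 3·base_error` and each other base with `base_error`; fingerprint
  (`N`) positions and the background chain emit the zero-order background
  frequencies.  For chains of length ≥ 2, insert states (emitting
  background, self-transition `indel_extend`) sit between match columns
  and silent delete states allow skipping columns, both entered with
  probability `indel_open`.  Deletions begin at chain position 2: all
  entry mass flows through the first match state, which makes the
  barcode chain-entry posteriors a proper distribution over chains (they
  sum to 1 whenever every path must traverse the barcode segment).
  A whole 1-nt segment can therefore not be deleted; in practice a
  deletion inside any same-base run is equivalent to deleting its first
  base, so this costs nothing for fingerprint runs.
* **Barcode segments** hold one chain per declared alternative plus one
  background chain of the same length emitting background frequencies,
  all sharing the entry/exit silent states with uniform entry weights
  `1/(n_alternatives + 1)`.  Reads whose barcode region is best explained
  by the background chain are rejected as ambiguous instead of being
  forced onto the nearest barcode.
* **The read segment** is a single match column emitting background
  frequencies with a self-looping insert state — a geometric length
  prior.  The self-loop probability is `1 − 1/E` with expected body
  length `E` (default 1000), i.e. nearly flat over realistic read
  lengths so the prior does not dominate the likelihood.
* **Partial adapters** allow truncated occurrences: 90% of the entry mass
  enters at column 1 and 10% is spread over the later columns (5'
  truncation); every column may exit with probability 0.1 (3'
  truncation); the whole segment may be absent with probability 0.02.
  These weights are design constants, not fitted quantities; results are
  insensitive to them because adapters contribute through many matched
  positions.

Segments are concatenated through their silent connectors into one model
with a single start and end state.  States are created in topological
order (silent-to-silent transitions only go forward), so the forward and
backward sweeps resolve silent chains with one in-order pass per read
position.  All dynamic programming is in natural-log space with
log-sum-exp accumulation; `-inf` marks impossible events.  Reads are
scored whole — the model is global, which is what lets primer dimers and
other junk fail loudly instead of partially matching.

## Scoring and decoding

For read `x`: `P(x|M)` comes from the forward algorithm, `P(x|R)` from
the zero-order background model (estimated from the first 100,000 input
reads; uniform fallback).  The barcode confidence `V` is the posterior
mass of the winning chain's silent-entry → first-match transition summed
over all read positions (computed from the forward and backward
matrices); without barcode segments `V = 1`.  With several barcode
segments, per-segment maxima multiply and the call is the tuple of
winners — an extension beyond the single-segment designs exercised by
the benchmarks.  Ties between barcode alternatives resolve to the lowest
index; a tie with the background chain resolves to background
(conservative: the read is rejected as ambiguous rather than assigned).

The extraction error probability is `P_err = 1 − V·P(x|M)/(P(x|M) +
P(x|R))`, computed stably in log space, reported as
`q = −10·log10(P_err)` capped at 60 (the cap mirrors mapping-quality
conventions; `P_err` underflows to 0 when the background is negligible).

Per-nucleotide labels: position `i`'s posterior mass per segment is
`Σ_states f(i)·b(i)/P(x|M)` over the segment's emitting states (the
background chain is exposed as its own pseudo-label and folded into its
barcode segment for pathing).  The optimal-accuracy decoder maximizes the
summed chosen-label posterior over all monotone labelings (each segment
one contiguous, possibly empty, block in architecture order).  Skipping a
partial-adapter segment is free; skipping any other segment costs −100,
which only ever wins when no monotone labeling can populate every
segment.  Ties break toward the earliest possible segment transition
(implemented by preferring "stay" during the backward trace), making
labelings deterministic.  The barcode call comes from `V`'s argmax, not
from the label path; labels are used for trimming and UMI extraction.
Fingerprint-labeled bases concatenate into the UMI; a decoded UMI whose
length differs from the declared fingerprint total rejects the read
("fingerprint length"), and UMIs are encoded base-4 (A=0, C=1, G=2, T=3,
big-endian).

## Threshold calibration

Per architecture: emit `n` reads (default 10,000) from the model by
sampling transitions and emissions, and `n` zero-order reads with the
same lengths; score both populations; choose the cutoff on `q` (midpoints
of the pooled unique scores) maximizing sensitivity + specificity, lowest
cutoff on ties.  Model emission caps the read-body loop at a realistic
body length (the pipeline uses the median input read length minus the
fixed prefix) so emitted reads match real data rather than the nearly
flat length prior.  The calibration seed is recorded in the run report;
runs are reproducible bit-for-bit.

## Filters

* **Contaminants**: each extracted read is searched semi-globally (whole
  read, anywhere in the reference, both strands) against every reference
  with Myers' bit-parallel edit-distance recurrence.  The bit vectors are
  Python arbitrary-precision integers at pattern width — a single-word
  formulation that is exact for any read length, traded against the
  64-bit blocked variant for simplicity; equivalence with the quadratic
  DP is tested for patterns well beyond 64 nt.  A read is removed iff its
  best distance is ≤ `max_edits` (default 3), attributed to its single
  best reference.  `N` matches no base.
* **Low complexity**: over the first 64 nt, `score = 100 · Σ_t
  c_t(c_t−1)/2 / (w−3)` with `c_t` the overlapping 3-mer counts and `w`
  the window length; flagged above 100 (default).  A 64-nt homopolymer
  scores 3100; random sequence stays near 5–10.  The normalization and
  scale are declared constants of this variant.

## Simulation benchmark

`simulate_dataset` renders each true read exactly from the architecture
(uniform random barcode choice, uniform UMI and read body, default body
30 nt) and applies i.i.d. per-base substitutions at the requested rate;
single-base indels are available behind `indel_rate` but default to off —
the headline benchmark varies only the substitution rate.  Decoys are
i.i.d. uniform sequences of matching length.  The benchmark regime is
9,000 true + 1,000 random reads with 8 barcodes of 6 nt at pairwise
Hamming distance ≥ 3 (4-nt sets use distance ≥ 2), a 1/10 scale of the
classic 90,000 + 10,000 design with identical composition; barcode sets
come from a seeded greedy maximal-dissimilarity search.  Recall is
correctly-assigned true reads over all true reads; precision is
correctly-assigned over all assigned; with nothing assigned, precision is
reported as 1.0 by convention (no assignments, no errors).

What the simulation does *not* model: position-dependent and
quality-string-correlated error rates, instrument-specific artifacts
(optical duplicates, poly-G tails), real contaminant abundance, or
adapter chimeras.  Passing benchmarks therefore demonstrate the method's
statistical behavior under its own error model, not instrument-calibrated
performance.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `base_error` | 0.05 | per-wrong-base match emission; tolerant across the 1–10% benchmark range |
| `indel_open` | 0.01 | insert/delete opening probability |
| `indel_extend` | 0.3 | insert self-transition |
| `expected_read_length` | 1000 | geometric read-length prior (nearly flat) |
| quality cap | 60 | phred ceiling when `P_err` underflows |
| `calibration_n` | 10,000 | emitted reads per population; stabilizes the cutoff to ~±1 phred across seeds |
| `max_edits` | 3 | contaminant error budget |
| dust threshold | 100 | complexity cutoff (0 disables) |
| `detect_sample` | 1,000 | reads scored for architecture detection |
| `background_reads` | 100,000 | reads used to estimate background frequencies |

These are declared defaults, not values fitted to data; every one is
configurable on `RunConfig` / the CLI.

## Numerical and degenerate-case choices

* `N` in an input read is emitted by every state at the probability of
  that state's likeliest base, and scores as the maximum base frequency
  under the background — score-neutral by construction.
* `extraction_quality` requires at least one of `P(x|M)`, `P(x|R)` to be
  non-zero; both impossible is an error.
* Empty READ span after decoding rejects the read ("empty read");
  rejection reasons are checked in the order threshold → ambiguous
  barcode → empty read → fingerprint length → ambiguous UMI.
* Paired-end: the architecture applies to read 1; an optional second
  architecture may be declared for read 2, in which case evidence
  combines as `P(x|M) = P(x1|M1)·P(x2|M2)` (likewise for the background)
  and `V = V1·V2`, and the pair follows the joint accept/reject decision.
  With no second architecture the mate simply follows read 1.  Mates are
  never split across accept/reject.
* Outputs are written with LF newlines and gzip mtime 0, so identical
  configurations give byte-identical files; processing is sequential and
  independent of the configured thread count.

## Known limitations

* The decoder models partial adapters only at their declared positions;
  adapter sequence appearing mid-read (chimeras) is not trimmed.
* The profile parameters are fixed, not trained (no Baum–Welch), and
  error rates are not position- or quality-aware.
* The greedy barcode-set search is not guaranteed to find maximal codes
  near the sphere-packing bound; infeasible requests fail after a bounded
  number of attempts.
* Architecture detection compares mean log-odds and assumes candidates
  are reasonably distinct; near-duplicate candidates tie toward file
  order.
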