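# hmmdemux

Profile-HMM extraction, demultiplexing and trimming of raw sequencing reads.

## The problem

The first step of almost every sequencing analysis is recovering the
*mappable* insert from raw reads that also carry adapters, sample barcodes,
spacers and unique molecular identifiers (UMIs) — all subject to sequencing
errors.  String-matching trimmers handle each artifact separately and
degrade quickly as error rates rise; mistakes at this stage either lose
reads or, worse, assign them to the wrong sample.

`hmmdemux` treats the whole problem probabilistically.  The user declares
the expected **read architecture** as an ordered list of blocks:

| block | meaning | example |
|-------|---------|---------|
| `B:`  | mutually exclusive sample barcodes | `B:GTA,AAC` |
| `F:`  | random fingerprint / UMI of fixed length | `F:NNNN` |
| `S:`  | constant spacer | `S:GGGG` |
| `P:`  | 5'/3' adapter, possibly truncated at a read end | `P:AGGGAGG` |
| `R:`  | the variable-length mappable read (exactly one) | `R:N` |

The architecture is compiled into a **global profile hidden Markov model**:
each block becomes a small profile HMM (match chains with insert/delete
states for sequencing errors; the read block is a single match column with
a self-looping insert state, a geometric length prior) and the blocks are
concatenated through silent states.  When barcodes are present, an extra
chain of the same length emitting background frequencies competes with
them, so reads whose barcode region is too ambiguous are rejected rather
than misassigned.

## The statistic

Each read `x` is scored with the forward algorithm against the model `M`
and a zero-order background model `R`.  The barcode confidence

```
V = max_j  Σ_i  f_s(i) · a(s, m_j) · e_{m_j}(x_i) · b_{m_j}(i+1)  /  P(x|M)
```

is the posterior probability (from the forward matrix `f` and backward
matrix `b`) of entering barcode chain `j` at its first match state `m_j`,
maximized over chains.  The extraction error probability

```
P_err = 1 − V · P(x|M) / ( P(x|M) + P(x|R) )
```

is reported phred-scaled as the extraction quality `q = −10·log10(P_err)`
(capped at 60), analogous to a mapping quality.  The acceptance threshold
on `q` is calibrated per architecture by emitting reads from `M` and from
`R`, scoring both, and choosing the cutoff with the best sensitivity plus
specificity.  Accepted reads are labeled per nucleotide with an
optimal-accuracy decoder (a dynamic program over posterior segment-label
probabilities, constrained to visit segments in order), trimmed, and their
UMIs checked for length and encoded as base-4 integers.  Post-extraction,
reads matching contaminant references (Myers' bit-parallel semi-global
edit distance, both strands) or low-complexity reads (a triplet-frequency
DUST-style score over the first 64 nt) are removed.

Given a file of candidate architectures, the library type of a run is
auto-detected by the mean log-odds `log P(x|M) − log P(x|R)` over the
first reads.

## Worked example

Simulate a benchmark with three 6-nt barcodes, a 4-nt UMI and 2% per-base
error, then extract with an auto-calibrated threshold:

```bash
hmmdemux simulate -1 B:GTATCG,GCTACC,ATAGTA -2 F:NNNN -3 R:N \
    -o sim --n-true 2000 --n-random 200 --error-rate 0.02 --seed 4
hmmdemux extract -1 B:GTATCG,GCTACC,ATAGTA -2 F:NNNN -3 R:N \
    -o demo sim.fastq --calibration-n 2000 --seed 7
```

which prints

```
input reads          : 2200
architecture         : arch
extraction threshold : q >= 0.003
accepted             : 2021
    ATAGTA               691
    GCTACC               682
    GTATCG               648
rejected             : 179
    low complexity       1
    threshold            178
```

2,021 of the 2,200 reads were accepted and demultiplexed into per-barcode
FASTQ files (`demo_BC_GTATCG_R1.fastq`, ...); the 178 reads below the
calibrated quality cutoff — almost exactly the 200 planted random decoys —
went to `demo_un_R1.fastq` with the rejection reason in the header.
Accepted records carry the barcode call, encoded UMI and extraction
quality in their names:

```
@true_4;BC:GTATCG;UMI:48;Q:1.27
TAGCACGAATGCGTGGAAGGCGCTCGGGGG
```

Scoring the run against the simulation truth:

```bash
hmmdemux evaluate -1 B:GTATCG,GCTACC,ATAGTA -2 F:NNNN -3 R:N \
    --truth sim_truth.tsv --prefix demo
# recall     0.9995
# precision  0.9891
```

i.e. 99.95% of the architecture-conforming reads were recovered with the
correct barcode, and 98.9% of everything assigned to a sample was assigned
correctly.

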