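"""Benchmark simulation with known ground truth, and recall/precision.

The benchmark design: a large set of reads rendered exactly from the
declared architecture (random barcode choice, random UMI, random read body)
with per-base substitution errors, mixed with a smaller set of purely
random decoy sequences of matching length.  Because the origin, planted
barcode and planted insert of every record are known, extraction runs can
be scored for recall (correctly assigned true reads / all true reads) and
precision (correctly assigned / all assigned).

Barcode sets are designed greedily for maximal dissimilarity: candidates
are kept only when at least ``min_distance`` substitutions separate them
from every barcode already chosen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architecture import ReadArchitecture, SegmentKind
from .decoder import LabeledRead

__all__ = [
    "ReadTruth",
    "SimulatedDataset",
    "EvalResult",
    "generate_barcode_set",
    "simulate_dataset",
    "evaluate",
    "evaluate_outputs",
    "hamming",
]

_BASES = np.array(list("ACGT"))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))


def generate_barcode_set(n: int, length: int, min_distance: int,
                         seed: int = 0, max_tries: int = 200_000) -> list[str]:
    """Greedy random search for ``n`` barcodes with pairwise Hamming
    distance >= ``min_distance``; deterministic given the seed."""
    if n < 1 or length < 1 or min_distance < 0:
        raise ValueError("invalid barcode design request")
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n} barcodes of length {length} at pairwise "
                f"distance >= {min_distance} within {max_tries} attempts"
            )
        cand = "".join(_BASES[rng.integers(0, 4, size=length)])
        if all(hamming(cand, b) >= min_distance for b in chosen):
            chosen.append(cand)
    return chosen


@dataclass(frozen=True)
class ReadTruth:
    origin: str                 # "true" or "random"
    barcode_index: int          # -1 for random decoys / no barcode
    read_start: int             # 0-based half-open span of the planted body
    read_end: int
    umi: str


@dataclass
class SimulatedDataset:
    records: list[tuple[str, str, str]]      # (id, seq, qual)
    truth: dict[str, ReadTruth]
    arch: ReadArchitecture
    barcodes: list[str]
    error_rate: float
    seed: int

    @property
    def n_true(self) -> int:
        return sum(1 for t in self.truth.values() if t.origin == "true")

    @property
    def n_random(self) -> int:
        return sum(1 for t in self.truth.values() if t.origin == "random")


def _mutate(seq: list[str], error_rate: float, rng) -> None:
    if error_rate <= 0:
        return
    hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
    for i in hits:
        alt = [b for b in "ACGT" if b != seq[i]]
        seq[i] = alt[rng.integers(0, 3)]


def _apply_indels(chars: list[str], rate: float, rng,
                  span: list[int]) -> list[str]:
    """Random single-base deletions/insertions; ``span`` (start, end) of the
    planted read body is adjusted in place."""
    if rate <= 0:
        return chars
    out: list[str] = []
    shift_at: list[int] = []
    for i, ch in enumerate(chars):
        r = rng.random()
        if r < rate / 2.0:          # deletion
            shift_at.append(i)
            continue
        out.append(ch)
        if r < rate:                # insertion after this base
            out.append(str(_BASES[rng.integers(0, 4)]))
            shift_at.append(-(i + 1))
    for s in shift_at:
        if s >= 0:                  # deletion at position s
            if s < span[0]:
                span[0] -= 1
                span[1] -= 1
            elif s < span[1]:
                span[1] -= 1
        else:                       # insertion after position -s-1
            p = -s - 1
            if p < span[0]:
                span[0] += 1
                span[1] += 1
            elif p < span[1]:
                span[1] += 1
    return out


def simulate_dataset(arch: ReadArchitecture, barcodes: list[str] | None = None,
                     error_rate: float = 0.0, n_true: int = 90_000,
                     n_random: int = 10_000, read_length: int = 30,
                     seed: int = 0, indel_rate: float = 0.0
                     ) -> SimulatedDataset:
    """Render architecture-conforming reads plus random decoys.

    Substitutions hit every base independently at ``error_rate``; indels
    (off by default) at ``indel_rate``.  Decoys are i.i.d. uniform
    sequences whose length matches an error-free rendering.
    """
    if not (0.0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    # separate stream for the error process: datasets at different error
    # rates share identical underlying content for the same seed
    rng_err = np.random.default_rng([seed, 7])
    bseg = arch.barcode_segments
    if barcodes is None:
        barcodes = list(bseg[0].sequences) if bseg else []
    if bseg and list(bseg[0].sequences) != list(barcodes):
        raise ValueError("barcodes must match the architecture's BARCODE segment")
    records: list[tuple[str, str, str]] = []
    truth: dict[str, ReadTruth] = {}

    total_len = 0
    for i in range(n_true):
        rid = f"true_{i}"
        chars: list[str] = []
        bc_idx = -1
        umi_parts: list[str] = []
        span = [0, 0]
        for seg in arch.segments:
            if seg.kind is SegmentKind.BARCODE:
                bc_idx = int(rng.integers(0, len(seg.sequences)))
                chars.extend(seg.sequences[bc_idx])
            elif seg.kind is SegmentKind.FINGERPRINT:
                u = "".join(_BASES[rng.integers(0, 4, size=len(seg.sequences[0]))])
                umi_parts.append(u)
                chars.extend(u)
            elif seg.kind is SegmentKind.READ:
                span[0] = len(chars)
                chars.extend(_BASES[rng.integers(0, 4, size=read_length)])
                span[1] = len(chars)
            else:                     # SPACER / PARTIAL rendered in full
                chars.extend(seg.sequences[0])
        _mutate(chars, error_rate, rng_err)
        chars = _apply_indels(chars, indel_rate, rng_err, span)
        seq = "".join(chars)
        total_len += len(seq)
        records.append((rid, seq, "I" * len(seq)))
        truth[rid] = ReadTruth(origin="true", barcode_index=bc_idx,
                               read_start=span[0], read_end=span[1],
                               umi="".join(umi_parts))
    decoy_len = (total_len // max(1, n_true)) if n_true else read_length
    for i in range(n_random):
        rid = f"random_{i}"
        seq = "".join(_BASES[rng.integers(0, 4, size=max(1, decoy_len))])
        records.append((rid, seq, "I" * len(seq)))
        truth[rid] = ReadTruth(origin="random", barcode_index=-1,
                               read_start=0, read_end=0, umi="")
    return SimulatedDataset(records=records, truth=truth, arch=arch,
                            barcodes=list(barcodes), error_rate=error_rate,
                            seed=seed)


@dataclass(frozen=True)
class EvalResult:
    recall: float
    precision: float
    misassigned: int          # accepted true reads called with a wrong barcode
    false_positives: int      # accepted random decoys
    n_true: int
    n_assigned: int


def evaluate(labeled: list[LabeledRead], truth: dict[str, ReadTruth],
             barcodes: list[str] | None = None) -> EvalResult:
    """Recall/precision of an extraction run against the planted truth.

    A read counts as correctly assigned when it was accepted, originates
    from the architecture, and its called barcode equals the planted one
    (trivially true for barcode-free architectures).  With no assigned
    reads at all, precision is reported as 1.0 (no assignments, no errors).
    """
    n_true = sum(1 for t in truth.values() if t.origin == "true")
    correct = misassigned = false_pos = assigned = 0
    for lr in labeled:
        if not lr.accepted:
            continue
        t = truth.get(lr.source)
        if t is None:
            raise KeyError(f"no truth entry for read {lr.source!r}")
        assigned += 1
        if t.origin == "random":
            false_pos += 1
            continue
        if barcodes is not None and t.barcode_index >= 0:
            ok = lr.barcode == barcodes[t.barcode_index]
        else:
            ok = True
        if ok:
            correct += 1
        else:
            misassigned += 1
    recall = correct / n_true if n_true else 0.0
    precision = correct / assigned if assigned else 1.0
    return EvalResult(recall=recall, precision=precision,
                      misassigned=misassigned, false_positives=false_pos,
                      n_true=n_true, n_assigned=assigned)


def evaluate_outputs(prefix: str, truth: dict[str, ReadTruth],
                     barcodes: list[str]) -> EvalResult:
    """Score a finished pipeline run from its demultiplexed output files.

    Reads every ``<prefix>_BC_<seq>_R1.fastq[.gz]`` (or
    ``<prefix>_extracted_R1`` for barcode-free architectures), takes the
    barcode call from the file name and the source read from the record id,
    and computes the same recall/precision as :func:`evaluate`.
    """
    import glob

    from .pipeline import read_fastq

    n_true = sum(1 for t in truth.values() if t.origin == "true")
    correct = misassigned = false_pos = assigned = 0
    paths = sorted(glob.glob(f"{prefix}_BC_*_R1.fastq*") +
                   glob.glob(f"{prefix}_extracted_R1.fastq*"))
    for path in paths:
        called = None
        if "_BC_" in path:
            called = path.split("_BC_")[1].rsplit("_R1", 1)[0]
        for rec in read_fastq(path):
            rid = rec.id.split(";")[0]
            t = truth[rid]
            assigned += 1
            if t.origin == "random":
                false_pos += 1
            elif called is None or (0 <= t.barcode_index < len(barcodes)
                                    and barcodes[t.barcode_index] == called):
                correct += 1
            else:
                misassigned += 1
    recall = correct / n_true if n_true else 0.0
    precision = correct / assigned if assigned else 1.0
    return EvalResult(recall=recall, precision=precision,
                      misassigned=misassigned, false_positives=false_pos,
                      n_true=n_true, n_assigned=assigned)
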