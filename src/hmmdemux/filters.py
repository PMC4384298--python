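"""Post-extraction read filters.

Two independent screens applied after reads are extracted:

* contaminant removal — every read is aligned semi-globally (whole read,
  anywhere in the reference, both strands) against a FASTA of unwanted
  references (rRNA, spike-ins, ...) with Myers' bit-parallel edit-distance
  algorithm; reads within the configured error budget are removed and
  counted per reference;
* low-complexity removal — a triplet-frequency (DUST-style) score over the
  first 64 nucleotides flags homopolymer-like reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ContaminantHit",
    "DustResult",
    "bitvector_edit_search",
    "filter_contaminants",
    "dust_score",
    "reverse_complement",
    "DEFAULT_MAX_EDITS",
    "DEFAULT_DUST_THRESHOLD",
]

DEFAULT_MAX_EDITS = 3
DEFAULT_DUST_THRESHOLD = 100.0
DUST_WINDOW = 64

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ContaminantHit:
    read_id: str
    reference: str
    distance: int
    end_offset: int       # 0-based position in the reference where the
    strand: str = "+"     # best alignment of the full read ends

    @property
    def start_offset(self) -> int:
        """Estimated 0-based start of the hit (exact for indel-free hits)."""
        return max(0, self.end_offset + 1 - self._read_len) \
            if self._read_len else self.end_offset

    _read_len: int = 0


@dataclass(frozen=True)
class DustResult:
    score: float
    flagged: bool


def bitvector_edit_search(read: str, reference: str, max_k: int
                          ) -> tuple[int, int] | None:
    """Semi-global approximate search of ``read`` in ``reference``.

    Myers' bit-parallel recurrence: one column of the edit-distance DP is
    kept as two bit vectors (positive/negative deltas) of pattern width and
    advanced per reference character in O(1) big-integer operations.  The
    full read must align; it may start and end anywhere in the reference.

    Returns ``(min_distance, end_offset)`` of the best hit if the minimal
    distance is <= ``max_k``, else ``None``.  ``N`` matches no base.
    """
    if not read or not reference:
        raise ValueError("read and reference must be non-empty")
    if max_k < 0:
        raise ValueError("max_k must be >= 0")
    m = len(read)
    mask = (1 << m) - 1
    high = 1 << (m - 1)
    peq = {c: 0 for c in "ACGT"}
    for i, ch in enumerate(read.upper()):
        if ch in peq:
            peq[ch] |= 1 << i
    pv = mask
    mv = 0
    score = m
    best = None
    for j, ch in enumerate(reference.upper()):
        eq = peq.get(ch, 0)
        xv = eq | mv
        xh = (((eq & pv) + pv) ^ pv) | eq
        ph = mv | (~(xh | pv) & mask)
        mh = pv & xh
        if ph & high:
            score += 1
        elif mh & high:
            score -= 1
        ph = (ph << 1) & mask          # no carry-in: text start is free
        mh = (mh << 1) & mask
        pv = (mh | (~(xv | ph) & mask))
        mv = ph & xv
        if best is None or score < best[0]:
            best = (score, j)
    if best is not None and best[0] <= max_k:
        return best
    return None


def _best_hit(read_id: str, read: str, references: Sequence[tuple[str, str]],
              max_k: int) -> ContaminantHit | None:
    best: ContaminantHit | None = None
    for name, ref in references:
        for strand, r in (("+", read), ("-", reverse_complement(read))):
            hit = bitvector_edit_search(r, ref, max_k)
            if hit is None:
                continue
            dist, end = hit
            if best is None or dist < best.distance:
                best = ContaminantHit(read_id=read_id, reference=name,
                                      distance=dist, end_offset=end,
                                      strand=strand, _read_len=len(read))
    return best


def filter_contaminants(reads: Iterable[tuple[str, str]],
                        references: Sequence[tuple[str, str]] | str | Path,
                        max_k: int = DEFAULT_MAX_EDITS):
    """Split ``(id, seq)`` reads into (kept, removed, per-reference counts).

    A read is removed iff it aligns to any reference, on either strand,
    with at most ``max_k`` mismatches+insertions+deletions; each removed
    read is attributed to its single best reference (first seen on ties).
    """
    if isinstance(references, (str, Path)):
        from Bio import SeqIO
        references = [(rec.id, str(rec.seq))
                      for rec in SeqIO.parse(str(references), "fasta")]
    kept: list[tuple[str, str]] = []
    removed: list[ContaminantHit] = []
    counts: Counter[str] = Counter()
    for read_id, seq in reads:
        hit = _best_hit(read_id, seq, references, max_k) if references else None
        if hit is None:
            kept.append((read_id, seq))
        else:
            removed.append(hit)
            counts[hit.reference] += 1
    return kept, removed, dict(counts)


def dust_score(seq: str, threshold: float = DEFAULT_DUST_THRESHOLD,
               window: int = DUST_WINDOW) -> DustResult:
    """Triplet-frequency complexity score over the first ``window`` bases.

    score = 100 * sum_t c_t*(c_t-1)/2 / (w-3), with c_t the count of
    overlapping 3-mer t in the window of length w.  Sequences shorter than
    3 nt score 0.  Flagged iff score > threshold.
    """
    w = seq[:window].upper()
    if len(w) < 3:
        return DustResult(score=0.0, flagged=False)
    counts: Counter[str] = Counter(w[i:i + 3] for i in range(len(w) - 2))
    num = sum(c * (c - 1) / 2.0 for c in counts.values())
    denom = max(1, len(w) - 3)
    score = 100.0 * num / denom
    return DustResult(score=score, flagged=score > threshold)
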