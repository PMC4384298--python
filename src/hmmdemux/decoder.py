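"""Posterior labeling, optimal-accuracy decoding and read extraction.

The forward/backward matrices give, for every read position, the posterior
probability that the position was emitted by each architecture segment
(plus a pseudo-label for the competing background-barcode chain).  A
secondary dynamic program picks the labeling with maximal summed posterior
label probability among all labelings that traverse the segments in
architecture order; the label run assigned to the READ segment is the
mappable subsequence, fingerprint-labeled bases are concatenated into the
UMI, and the barcode call comes from the chain-entry posterior (not from
the label path).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architecture import ReadArchitecture, SegmentKind
from .hmm import ProfileHMM, ScoreResult, ScoringMatrices

__all__ = [
    "FastqRecord",
    "LabeledRead",
    "posterior_labels",
    "segment_posteriors",
    "optimal_accuracy_decode",
    "extract_read",
    "encode_umi",
    "decode_umi",
]

# Penalty for leaving a mandatory (non-PARTIAL) segment empty.  Per-position
# posteriors are <= 1, so -100 forbids emptiness unless no monotone labeling
# can populate every segment (read shorter than the segment count).
SKIP_PENALTY = -100.0


@dataclass(frozen=True)
class FastqRecord:
    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"record {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )


@dataclass
class LabeledRead:
    """Decoded read: per-nucleotide labels plus the extracted pieces."""

    source: str
    labels: np.ndarray            # 1-based segment index per position
    read_seq: str
    read_qual: str
    barcode: str | None
    umi_seq: str
    umi_code: int | None
    q: float
    accepted: bool
    reason: str | None = None     # rejection reason when not accepted


def segment_posteriors(m: ScoringMatrices, hmm: ProfileHMM) -> np.ndarray:
    """(L, K) matrix of per-position posterior segment mass, background
    chains folded into their own barcode segment's column."""
    full = posterior_labels(m, hmm, fold_background=True)
    return full


def posterior_labels(m: ScoringMatrices, hmm: ProfileHMM,
                     fold_background: bool = False) -> np.ndarray:
    """Per-position posterior label probabilities.

    Returns an ``(L, K+1)`` matrix whose columns are the K architecture
    segments in order plus one pseudo-label collecting the
    background-barcode chain mass, or ``(L, K)`` with that mass folded back
    into its barcode segment when ``fold_background`` is set.
    """
    if m.f is None or m.b is None:
        raise ValueError("posterior labels need both forward and backward matrices")
    L = len(m.x)
    K = len(hmm.segments)
    emitting = ~hmm.is_silent
    post = np.exp(m.f[1:, emitting] + m.b[1:, emitting] - m.logPxM)  # (L, E)
    seg = hmm.seg_of[emitting]
    bg = hmm.is_bg[emitting]
    ncol = K if fold_background else K + 1
    out = np.zeros((L, ncol))
    for col in range(K):
        if fold_background:
            mask = seg == col + 1
        else:
            mask = (seg == col + 1) & ~bg
        out[:, col] = post[:, mask].sum(axis=1)
    if not fold_background:
        out[:, K] = post[:, bg].sum(axis=1)
    return out


def optimal_accuracy_decode(post: np.ndarray, arch: ReadArchitecture) -> np.ndarray:
    """Best monotone per-position labeling of the read.

    ``post`` is a per-position posterior label matrix over the K segments
    (a trailing background pseudo-column, if present, is folded into the
    single barcode segment).  The DP maximizes the summed posterior of the
    chosen labels over all labelings that visit segments in order, each as
    one contiguous (possibly empty) block; skipping a mandatory segment
    incurs a large penalty, skipping a PARTIAL adapter is free.  Ties are
    broken toward the earliest possible segment transition.
    """
    K = len(arch.segments)
    post = np.asarray(post, dtype=float)
    if post.ndim != 2 or post.shape[1] not in (K, K + 1):
        raise ValueError(f"posterior matrix must have {K} or {K + 1} columns")
    if post.shape[1] == K + 1:
        bseg = [s.index for s in arch.segments if s.kind is SegmentKind.BARCODE]
        bgcol = post[:, K].copy()
        post = post[:, :K].copy()
        if bseg:
            if len(bseg) > 1:
                raise ValueError(
                    "fold the background column per segment before decoding "
                    "architectures with several barcode segments"
                )
            post[:, bseg[0] - 1] += bgcol
    L = post.shape[0]
    skip = np.array([
        0.0 if s.kind is SegmentKind.PARTIAL else SKIP_PENALTY
        for s in arch.segments
    ])
    # prefix sums of skip costs: cost of skipping segments a..b (1-based)
    cskip = np.concatenate([[0.0], np.cumsum(skip)])

    def skip_cost(a: int, b: int) -> float:   # skip segments a..b inclusive
        if a > b:
            return 0.0
        return cskip[b] - cskip[a - 1]

    S = np.full((L, K), -np.inf)
    for k in range(K):
        S[0, k] = skip_cost(1, k) + post[0, k]
    for i in range(1, L):
        best_prev = np.full(K, -np.inf)
        for k in range(K):
            v = S[i - 1, k]          # stay
            for j in range(k):       # advance from j+1, skipping j+2..k
                cand = S[i - 1, j] + skip_cost(j + 2, k)
                if cand > v:
                    v = cand
            best_prev[k] = v
        S[i] = best_prev + post[i]
    # choose final segment, completing trailing skips; ties -> later segment
    # (pushes transitions earlier in the backtrack)
    finals = S[L - 1] + np.array([skip_cost(k + 2, K) for k in range(K)])
    k = int(np.flatnonzero(finals == finals.max())[-1])
    labels = np.empty(L, dtype=np.int64)
    labels[L - 1] = k + 1
    for i in range(L - 1, 0, -1):
        best_v, best_j = -np.inf, k
        for j in range(k + 1):
            cand = S[i - 1, j] + skip_cost(j + 2, k)
            if cand >= best_v:      # >= prefers the largest j (stay) on ties
                best_v, best_j = cand, j
        k = best_j
        labels[i - 1] = k + 1
    return labels


def encode_umi(umi_seq: str) -> int:
    """Base-4 big-endian encoding of a fingerprint (A=0, C=1, G=2, T=3)."""
    digits = {"A": 0, "C": 1, "G": 2, "T": 3}
    code = 0
    for ch in umi_seq:
        if ch not in digits:
            raise ValueError(f"ambiguous UMI: {umi_seq!r}")
        code = code * 4 + digits[ch]
    return code


def decode_umi(code: int, length: int) -> str:
    bases = "ACGT"
    out = []
    for _ in range(length):
        out.append(bases[code % 4])
        code //= 4
    return "".join(reversed(out))


def extract_read(record: FastqRecord, labels: np.ndarray,
                 arch: ReadArchitecture, score: ScoreResult,
                 threshold: float) -> LabeledRead:
    """Cut the labeled read into mappable sequence, barcode and UMI.

    Rejection reasons, in priority order: extraction quality below the
    threshold; barcode routed to the background chain (ambiguous); empty
    READ span; decoded fingerprint length differing from the declared one;
    N inside the fingerprint.
    """
    read_idx = arch.read_segment.index
    fp_idx = {s.index for s in arch.segments
              if s.kind is SegmentKind.FINGERPRINT}
    positions = np.asarray(labels)
    read_mask = positions == read_idx
    read_seq = "".join(c for c, m in zip(record.seq, read_mask) if m)
    read_qual = "".join(c for c, m in zip(record.qual, read_mask) if m)
    umi_seq = "".join(c for c, lab in zip(record.seq, positions)
                      if lab in fp_idx)
    barcode = None
    if score.best_barcode is not None and not score.is_background:
        parts = []
        for seg, win in zip(arch.barcode_segments, score.best_barcode):
            parts.append(seg.sequences[win])
        barcode = "-".join(parts)

    reason = None
    umi_code: int | None = None
    if score.q < threshold:
        reason = "threshold"
    elif score.is_background:
        reason = "ambiguous barcode"
    elif not read_seq:
        reason = "empty read"
    elif len(umi_seq) != arch.total_fingerprint_length:
        reason = "fingerprint length"
    else:
        try:
            umi_code = encode_umi(umi_seq) if umi_seq else None
        except ValueError:
            reason = "ambiguous UMI"
    return LabeledRead(
        source=record.id,
        labels=positions,
        read_seq=read_seq,
        read_qual=read_qual,
        barcode=barcode,
        umi_seq=umi_seq,
        umi_code=umi_code,
        q=score.q,
        accepted=reason is None,
        reason=reason,
    )
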