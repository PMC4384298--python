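"""Global profile HMM construction and scoring.

Each architecture segment becomes a small profile HMM: linear chains of
match states (one chain per barcode alternative) bracketed by a silent entry
and exit state; insert states between match columns and silent delete states
model sequencing indels; the variable-length READ segment is a single match
column with a self-looping insert state (geometric length prior).  Segments
are concatenated through their silent connectors into one global model with
a single start and end state.

If a BARCODE segment is present, a parallel chain of the same length whose
emissions are the zero-order background frequencies competes with the real
barcodes; reads whose barcode region is too ambiguous route their posterior
mass there and are rejected rather than misassigned.

Scoring: the forward algorithm yields the total model likelihood P(x|M), a
zero-order background model yields P(x|R), and the backward matrix gives the
posterior mass V of the best barcode chain (the posterior probability of the
silent-entry -> first-match transition of that chain, summed over all read
positions).  The extraction error probability is

    P_err = 1 - V * P(x|M) / (P(x|M) + P(x|R))

reported as a phred-scaled extraction quality q = -10*log10(P_err), capped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._kernels import backward_matrix, forward_matrix
from .architecture import ReadArchitecture, SegmentKind, SegmentSpec

__all__ = [
    "ErrorModel",
    "BackgroundModel",
    "ProfileHMM",
    "ScoringMatrices",
    "ScoreResult",
    "build_segment_hmm",
    "assemble_global_hmm",
    "assemble_segments",
    "forward",
    "backward",
    "forward_backward",
    "background_score",
    "barcode_confidence",
    "extraction_quality",
    "score_read",
    "encode_seq",
    "ScoringError",
    "QUALITY_CAP",
]

QUALITY_CAP = 60.0

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
NEG_INF = float("-inf")


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ErrorModel:
    """Sequencing-error tolerance of the model.

    ``base_error`` is the probability of emitting one particular wrong base
    from a match state (a match emits its own base with ``1 - 3*base_error``).
    ``indel_open`` opens an insertion or deletion between match columns;
    ``indel_extend`` is the insert-state self-transition.
    """

    base_error: float = 0.05
    indel_open: float = 0.01
    indel_extend: float = 0.3

    def __post_init__(self) -> None:
        for name in ("base_error", "indel_open", "indel_extend"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0,1), got {v}")
        if 3.0 * self.base_error >= 1.0:
            raise ValueError("base_error*3 must be < 1")


@dataclass(frozen=True)
class BackgroundModel:
    """Zero-order nucleotide model R: i.i.d. base frequencies."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must be 4 non-negative values summing to 1")
        object.__setattr__(self, "freqs", f)

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_reads(cls, seqs: Iterable[str], max_reads: int = 100_000) -> "BackgroundModel":
        """Estimate frequencies from the first ``max_reads`` sequences.

        Falls back to uniform when no countable bases are seen.
        """
        counts = np.zeros(4)
        for i, s in enumerate(seqs):
            if i >= max_reads:
                break
            for ch in s.upper():
                j = _BASE_INDEX.get(ch)
                if j is not None and j < 4:
                    counts[j] += 1
        if counts.sum() == 0:
            return cls.uniform()
        return cls(counts / counts.sum())


@dataclass(frozen=True)
class BarcodeGroup:
    """Eq.-2 bookkeeping for one BARCODE segment.

    ``chains`` holds ``(label, first_match_state, log_entry_prob)`` per
    competing chain; label ``-1`` is the background-barcode chain.
    """

    segment_index: int
    entry_state: int
    chains: tuple[tuple[int, int, float], ...]


@dataclass
class ProfileHMM:
    """Frozen global model: topologically ordered states with CSR edges."""

    n_states: int
    is_silent: np.ndarray          # bool (S,)
    seg_of: np.ndarray             # int (S,), 1-based segment; 0 = global start/end
    is_bg: np.ndarray              # bool (S,), background-barcode chain states
    emit_log: np.ndarray           # float (S, 5); col 4 = N handling
    out_ptr: np.ndarray
    out_dst: np.ndarray
    out_logp: np.ndarray
    in_ptr: np.ndarray
    in_src: np.ndarray
    in_logp: np.ndarray
    barcode_groups: tuple[BarcodeGroup, ...]
    segments: tuple[SegmentSpec, ...]
    read_match_state: int | None = None
    read_insert_state: int | None = None

    @property
    def start(self) -> int:
        return 0

    @property
    def end(self) -> int:
        return self.n_states - 1


class _Builder:
    def __init__(self) -> None:
        self.is_silent: list[bool] = []
        self.seg_of: list[int] = []
        self.is_bg: list[bool] = []
        self.emit: list[np.ndarray | None] = []
        self.edges: list[tuple[int, int, float]] = []

    def add_state(self, silent: bool, seg: int, emit: np.ndarray | None = None,
                  bg_chain: bool = False) -> int:
        self.is_silent.append(silent)
        self.seg_of.append(seg)
        self.is_bg.append(bg_chain)
        self.emit.append(None if silent else np.asarray(emit, dtype=float))
        return len(self.is_silent) - 1

    def add_edge(self, src: int, dst: int, p: float) -> None:
        if p > 0.0:
            self.edges.append((src, dst, p))

    def freeze(self, barcode_groups, segments, read_match=None,
               read_insert=None) -> ProfileHMM:
        n = len(self.is_silent)
        # outgoing probabilities must sum to 1 (end state has none)
        sums = np.zeros(n)
        for s, _, p in self.edges:
            sums[s] += p
        for s in range(n - 1):
            if abs(sums[s] - 1.0) > 1e-9:
                raise ValueError(f"state {s}: outgoing probabilities sum to {sums[s]}")
        for s, d, _ in self.edges:
            if self.is_silent[s] and self.is_silent[d] and d <= s:
                raise ValueError("silent->silent edge violates topological order")
        emit_log = np.full((n, 5), NEG_INF)
        for s in range(n):
            e = self.emit[s]
            if e is None:
                continue
            if abs(e.sum() - 1.0) > 1e-9:
                raise ValueError(f"state {s}: emissions sum to {e.sum()}")
            with np.errstate(divide="ignore"):
                emit_log[s, :4] = np.log(e)
                emit_log[s, 4] = np.log(e.max())  # N scores as the likeliest base
        out = sorted(self.edges)
        inn = sorted(self.edges, key=lambda t: (t[1], t[0]))
        out_ptr = np.zeros(n + 1, dtype=np.int64)
        in_ptr = np.zeros(n + 1, dtype=np.int64)
        for s, d, _ in out:
            out_ptr[s + 1] += 1
            in_ptr[d + 1] += 1
        out_ptr = np.cumsum(out_ptr)
        in_ptr = np.cumsum(in_ptr)
        return ProfileHMM(
            n_states=n,
            is_silent=np.array(self.is_silent),
            seg_of=np.array(self.seg_of, dtype=np.int64),
            is_bg=np.array(self.is_bg),
            emit_log=emit_log,
            out_ptr=out_ptr,
            out_dst=np.array([d for _, d, _ in out], dtype=np.int64),
            out_logp=np.log(np.array([p for _, _, p in out])),
            in_ptr=in_ptr,
            in_src=np.array([s for s, _, _ in inn], dtype=np.int64),
            in_logp=np.log(np.array([p for _, _, p in inn])),
            barcode_groups=tuple(barcode_groups),
            segments=tuple(segments),
            read_match_state=read_match,
            read_insert_state=read_insert,
        )


def _match_emission(base: str, err: ErrorModel, bg: BackgroundModel) -> np.ndarray:
    if base == "N":
        return bg.freqs.copy()
    e = np.full(4, err.base_error)
    e[_BASE_INDEX[base]] = 1.0 - 3.0 * err.base_error
    return e


def _add_chain(b: _Builder, entry: int, exit_: int, seq: str, weight: float,
               seg: int, err: ErrorModel, bg: BackgroundModel,
               bg_chain: bool = False, partial: bool = False,
               partial_stop: float = 0.1, allow_entry_delete: bool = False):
    """Add one linear match chain between entry and exit silent states.

    Deletions start at chain position 2 so all entry mass flows through the
    first match state (keeps the barcode entry posterior a proper
    distribution over chains).  Returns the first match state id.
    """
    k = len(seq)
    d_open = err.indel_open if k >= 2 else 0.0
    matches: list[int] = []
    inserts: dict[int, int] = {}
    deletes: dict[int, int] = {}
    bgfreqs = bg.freqs.copy()
    for j in range(1, k + 1):
        emit = bgfreqs if bg_chain else _match_emission(seq[j - 1], err, bg)
        matches.append(b.add_state(False, seg, emit, bg_chain=bg_chain))
        if j < k:
            if d_open > 0.0:
                inserts[j] = b.add_state(False, seg, bgfreqs, bg_chain=bg_chain)
            deletes[j + 1] = b.add_state(True, seg, bg_chain=bg_chain) \
                if d_open > 0.0 else -1
    if partial and k >= 2:
        # truncated 5' entry: most mass enters at column 1, the rest spread
        b.add_edge(entry, matches[0], weight * 0.9)
        for j in range(2, k + 1):
            b.add_edge(entry, matches[j - 1], weight * 0.1 / (k - 1))
    else:
        b.add_edge(entry, matches[0], weight)
    for j in range(1, k + 1):
        m = matches[j - 1]
        if j == k:
            b.add_edge(m, exit_, 1.0)
            continue
        stop = partial_stop if partial else 0.0
        cont = 1.0 - stop
        if stop > 0.0:
            b.add_edge(m, exit_, stop)
        if d_open > 0.0:
            b.add_edge(m, inserts[j], cont * d_open)
            b.add_edge(m, deletes[j + 1], cont * d_open)
            b.add_edge(m, matches[j], cont * (1.0 - 2.0 * d_open))
            ins = inserts[j]
            b.add_edge(ins, ins, err.indel_extend)
            b.add_edge(ins, matches[j], 1.0 - err.indel_extend)
            d = deletes[j + 1]          # deletes chain position j+1
            if j + 1 == k:
                b.add_edge(d, exit_, 1.0)
            else:
                b.add_edge(d, matches[j + 1], 1.0 - d_open)
                b.add_edge(d, deletes[j + 2], d_open)
        else:
            b.add_edge(m, matches[j], cont)
    return matches[0]


def _add_segment(b: _Builder, seg: SegmentSpec, err: ErrorModel,
                 bg: BackgroundModel, expected_read_length: float,
                 add_bg_barcode: bool):
    """Append one segment (entry silent ... exit silent) to the builder.

    Returns ``(entry, exit, barcode_group_or_None, read_states_or_None)``.
    """
    idx = seg.index
    entry = b.add_state(True, idx)
    group = None
    read_states = None
    if seg.kind is SegmentKind.READ:
        p_cont = 1.0 - 1.0 / float(expected_read_length)
        m = b.add_state(False, idx, bg.freqs.copy())
        ins = b.add_state(False, idx, bg.freqs.copy())
        exit_ = b.add_state(True, idx)
        b.add_edge(entry, m, 1.0)
        b.add_edge(m, ins, p_cont)
        b.add_edge(m, exit_, 1.0 - p_cont)
        b.add_edge(ins, ins, p_cont)
        b.add_edge(ins, exit_, 1.0 - p_cont)
        read_states = (m, ins)
    elif seg.kind is SegmentKind.BARCODE:
        chain_specs = [(lab, s, False) for lab, s in enumerate(seg.sequences)]
        if add_bg_barcode:
            chain_specs.append((-1, "N" * len(seg.sequences[0]), True))
        w = 1.0 / len(chain_specs)
        stash: list[tuple[int, int]] = []
        for lab, s, is_bg in chain_specs:
            first = _add_chain_deferred(b, entry, s, w, idx, err, bg, is_bg)
            stash.append((lab, first))
        exit_ = b.add_state(True, idx)
        _resolve_deferred(b, exit_)
        chains = tuple((lab, first, math.log(w)) for lab, first in stash)
        group = BarcodeGroup(segment_index=idx, entry_state=entry, chains=chains)
    else:
        partial = seg.kind is SegmentKind.PARTIAL
        skip = 0.02 if partial else 0.0
        _add_chain_deferred(b, entry, seg.sequences[0], 1.0 - skip, idx, err, bg,
                            False, partial=partial)
        exit_ = b.add_state(True, idx)
        if skip > 0.0:
            b.add_edge(entry, exit_, skip)
        _resolve_deferred(b, exit_)
    return entry, exit_, group, read_states


_DEFERRED_EXIT = -999999


def _add_chain_deferred(b: _Builder, entry: int, seq: str, weight: float,
                        seg: int, err: ErrorModel, bg: BackgroundModel,
                        bg_chain: bool, partial: bool = False) -> int:
    """As _add_chain but edges to the (not yet created) exit use a sentinel."""
    return _add_chain(b, entry, _DEFERRED_EXIT, seq, weight, seg, err, bg,
                      bg_chain=bg_chain, partial=partial)


def _resolve_deferred(b: _Builder, exit_: int) -> None:
    b.edges = [(s, exit_ if d == _DEFERRED_EXIT else d, p) for s, d, p in b.edges]


def assemble_segments(segments: Sequence[SegmentSpec], err: ErrorModel | None = None,
                      bg: BackgroundModel | None = None,
                      expected_read_length: float = 1000.0) -> ProfileHMM:
    """Assemble a global model from an ordered list of segments.

    Accepts arbitrary segment lists (including READ-less test fragments);
    :func:`assemble_global_hmm` applies the architecture-level validation.
    """
    err = err or ErrorModel()
    bg = bg or BackgroundModel.uniform()
    b = _Builder()
    start = b.add_state(True, 0)
    groups = []
    read_match = read_insert = None
    prev_exit = start
    for seg in segments:
        entry, exit_, group, read_states = _add_segment(
            b, seg, err, bg, expected_read_length,
            add_bg_barcode=(seg.kind is SegmentKind.BARCODE),
        )
        b.add_edge(prev_exit, entry, 1.0)
        if group is not None:
            groups.append(group)
        if read_states is not None:
            read_match, read_insert = read_states
        prev_exit = exit_
    end = b.add_state(True, 0)
    b.add_edge(prev_exit, end, 1.0)
    return b.freeze(groups, segments, read_match, read_insert)


def build_segment_hmm(seg: SegmentSpec, err: ErrorModel | None = None,
                      bg: BackgroundModel | None = None,
                      expected_read_length: float = 1000.0) -> ProfileHMM:
    """Compile a single segment into a standalone model (start/end silent)."""
    return assemble_segments([seg], err, bg, expected_read_length)


def assemble_global_hmm(arch: ReadArchitecture, err: ErrorModel | None = None,
                        bg: BackgroundModel | None = None,
                        expected_read_length: float = 1000.0) -> ProfileHMM:
    """Compile a full read architecture into the global scoring model."""
    return assemble_segments(arch.segments, err, bg, expected_read_length)


# ---------------------------------------------------------------------------
# scoring


def encode_seq(x: str) -> np.ndarray:
    if not x:
        raise ScoringError("empty sequence")
    codes = np.empty(len(x), dtype=np.int8)
    for i, ch in enumerate(x.upper()):
        j = _BASE_INDEX.get(ch)
        if j is None:
            raise ScoringError(f"invalid character {ch!r} at position {i}")
        codes[i] = j
    return codes


@dataclass
class ScoringMatrices:
    """Forward/backward log matrices for one (model, read) pair."""

    x: np.ndarray                  # int8 codes
    logPxM: float
    f: np.ndarray | None = None    # (L+1, S)
    b: np.ndarray | None = None    # (L+1, S)


def forward(hmm: ProfileHMM, x: str | np.ndarray) -> ScoringMatrices:
    codes = encode_seq(x) if isinstance(x, str) else x
    f = forward_matrix(hmm.n_states, hmm.is_silent, hmm.emit_log,
                       hmm.in_ptr, hmm.in_src, hmm.in_logp, codes)
    return ScoringMatrices(x=codes, logPxM=float(f[len(codes), hmm.end]), f=f)


def backward(hmm: ProfileHMM, x: str | np.ndarray) -> ScoringMatrices:
    codes = encode_seq(x) if isinstance(x, str) else x
    b = backward_matrix(hmm.n_states, hmm.is_silent, hmm.emit_log,
                        hmm.out_ptr, hmm.out_dst, hmm.out_logp, codes)
    return ScoringMatrices(x=codes, logPxM=float(b[0, hmm.start]), b=b)


def forward_backward(hmm: ProfileHMM, x: str | np.ndarray) -> ScoringMatrices:
    codes = encode_seq(x) if isinstance(x, str) else x
    m = forward(hmm, codes)
    mb = backward(hmm, codes)
    if math.isfinite(m.logPxM) or math.isfinite(mb.logPxM):
        if not math.isclose(m.logPxM, mb.logPxM, rel_tol=1e-9, abs_tol=1e-9):
            raise ScoringError(
                f"forward/backward disagree: {m.logPxM} vs {mb.logPxM}"
            )
    m.b = mb.b
    return m


def background_score(x: str, bg: BackgroundModel) -> float:
    """log P(x|R) under the zero-order model; N scores as the likeliest base."""
    if not x:
        raise ScoringError("empty sequence")
    with np.errstate(divide="ignore"):
        logf = np.log(bg.freqs)
    logn = float(logf.max())
    total = 0.0
    for ch in x.upper():
        j = _BASE_INDEX.get(ch)
        if j is None:
            raise ScoringError(f"invalid character {ch!r}")
        total += logn if j == 4 else float(logf[j])
    return total


def _chain_entry_posteriors(m: ScoringMatrices, hmm: ProfileHMM,
                            group: BarcodeGroup) -> list[float]:
    """Posterior mass of entering each chain of one barcode segment."""
    if m.f is None or m.b is None:
        raise ScoringError("both forward and backward matrices required")
    L = len(m.x)
    out = []
    f_s = m.f[:, group.entry_state]          # counts 0..L
    for _, first_match, log_a in group.chains:
        emit = hmm.emit_log[first_match]
        terms = f_s[:L] + log_a + emit[m.x] + m.b[1:, first_match]
        mx = terms.max()
        if mx == NEG_INF:
            out.append(0.0)
            continue
        lse = mx + math.log(np.exp(terms - mx).sum())
        out.append(float(math.exp(lse - m.logPxM)))
    return out


def barcode_confidence(m: ScoringMatrices, hmm: ProfileHMM):
    """Best-barcode posterior V and the winning chain per barcode segment.

    Returns ``(V, winners)`` where ``winners`` is ``None`` when the model has
    no barcode segment, else a tuple with one entry per BARCODE segment:
    the winning alternative index, or ``-1`` for the background chain.
    Ties between barcode alternatives go to the lowest index; a tie with the
    background chain goes to the background (read treated as ambiguous).
    """
    if not hmm.barcode_groups:
        return 1.0, None
    V = 1.0
    winners = []
    for group in hmm.barcode_groups:
        post = _chain_entry_posteriors(m, hmm, group)
        labels = [lab for lab, _, _ in group.chains]
        bc_vals = [(v, lab) for v, lab in zip(post, labels) if lab >= 0]
        bg_val = max((v for v, lab in zip(post, labels) if lab == -1), default=None)
        best_val = max(v for v, _ in bc_vals)
        best_lab = min(lab for v, lab in bc_vals if v == best_val)
        if bg_val is not None and bg_val >= best_val:
            winners.append(-1)
            V *= min(1.0, bg_val)
        else:
            winners.append(best_lab)
            V *= min(1.0, best_val)
    return V, tuple(winners)


def extraction_quality(logPxM: float, logPxR: float, V: float,
                       cap: float = QUALITY_CAP) -> tuple[float, float]:
    """Map model/background evidence and barcode confidence to (P_err, q)."""
    if logPxM == NEG_INF and logPxR == NEG_INF:
        raise ScoringError("both P(x|M) and P(x|R) are zero")
    if not (0.0 <= V <= 1.0 + 1e-12):
        raise ScoringError(f"V out of range: {V}")
    V = min(V, 1.0)
    if logPxM == NEG_INF:
        frac = 0.0
    else:
        frac = math.exp(logPxM - np.logaddexp(logPxM, logPxR))
    p_error = 1.0 - V * frac
    p_error = min(1.0, max(0.0, p_error))
    if p_error <= 0.0:
        return 0.0, cap
    q = min(cap, -10.0 * math.log10(p_error))
    return p_error, max(0.0, q)


@dataclass
class ScoreResult:
    """Per-read scoring summary."""

    logPxM: float
    logPxR: float
    V: float
    p_error: float
    q: float
    best_barcode: tuple[int, ...] | None   # None = no barcode segment

    @property
    def is_background(self) -> bool:
        return self.best_barcode is not None and -1 in self.best_barcode


def score_read(hmm: ProfileHMM, x: str, bg: BackgroundModel
               ) -> tuple[ScoreResult, ScoringMatrices]:
    """Forward-backward score of one read: likelihoods, V, P_err and q."""
    m = forward_backward(hmm, x)
    logR = background_score(x, bg)
    V, winners = barcode_confidence(m, hmm)
    p_err, q = extraction_quality(m.logPxM, logR, V)
    return ScoreResult(logPxM=m.logPxM, logPxR=logR, V=V,
                       p_error=p_err, q=q, best_barcode=winners), m
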