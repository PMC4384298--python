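"""Automatic extraction-quality threshold calibration.

A single fixed cutoff on the extraction quality cannot fit every read
architecture: long, information-rich layouts separate cleanly from random
sequence while minimal ones overlap the background.  The threshold is
therefore set per architecture by emitting reads from the compiled model M
and from the random background model R, scoring both populations, and
choosing the cutoff with the best sensitivity plus specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hmm import (BackgroundModel, ProfileHMM, barcode_confidence,
                  background_score, extraction_quality, forward_backward)

__all__ = [
    "ThresholdResult",
    "emit_from_model",
    "emit_random",
    "select_threshold",
    "calibrate_threshold",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ThresholdResult:
    """Chosen phred-scale cutoff and its operating point."""

    threshold: float
    sensitivity: float
    specificity: float
    n_model: int
    n_random: int
    seed: int | None = None


def emit_from_model(hmm: ProfileHMM, n: int, seed: int,
                    read_length: int = 50) -> list[str]:
    """Sample ``n`` reads by walking the model start to end.

    ``read_length`` caps the geometric READ-segment body so emitted reads
    match realistic instrument lengths rather than the nearly flat length
    prior of the scoring model.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out_prob = np.exp(hmm.out_logp)
    reads: list[str] = []
    bases = "ACGTN"
    emit_prob = np.where(np.isfinite(hmm.emit_log[:, :4]),
                         np.exp(hmm.emit_log[:, :4]), 0.0)
    read_states = {hmm.read_match_state, hmm.read_insert_state} - {None}
    for _ in range(n):
        state = hmm.start
        chars: list[str] = []
        body = 0
        while state != hmm.end:
            if not hmm.is_silent[state]:
                p = emit_prob[state]
                chars.append(bases[rng.choice(4, p=p / p.sum())])
                if state in read_states:
                    body += 1
            lo, hi = hmm.out_ptr[state], hmm.out_ptr[state + 1]
            dsts = hmm.out_dst[lo:hi]
            probs = out_prob[lo:hi].copy()
            if body >= read_length and state in read_states:
                # force the walk out of the read-body loop
                keep = np.array([d not in read_states for d in dsts])
                if keep.any():
                    probs = np.where(keep, probs, 0.0)
            probs = probs / probs.sum()
            state = int(dsts[rng.choice(len(dsts), p=probs)])
        reads.append("".join(chars))
    return reads


def emit_random(bg: BackgroundModel, n: int, seed: int,
                lengths: int | list[int]) -> list[str]:
    """Sample ``n`` i.i.d. zero-order reads; ``lengths`` is a single length
    or one length per read (cycled)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(lengths, int):
        lens = [lengths] * n
    else:
        if not lengths:
            raise ValueError("empty length list")
        lens = [lengths[i % len(lengths)] for i in range(n)]
    return [
        "".join(_BASES[rng.choice(4, size=L, p=bg.freqs)]) for L in lens
    ]


def select_threshold(scores_model: list[float], scores_random: list[float],
                     n_model: int | None = None, n_random: int | None = None,
                     seed: int | None = None) -> ThresholdResult:
    """Cutoff maximizing sensitivity + specificity.

    Candidate cutoffs are the midpoints between adjacent pooled unique
    scores plus one below and one above the range; sensitivity is the
    fraction of model scores >= cutoff, specificity the fraction of random
    scores < cutoff.  The lowest maximizing cutoff is returned.
    """
    if not scores_model or not scores_random:
        raise ValueError("both score lists must be non-empty")
    sm = np.asarray(scores_model, dtype=float)
    sr = np.asarray(scores_random, dtype=float)
    uniq = np.unique(np.concatenate([sm, sr]))
    candidates = [uniq[0] - 1.0]
    candidates += list((uniq[:-1] + uniq[1:]) / 2.0)
    candidates += [uniq[-1] + 1.0]
    best = None
    for c in candidates:
        sens = float((sm >= c).mean())
        spec = float((sr < c).mean())
        if best is None or sens + spec > best[0] + best[1] + 1e-15:
            best = (sens, spec, c)
    sens, spec, cut = best
    return ThresholdResult(threshold=float(cut), sensitivity=sens,
                           specificity=spec,
                           n_model=n_model if n_model is not None else len(sm),
                           n_random=n_random if n_random is not None else len(sr),
                           seed=seed)


def _score_q(hmm: ProfileHMM, bg: BackgroundModel, read: str) -> float:
    m = forward_backward(hmm, read)
    V, _ = barcode_confidence(m, hmm)
    _, q = extraction_quality(m.logPxM, background_score(read, bg), V)
    return q


def calibrate_threshold(hmm: ProfileHMM, bg: BackgroundModel,
                        n: int = 10_000, seed: int = 42,
                        read_length: int = 50) -> ThresholdResult:
    """Emit ``n`` model and ``n`` random reads, score both, pick the cutoff.

    Random reads reuse the emitted model reads' lengths so the cutoff
    reflects the architecture's length, not an arbitrary instrument length.
    """
    model_reads = emit_from_model(hmm, n, seed, read_length=read_length)
    lens = [len(r) for r in model_reads]
    random_reads = emit_random(bg, n, seed + 1, lens)
    q_model = [_score_q(hmm, bg, r) for r in model_reads]
    q_random = [_score_q(hmm, bg, r) for r in random_reads]
    return select_threshold(q_model, q_random, n_model=n, n_random=n, seed=seed)
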