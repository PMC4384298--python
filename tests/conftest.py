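"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's dynamic programming:
model probabilities are recomputed by explicit enumeration of every state
path, labelings by enumeration of every monotone labeling, and edit
distances by the classic quadratic DP, so the fast implementations are
checked against genuinely independent computations.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from hmmdemux.architecture import parse_architecture
from hmmdemux.hmm import BackgroundModel, ErrorModel, ProfileHMM, encode_seq


@pytest.fixture
def uniform_bg() -> BackgroundModel:
    return BackgroundModel.uniform()


@pytest.fixture
def zero_error() -> ErrorModel:
    return ErrorModel(base_error=0.0, indel_open=0.0, indel_extend=0.0)


# ---------------------------------------------------------------------------
# path-enumeration oracle


def enumerate_paths(hmm: ProfileHMM, x: str, max_paths: int = 2_000_000):
    """All complete state paths emitting exactly ``x``, in linear space.

    Returns ``(total_probability, paths)`` where each path is
    ``(probability, [(pos, state), ...] emissions, [(src, dst, pos), ...]
    traversed edges)``.
    """
    codes = encode_seq(x)
    L = len(codes)
    emit = np.where(np.isfinite(hmm.emit_log), np.exp(hmm.emit_log), 0.0)
    out: list[list[tuple[int, float]]] = [[] for _ in range(hmm.n_states)]
    for s in range(hmm.n_states):
        for k in range(hmm.out_ptr[s], hmm.out_ptr[s + 1]):
            out[s].append((int(hmm.out_dst[k]), math.exp(hmm.out_logp[k])))
    paths = []
    total = 0.0

    def dfs(state, pos, prob, emits, edges):
        nonlocal total
        if len(paths) > max_paths:
            raise RuntimeError("path explosion in enumeration oracle")
        if state == hmm.end:
            if pos == L:
                total += prob
                paths.append((prob, list(emits), list(edges)))
            return
        for t, p in out[state]:
            if hmm.is_silent[t]:
                edges.append((state, t, pos))
                dfs(t, pos, prob * p, emits, edges)
                edges.pop()
            elif pos < L:
                e = emit[t, codes[pos]]
                if e > 0.0:
                    emits.append((pos, t))
                    edges.append((state, t, pos))
                    dfs(t, pos + 1, prob * p * e, emits, edges)
                    edges.pop()
                    emits.pop()

    dfs(hmm.start, 0, 1.0, [], [])
    return total, paths


def oracle_state_posteriors(hmm: ProfileHMM, x: str) -> tuple[float, np.ndarray]:
    """(total P, (L, S) matrix of posterior emission mass) by enumeration."""
    total, paths = enumerate_paths(hmm, x)
    mass = np.zeros((len(x), hmm.n_states))
    for prob, emits, _ in paths:
        for pos, state in emits:
            mass[pos, state] += prob
    return total, mass / total if total > 0 else mass


def oracle_chain_posteriors(hmm: ProfileHMM, x: str) -> list[list[float]]:
    """Posterior mass of entering each barcode chain, by enumeration."""
    total, paths = enumerate_paths(hmm, x)
    result = []
    for group in hmm.barcode_groups:
        masses = []
        for _, first_match, _ in group.chains:
            m = 0.0
            for prob, _, edges in paths:
                if any(s == group.entry_state and d == first_match
                       for s, d, _ in edges):
                    m += prob
            masses.append(m / total if total > 0 else 0.0)
        result.append(masses)
    return result


# ---------------------------------------------------------------------------
# monotone-labeling oracle


def oracle_best_labeling(post: np.ndarray, skip: np.ndarray) -> float:
    """Best total score over all monotone labelings by enumeration.

    ``post`` is (L, K); ``skip[k]`` is the cost of leaving segment k+1
    empty.  Labelings assign each position a segment, non-decreasing along
    the read; skipped segments contribute their skip cost.
    """
    import itertools

    L, K = post.shape
    best = -np.inf
    for labels in itertools.product(range(K), repeat=L):
        if any(b < a for a, b in zip(labels, labels[1:])):
            continue
        used = set(labels)
        score = sum(post[i, k] for i, k in enumerate(labels))
        score += sum(skip[k] for k in range(K) if k not in used)
        best = max(best, score)
    return best


# ---------------------------------------------------------------------------
# quadratic edit-distance oracle


def wagner_fischer_semiglobal(read: str, ref: str) -> int:
    """Minimal edit distance of ``read`` against any substring of ``ref``."""
    m, n = len(read), len(ref)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j - 1] + (read[i - 1] != ref[j - 1]),
                         prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev[1:]) if n else m


# ---------------------------------------------------------------------------
# small random architectures for property tests


def random_tiny_architecture(rng: np.random.Generator):
    """A small random architecture whose model stays below ~14 states."""
    bases = "ACGT"
    choice = rng.integers(0, 3)
    if choice == 0:
        bc = ["".join(rng.choice(list(bases), 1)) for _ in range(2)]
        if bc[0] == bc[1]:
            bc[1] = bases[(bases.index(bc[0]) + 1) % 4]
        return parse_architecture([f"B:{','.join(bc)}", "R:N"])
    if choice == 1:
        sp = "".join(rng.choice(list(bases), rng.integers(1, 3)))
        return parse_architecture([f"S:{sp}", "R:N"])
    return parse_architecture(["F:NN", "R:N"])


def random_architecture(rng: np.random.Generator):
    """A moderate random architecture for forward/backward identities."""
    bases = list("ACGT")
    segs = []
    if rng.random() < 0.5:
        n_bc = int(rng.integers(2, 5))
        length = int(rng.integers(2, 5))
        bcs = set()
        while len(bcs) < n_bc:
            bcs.add("".join(rng.choice(bases, length)))
        segs.append("B:" + ",".join(sorted(bcs)))
    if rng.random() < 0.5:
        segs.append("F:" + "N" * int(rng.integers(2, 6)))
    if rng.random() < 0.5:
        segs.append("S:" + "".join(rng.choice(bases, int(rng.integers(1, 5)))))
    segs.append("R:N")
    if rng.random() < 0.3:
        segs.append("P:" + "".join(rng.choice(bases, int(rng.integers(4, 9)))))
    return parse_architecture(segs)
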