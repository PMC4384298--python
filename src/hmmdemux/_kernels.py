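"""Numba-jitted forward/backward dynamic programming kernels.

States are topologically ordered: every silent->silent transition goes from a
lower to a higher state id, so silent chains can be resolved with a single
in-order (forward) or reverse-order (backward) sweep per sequence position.
All probabilities are natural-log; ``-inf`` marks impossible events.

Matrix conventions (``L`` = read length, ``S`` = number of states):

``f[i, s]``
    log-probability of all paths that start at state 0, emit exactly the
    first ``i`` read characters, and sit at state ``s`` (an emitting state
    has just emitted character ``i-1``).
``b[i, s]``
    log-probability of emitting the suffix ``x[i:]`` and reaching the end
    state, starting from state ``s`` after ``i`` characters have been
    emitted.

The total log P(x|M) is ``f[L, end]`` and equals ``b[0, start]``.
"""

import numpy as np
from numba import njit

__all__ = ["forward_matrix", "backward_matrix"]


@njit(cache=True)
def forward_matrix(n_states, is_silent, emit, in_ptr, in_src, in_logp, x):
    L = x.shape[0]
    f = np.full((L + 1, n_states), -np.inf)
    f[0, 0] = 0.0
    for i in range(L + 1):
        if i > 0:
            xi = x[i - 1]
            for s in range(n_states):
                if is_silent[s]:
                    continue
                acc = -np.inf
                for k in range(in_ptr[s], in_ptr[s + 1]):
                    acc = np.logaddexp(acc, f[i - 1, in_src[k]] + in_logp[k])
                f[i, s] = acc + emit[s, xi]
        for s in range(n_states):
            if not is_silent[s]:
                continue
            if s == 0 and i == 0:
                continue
            acc = -np.inf
            for k in range(in_ptr[s], in_ptr[s + 1]):
                # silent predecessors have lower ids and are already done
                acc = np.logaddexp(acc, f[i, in_src[k]] + in_logp[k])
            f[i, s] = acc
    return f


@njit(cache=True)
def backward_matrix(n_states, is_silent, emit, out_ptr, out_dst, out_logp, x):
    L = x.shape[0]
    b = np.full((L + 1, n_states), -np.inf)
    b[L, n_states - 1] = 0.0
    for i in range(L, -1, -1):
        for s in range(n_states - 1, -1, -1):
            if not is_silent[s]:
                continue
            if s == n_states - 1 and i == L:
                continue
            acc = -np.inf
            for k in range(out_ptr[s], out_ptr[s + 1]):
                t = out_dst[k]
                if is_silent[t]:
                    acc = np.logaddexp(acc, b[i, t] + out_logp[k])
                elif i < L:
                    acc = np.logaddexp(
                        acc, out_logp[k] + emit[t, x[i]] + b[i + 1, t]
                    )
            b[i, s] = acc
        for s in range(n_states):
            if is_silent[s]:
                continue
            acc = -np.inf
            for k in range(out_ptr[s], out_ptr[s + 1]):
                t = out_dst[k]
                if is_silent[t]:
                    acc = np.logaddexp(acc, b[i, t] + out_logp[k])
                elif i < L:
                    acc = np.logaddexp(
                        acc, out_logp[k] + emit[t, x[i]] + b[i + 1, t]
                    )
            b[i, s] = acc
    return b
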