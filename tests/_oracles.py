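"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's own recursions: latent states are
enumerated exhaustively, integrals are done by generic numeric quadrature,
so they stay independent of the code paths they check.
"""

import numpy as np
from itertools import product


def enumerate_cjs_likelihood(history, pi, phi_seq, p_seq):
    """Likelihood of one capture history by exhaustive (R, z) enumeration."""
    h = np.asarray(history, dtype=int)
    K = h.size
    assert h[0] == 1
    total = 0.0
    # transient branch: never seen again with probability 1
    if not h[1:].any():
        total += (1.0 - pi)
    # resident branch: enumerate every alive-state path
    for z in product([0, 1], repeat=K - 1):
        prob = pi
        prev = 1
        ok = True
        for k in range(1, K):
            zk = z[k - 1]
            if prev == 1:
                prob *= phi_seq[k - 1] if zk == 1 else (1.0 - phi_seq[k - 1])
            else:
                if zk == 1:
                    ok = False
                    break
            if h[k] == 1:
                if zk != 1:
                    ok = False
                    break
                prob *= p_seq[k - 1]
            else:
                if zk == 1:
                    prob *= 1.0 - p_seq[k - 1]
            prev = zk
        if ok:
            total += prob
    return total


def enumerate_joint_likelihood(history, r, pi, rho, phi_seq, p_seq):
    """Joint (history, residency observation) likelihood by enumeration."""
    h = np.asarray(history, dtype=int)
    K = h.size
    total = 0.0
    # R = 0 (transient): r must be 0, no recaptures possible
    if r == 0 and not h[1:].any():
        total += (1.0 - pi)
    # R = 1 (resident)
    r_prob = rho if r == 1 else (1.0 - rho)
    for z in product([0, 1], repeat=K - 1):
        prob = pi * r_prob
        prev = 1
        ok = True
        for k in range(1, K):
            zk = z[k - 1]
            if prev == 1:
                prob *= phi_seq[k - 1] if zk == 1 else (1.0 - phi_seq[k - 1])
            else:
                if zk == 1:
                    ok = False
                    break
            if h[k] == 1:
                if zk != 1:
                    ok = False
                    break
                prob *= p_seq[k - 1]
            else:
                if zk == 1:
                    prob *= 1.0 - p_seq[k - 1]
            prev = zk
        if ok:
            total += prob
    return total


def all_continuations(K):
    """All 0/1 capture histories of length K starting with a capture."""
    for tail in product([0, 1], repeat=K - 1):
        yield np.array((1,) + tail, dtype=int)
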