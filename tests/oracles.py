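"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's recursions: the HMM quantities are
computed by exhaustive enumeration over all N^T state sequences, events by
itertools.groupby run-length encoding, and bearings by a tangent-plane
vector construction.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_hmm(delta, gammas, b):
    """Exhaustive HMM quantities for tiny problems.

    Parameters
    ----------
    delta : (N,) initial distribution
    gammas : (T-1, N, N) transition matrices
    b : (T, N) observation densities (linear scale)

    Returns
    -------
    loglik, viterbi path (ties -> lexicographically first, i.e. lower state
    index), posterior (T, N)
    """
    T, N = b.shape
    total = 0.0
    best_p = -1.0
    best_seq = None
    post = np.zeros((T, N))
    for seq in itertools.product(range(N), repeat=T):
        p = delta[seq[0]] * b[0, seq[0]]
        for t in range(1, T):
            p *= gammas[t - 1, seq[t - 1], seq[t]] * b[t, seq[t]]
        total += p
        if p > best_p:
            best_p = p
            best_seq = seq
        for t in range(T):
            post[t, seq[t]] += p
    return np.log(total), np.array(best_seq), post / total


def rle_foraging_events(observed):
    """Run-length encoding of foraging bouts: [(start, end_inclusive), ...]."""
    out = []
    i = 0
    for val, grp in itertools.groupby(observed):
        n = len(list(grp))
        if val == 1:
            out.append((i, i + n - 1))
        i += n
    return out


def vector_initial_bearing(lon1, lat1, lon2, lat2):
    """Initial bearing via tangent-plane projection of unit vectors (radians)."""
    lam1, phi1, lam2, phi2 = map(np.radians, (lon1, lat1, lon2, lat2))

    def unit(lam, phi):
        return np.array([np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam),
                         np.sin(phi)])

    p1, p2 = unit(lam1, phi1), unit(lam2, phi2)
    north = np.array([-np.sin(phi1) * np.cos(lam1), -np.sin(phi1) * np.sin(lam1),
                      np.cos(phi1)])
    east = np.array([-np.sin(lam1), np.cos(lam1), 0.0])
    d = p2 - p1 * np.dot(p1, p2)
    return float(np.mod(np.arctan2(np.dot(d, east), np.dot(d, north)), 2 * np.pi))
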