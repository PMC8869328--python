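"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here deliberately avoids the package's own vectorised code paths:
triple loops, exhaustive enumeration, Floyd–Warshall, direct density sums.
"""

from __future__ import annotations

import itertools

import numpy as np


def clustering_triple_loop(W: np.ndarray) -> np.ndarray:
    """Geometric-mean weighted clustering via explicit triple enumeration."""
    W = np.asarray(W, dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    wmax = W.max()
    Wn = W / wmax if wmax > 0 else W
    n = W.shape[0]
    C = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if W[i, j] > 0)
        if k < 2:
            continue
        s = 0.0
        for j in range(n):
            for l in range(j + 1, n):
                if j == i or l == i:
                    continue
                s += (Wn[i, j] * Wn[i, l] * Wn[j, l]) ** (1.0 / 3.0)
        C[i] = 2.0 * s / (k * (k - 1))
    return C


def floyd_warshall_paths(D: np.ndarray):
    """All-pairs shortest distances, hop counts and paths by Floyd–Warshall.

    Tie-break mirrors the spec: shorter distance first, then fewer hops,
    then lexicographically smaller node sequence.
    """
    n = D.shape[0]
    dist = D.copy().astype(float)
    np.fill_diagonal(dist, 0.0)
    paths = {}
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]):
                paths[(i, j)] = [i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if i == j or not (np.isfinite(dist[i, k]) and np.isfinite(dist[k, j])):
                    continue
                if k == i or k == j:
                    continue
                cand = dist[i, k] + dist[k, j]
                if (i, k) not in paths or (k, j) not in paths:
                    continue
                new_path = paths[(i, k)] + paths[(k, j)][1:]
                if cand < dist[i, j] - 1e-15:
                    dist[i, j] = cand
                    paths[(i, j)] = new_path
                elif abs(cand - dist[i, j]) <= 1e-12 and (i, j) in paths:
                    old = paths[(i, j)]
                    if (len(new_path), new_path) < (len(old), old):
                        paths[(i, j)] = new_path
    hops = {k: len(p) - 1 for k, p in paths.items()}
    return dist, hops, paths


def all_partitions(items):
    """Every partition of a list into non-empty blocks (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def newman_modularity(W: np.ndarray, blocks) -> float:
    """Standard weighted modularity of an explicit partition, direct sums."""
    W = np.asarray(W, dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    two_m = W.sum()
    s = W.sum(axis=1)
    q = 0.0
    for block in blocks:
        for i in block:
            for j in block:
                q += W[i, j] - s[i] * s[j] / two_m
    return q / two_m


def monotone_viterbi_bruteforce(logpi, logA, logB):
    """Best monotone (non-decreasing) state path by exhaustive enumeration."""
    T, S = logB.shape
    best_lp = -np.inf
    best_path = None
    for path in itertools.product(range(S), repeat=T):
        if any(b < a for a, b in zip(path, path[1:])):
            continue
        lp = logpi[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            lp += logA[path[t - 1], path[t]] + logB[t, path[t]]
        if lp > best_lp + 1e-12:
            best_lp = lp
            best_path = path
    return best_lp, np.array(best_path)


def spectral_amplitude(x: np.ndarray, fs: float, freq: float) -> float:
    """Discrete-Fourier magnitude of x at the bin nearest ``freq``."""
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    return float(spec[np.argmin(np.abs(freqs - freq))])
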