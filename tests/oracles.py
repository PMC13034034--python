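"""Independent oracle implementations shared across test modules.

These deliberately re-derive results by brute force (full sorts,
pairwise-comparison statistics, permutation enumeration, Monte-Carlo
permutation) so they stay independent of the library code paths they
check.
"""

import math
from itertools import combinations

import numpy as np
from scipy.stats import rankdata

import trichoflow as tf


def brute_force_knee(barcodes, counts, n, percentile=99.0, fraction=0.10):
    """Full sort, nearest-rank index, literal threshold filter."""
    order = sorted(range(len(barcodes)), key=lambda i: (-counts[i], barcodes[i]))
    n = min(n, len(barcodes))
    top = [counts[i] for i in order[:n]]
    rank = max(1, math.ceil((1 - percentile / 100.0) * n))
    m = top[rank - 1]
    if m == 0:
        return set(), 0
    threshold = fraction * m
    return {barcodes[i] for i in range(len(barcodes))
            if not counts[i] < threshold}, m


def random_profile(rng, n=500):
    counts = rng.integers(0, 5000, size=n)
    barcodes = np.array([f"BC{i:05d}" for i in rng.permutation(10 * n)[:n]])
    return tf.BarcodeProfile(barcodes=barcodes, umi_counts=counts)


def permutation_oracle(x, y):
    """Exact two-sided p by enumerating labelings and counting pairwise
    wins (independent of the midrank-based implementation)."""
    pooled = np.concatenate([x, y])
    n, n_x = len(pooled), len(x)

    def u_stat(indices):
        group = set(indices)
        u = 0.0
        for i in group:
            for j in range(n):
                if j in group:
                    continue
                if pooled[i] > pooled[j]:
                    u += 1.0
                elif pooled[i] == pooled[j]:
                    u += 0.5
        return u

    mu = n_x * (n - n_x) / 2.0
    u_obs = u_stat(range(n_x))
    hits = total = 0
    for combo in combinations(range(n), n_x):
        total += 1
        if abs(u_stat(combo) - mu) >= abs(u_obs - mu) - 1e-9:
            hits += 1
    return hits / total


def monte_carlo_p(x, y, n_draws=100_000, seed=0):
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    n_x = len(x)
    ranks = rankdata(pooled)
    mu = n_x * (len(pooled) - n_x) / 2.0
    offset = n_x * (n_x + 1) / 2.0
    u_obs = ranks[:n_x].sum() - offset
    keys = rng.random((n_draws, len(pooled)))
    order = np.argsort(keys, axis=1)[:, :n_x]
    u = ranks[order].sum(axis=1) - offset
    return np.mean(np.abs(u - mu) >= abs(u_obs - mu) - 1e-9)
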