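"""Independent brute-force oracles used to validate the fast metric
implementations.  Everything here is deliberately naive: explicit pair
counting, explicit entropy sums, exhaustive permutation search."""

from itertools import permutations

import numpy as np


def all_partitions(n):
    """Every set partition of range(n) as a label vector (restricted-growth
    enumeration)."""

    def rec(prefix, k):
        i = len(prefix)
        if i == n:
            yield tuple(prefix)
            return
        for label in range(k + 1):
            yield from rec(prefix + [label], max(k, label + 1))

    yield from rec([], 0)


def ari_bruteforce(p1, p2):
    """ARI from explicit same/different pair counts."""
    p1, p2 = np.asarray(p1), np.asarray(p2)
    n = len(p1)
    n11 = n10 = n01 = n00 = 0
    for i in range(n):
        for j in range(i + 1, n):
            s1 = p1[i] == p1[j]
            s2 = p2[i] == p2[j]
            if s1 and s2:
                n11 += 1
            elif s1:
                n10 += 1
            elif s2:
                n01 += 1
            else:
                n00 += 1
    denom = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if denom == 0:
        return 1.0
    return 2.0 * (n11 * n00 - n10 * n01) / denom


def vi_bruteforce(p1, p2):
    """VI from explicit joint counts and natural-log entropy sums."""
    p1, p2 = np.asarray(p1), np.asarray(p2)
    n = len(p1)
    labels1, labels2 = np.unique(p1), np.unique(p2)
    joint = np.zeros((len(labels1), len(labels2)))
    for a, la in enumerate(labels1):
        for b, lb in enumerate(labels2):
            joint[a, b] = np.sum((p1 == la) & (p2 == lb))
    joint /= n
    m1, m2 = joint.sum(axis=1), joint.sum(axis=0)

    def H(p):
        p = p[p > 0]
        return -np.sum(p * np.log(p))

    mi = 0.0
    for a in range(len(labels1)):
        for b in range(len(labels2)):
            if joint[a, b] > 0:
                mi += joint[a, b] * np.log(joint[a, b] / (m1[a] * m2[b]))
    return H(m1) + H(m2) - 2.0 * mi


def ccc_bruteforce(a, b):
    """Lin's CCC straight from the defining formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    cov = np.mean((a - a.mean()) * (b - b.mean()))
    return 2.0 * cov / (a.var() + b.var() + (a.mean() - b.mean()) ** 2)


def concordance_bruteforce(W_A, W_B):
    """Mean per-column CCC maximized over ALL column permutations of W_B,
    with the permutation chosen by exhaustive Pearson-correlation matching
    (mirrors the implementation contract but by brute force)."""
    W_A, W_B = np.asarray(W_A, float), np.asarray(W_B, float)
    k = W_A.shape[1]
    best_perm, best_score = None, -np.inf
    for perm in permutations(range(k)):
        score = 0.0
        for j in range(k):
            a, b = W_A[:, j], W_B[:, perm[j]]
            sa, sb = a.std(), b.std()
            if sa > 0 and sb > 0:
                score += np.corrcoef(a, b)[0, 1]
        if score > best_score:
            best_score, best_perm = score, perm
    return np.mean([ccc_bruteforce(W_A[:, j], W_B[:, best_perm[j]]) for j in range(k)])


def reconstruction_error_bruteforce(X, W):
    """Element-wise double-loop relative Frobenius reconstruction error."""
    X, W = np.asarray(X, float), np.asarray(W, float)
    proj = np.zeros_like(X)
    p, n = X.shape
    k = W.shape[1]
    for i in range(p):
        for j in range(n):
            s = 0.0
            for a in range(k):
                for b in range(p):
                    s += W[i, a] * W[b, a] * X[b, j]
            proj[i, j] = s
    num = np.sqrt(np.sum((X - proj) ** 2))
    den = np.sqrt(np.sum(X**2))
    return num / den
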