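"""Independent brute-force oracles used by the test suite.

Each function re-derives a statistic by the most literal route available
(all-pairs scans, explicit loops, exhaustive enumeration) so the
vectorised implementations can be checked against code that shares
nothing with them.
"""

from __future__ import annotations

import itertools
from math import comb, sqrt

import numpy as np

MISSING = -1


def brute_force_clone_partition(calls: np.ndarray, ids: list[str]):
    """All-pairs identity scan with union-find transitive closure.

    Loci with any missing call (in this block) are dropped first, as in
    the pipeline's clone rule.
    """
    keep = [j for j in range(calls.shape[1]) if not (calls[:, j] == MISSING).any()]
    sub = calls[:, keep]
    n = len(ids)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if all(sub[i, l] == sub[j, l] for l in range(sub.shape[1])):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(ids[i])
    return sorted(groups.values(), key=lambda g: ids.index(g[0]))


def yates_chi2(a, b, c, d):
    """Textbook Yates-corrected chi-squared for a 2x2 table [[a,b],[c,d]]."""
    n = a + b + c + d
    num = n * (abs(a * d - b * c) - n / 2) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


def tally_ho_hs(genos: list[int]):
    """Per-locus Ho and Nei unbiased Hs by explicit genotype counting."""
    obs = [g for g in genos if g != MISSING]
    n = len(obs)
    het = sum(1 for g in obs if g == 1)
    ho = het / n
    p = sum(obs) / (2 * n)
    hs = n / (n - 1) * (1 - (p**2 + (1 - p) ** 2) - ho / (2 * n))
    return ho, hs


def wc_theta_loops(calls: np.ndarray, pops: list[str]):
    """Weir-Cockerham multilocus theta via explicit per-locus loops."""
    pop_names = sorted(set(pops))
    A = B = C = 0.0
    for l in range(calls.shape[1]):
        ns, ps, hs = [], [], []
        for pop in pop_names:
            rows = [i for i, p in enumerate(pops) if p == pop]
            obs = [calls[i, l] for i in rows if calls[i, l] != MISSING]
            if not obs:
                continue
            ns.append(len(obs))
            ps.append(sum(obs) / (2 * len(obs)))
            hs.append(sum(1 for g in obs if g == 1) / len(obs))
        r = len(ns)
        if r < 2:
            continue
        nbar = sum(ns) / r
        if nbar <= 1:
            continue
        nc = (sum(ns) - sum(x * x for x in ns) / sum(ns)) / (r - 1)
        pbar = sum(n * p for n, p in zip(ns, ps)) / sum(ns)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / sum(ns)
        a = (nbar / nc) * (
            s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        if nc == 0:
            continue
        A += a
        B += b
        C += c
    return A / (A + B + C)


def exhaustive_rarefied_ar(copies: list[int], g: int) -> float:
    """Mean allele count over ALL size-g subsamples of the listed gene copies.

    ``copies`` lists each gene copy's allele (0/1).  Feasible for
    len(copies) <= 10 and small g.
    """
    total = 0
    n_sub = 0
    for sub in itertools.combinations(range(len(copies)), g):
        alleles = {copies[i] for i in sub}
        total += len(alleles)
        n_sub += 1
    return total / n_sub


def exhaustive_mantel_p(a: np.ndarray, b: np.ndarray) -> float:
    """One-sided Mantel p by full enumeration of all n! permutations."""
    n = a.shape[0]
    idx = np.tril_indices(n, k=-1)
    x = a[idx]

    def corr(mat):
        y = mat[idx]
        return np.corrcoef(x, y)[0, 1]

    r_obs = corr(b)
    perms = list(itertools.permutations(range(n)))
    count = sum(corr(b[np.ix_(p, p)]) >= r_obs for p in perms)
    return count / len(perms)


def cosine_law_km(lat1, lon1, lat2, lon2, radius=6371.0):
    """Great-circle distance by the spherical law of cosines."""
    import math

    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    val = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return radius * math.acos(min(1.0, max(-1.0, val)))


def literal_chord_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Cavalli-Sforza & Edwards chord distance, locus by locus in a loop."""
    total = 0.0
    L = len(p)
    for l in range(L):
        total += sqrt(p[l] * q[l]) + sqrt((1 - p[l]) * (1 - q[l]))
    return (2 / np.pi) * sqrt(max(0.0, 2 * (1 - total / L)))
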