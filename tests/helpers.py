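"""Brute-force oracles shared by the test modules.

Everything here works by explicit enumeration over expanded individual
sequences, independently of the count-weighted formulas in the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mitopop.distances import DistanceMatrix
from mitopop.haplotypes import HaplotypeTable
from mitopop.io import Alignment


def make_alignment(seqs, pops=None, ids=None) -> Alignment:
    n = len(seqs)
    ids = ids or [f"s{i}" for i in range(n)]
    pops = pops or ["pop1"] * n
    return Alignment(ids=ids, seqs=list(seqs),
                     population_of=dict(zip(ids, pops)))


def random_table(rng, max_pops=4, max_haps=6, max_count=8):
    """Random count table + random symmetric integer distance matrix."""
    P = int(rng.integers(2, max_pops + 1))
    m = int(rng.integers(2, max_haps + 1))
    counts = rng.integers(0, max_count + 1, size=(P, m))
    counts[:, 0] += 1  # keep every row non-empty
    for j in range(m):  # keep every column non-empty
        if counts[:, j].sum() == 0:
            counts[int(rng.integers(P)), j] = 1
    d = rng.integers(1, 6, size=(m, m)).astype(float)
    d = np.triu(d, 1)
    d = d + d.T
    tab = HaplotypeTable(counts=pd.DataFrame(
        counts, index=[f"P{i}" for i in range(P)],
        columns=[f"H{j+1}" for j in range(m)]))
    dm = DistanceMatrix(labels=tab.haplotype_ids, values=d)
    return tab, dm


def expand_individuals(tab: HaplotypeTable):
    """(pop index, hap index) per individual, in table order."""
    out = []
    C = tab.counts.values
    for p in range(C.shape[0]):
        for h in range(C.shape[1]):
            out.extend([(p, h)] * int(C[p, h]))
    return out


def brute_hd(counts) -> float:
    """P(two draws without replacement are different haplotypes), by pair
    enumeration — identical to Nei's unbiased Hd."""
    haps = []
    for h, c in enumerate(counts):
        haps.extend([h] * int(c))
    n = len(haps)
    diff = sum(
        1 for i in range(n) for j in range(i + 1, n) if haps[i] != haps[j]
    )
    return diff / (n * (n - 1) / 2)


def brute_k(counts, d) -> float:
    haps = []
    for h, c in enumerate(counts):
        haps.extend([h] * int(c))
    n = len(haps)
    tot = sum(
        d[haps[i], haps[j]] for i in range(n) for j in range(i + 1, n)
    )
    return tot / (n * (n - 1) / 2)


def brute_mismatch(counts, d) -> np.ndarray:
    haps = []
    for h, c in enumerate(counts):
        haps.extend([h] * int(c))
    n = len(haps)
    top = int(d.max())
    freq = np.zeros(top + 1)
    for i in range(n):
        for j in range(i + 1, n):
            freq[int(d[haps[i], haps[j]])] += 1
    return freq / (n * (n - 1) / 2)


def brute_amova_components(tab: HaplotypeTable, d: np.ndarray):
    """AMOVA sums computed from the expanded individual-level distance
    matrix by direct summation."""
    ind = expand_individuals(tab)
    N = len(ind)
    pops = sorted({p for p, _ in ind})
    P = len(pops)
    delta2 = np.array([
        [d[h1, h2] ** 2 for _, h2 in ind] for _, h1 in ind
    ])
    ssd_total = sum(
        delta2[i, j] for i in range(N) for j in range(i + 1, N)
    ) / N
    ssd_within = 0.0
    sizes = []
    for p in pops:
        members = [i for i, (pp, _) in enumerate(ind) if pp == p]
        np_ = len(members)
        sizes.append(np_)
        ssd_within += sum(
            delta2[i, j] for ii, i in enumerate(members)
            for j in members[ii + 1:]
        ) / np_
    ssd_among = ssd_total - ssd_within
    df_among, df_within = P - 1, N - P
    var_b = ssd_within / df_within
    n_prime = (N - sum(s * s for s in sizes) / N) / (P - 1)
    var_a = (ssd_among / df_among - var_b) / n_prime
    phi = var_a / (var_a + var_b) if var_a + var_b > 0 else 0.0
    return dict(ssd_total=ssd_total, ssd_within=ssd_within,
                ssd_among=ssd_among, var_a=var_a, var_b=var_b, phi=phi)
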