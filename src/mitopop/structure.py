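"""Molecular variance partitioning: AMOVA, pairwise Φst, Bonferroni flags.

The analysis of molecular variance partitions squared inter-sequence
distances into among- and within-population components (Excoffier-style
Φ-statistics: the fixation index incorporates haplotype distances, not
just haplotype identity). Significance comes from permuting individuals
among populations with sample sizes held fixed; an add-one correction
keeps permutation p-values away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .errors import MitopopError
from .haplotypes import HaplotypeTable


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    ssd_among: float
    ssd_within: float
    ssd_total: float
    var_a: float
    var_b: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float | None
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d.f.": [self.df_among, self.df_within,
                         self.df_among + self.df_within],
                "sum_of_squares": [self.ssd_among, self.ssd_within,
                                   self.ssd_total],
                "variance_component": [self.var_a, self.var_b,
                                       self.var_a + self.var_b],
                "pct_of_variation": [self.pct_among, self.pct_within, 100.0],
            },
            index=["among_populations", "within_populations", "total"],
        )


@dataclass
class FstMatrix:
    """Pairwise Φst with permutation p-values and Bonferroni flags."""

    labels: list[str]
    phi_st: np.ndarray
    p_values: np.ndarray
    flags: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi_st, index=self.labels, columns=self.labels)

    def p_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p_values, index=self.labels, columns=self.labels)

    def report(self, upper: DistanceMatrix | None = None,
               path: str | Path | None = None) -> str:
        """Φst below the diagonal (with significance asterisks), an optional
        second matrix (e.g. dxy distances) above it."""
        P = len(self.labels)
        cells = [["" for _ in range(P)] for _ in range(P)]
        for i in range(P):
            for j in range(P):
                if i > j:
                    star = ""
                    if self.flags is not None:
                        lab_i, lab_j = self.labels[i], self.labels[j]
                        star = self.flags.at[lab_i, lab_j]
                    cells[i][j] = f"{self.phi_st[i, j]:.4f}{star}"
                elif i < j and upper is not None:
                    cells[i][j] = f"{upper.values[i, j]:.4f}"
        df = pd.DataFrame(cells, index=self.labels, columns=self.labels)
        text = df.to_csv(sep="\t")
        if path is not None:
            Path(path).write_text(text)
        return text


def _squared(d: DistanceMatrix) -> np.ndarray:
    return np.asarray(d.values, dtype=float) ** 2


def _ssd(vec: np.ndarray, d2: np.ndarray) -> float:
    """Sum over unordered pairs of squared distances, count-weighted.

    Within-haplotype pairs contribute zero (zero diagonal), so the quadratic
    form 0.5·vᵀD²v is exactly Σ_{i<j} cᵢcⱼδ²ᵢⱼ.
    """
    return float(0.5 * vec @ d2 @ vec)


def _components(counts: np.ndarray, d2: np.ndarray):
    """Variance components from a populations × haplotypes count matrix."""
    sizes = counts.sum(axis=1)
    N = sizes.sum()
    P = counts.shape[0]
    pooled = counts.sum(axis=0)
    ssd_total = _ssd(pooled, d2) / N
    ssd_within = sum(
        _ssd(counts[p], d2) / sizes[p] for p in range(P) if sizes[p] > 0
    )
    ssd_among = ssd_total - ssd_within
    df_among, df_within = P - 1, int(N - P)
    var_b = ssd_within / df_within if df_within > 0 else 0.0
    n_prime = (N - np.sum(sizes**2) / N) / (P - 1)
    var_a = (ssd_among / df_among - var_b) / n_prime
    total = var_a + var_b
    phi = var_a / total if total > 0 else 0.0
    return ssd_among, ssd_within, ssd_total, var_a, var_b, phi, df_among, df_within


def amova(
    tab: HaplotypeTable,
    d: DistanceMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level AMOVA over the table's populations.

    Requires ≥2 populations and N ≥ 3. The permutation p-value is the
    add-one-corrected fraction of permutations whose Φst is at least the
    observed one; pass ``n_perm=0`` to skip the test.
    """
    if list(d.labels) != tab.haplotype_ids:
        raise MitopopError("distance labels disagree with table haplotypes")
    C = tab.counts.values.astype(int)
    if C.shape[0] < 2:
        raise MitopopError("AMOVA needs at least two populations")
    if C.sum() < 3:
        raise MitopopError("AMOVA needs at least three individuals")
    d2 = _squared(d)
    (ssd_a, ssd_w, ssd_t, var_a, var_b, phi,
     df_a, df_w) = _components(C, d2)
    total = var_a + var_b
    pct_among = 100.0 * var_a / total if total > 0 else 0.0
    p = None
    if n_perm > 0:
        p = _permutation_p(C, d2, phi, n_perm, seed)
    return AmovaResult(
        df_among=df_a, df_within=df_w,
        ssd_among=ssd_a, ssd_within=ssd_w, ssd_total=ssd_t,
        var_a=var_a, var_b=var_b,
        pct_among=pct_among, pct_within=100.0 - pct_among,
        phi_st=phi, p_value=p, n_perm=n_perm,
    )


def _permutation_p(
    C: np.ndarray, d2: np.ndarray, phi_obs: float,
    n_perm: int, seed: int | None
) -> float:
    rng = np.random.default_rng(seed)
    sizes = C.sum(axis=1)
    m = C.shape[1]
    # individual-level haplotype assignment vector
    h = np.repeat(
        np.tile(np.arange(m), C.shape[0]), C.ravel()
    )
    bounds = np.cumsum(sizes)[:-1]
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(h)
        groups = np.split(h, bounds)
        Cp = np.stack([np.bincount(g, minlength=m) for g in groups])
        phi_p = _components(Cp, d2)[5]
        if phi_p >= phi_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def pairwise_phist(
    tab: HaplotypeTable,
    d: DistanceMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> FstMatrix:
    """Φst for every population pair via two-population AMOVA.

    Each pair gets its own permutation test; the Bonferroni flags mark
    pairs significant at the adjusted 0.05 (*) and 0.01 (**) levels across
    the C(P,2) comparisons.
    """
    pops = tab.populations
    P = len(pops)
    if P < 2:
        raise MitopopError("need at least two populations")
    rng = np.random.default_rng(seed)
    phi = np.zeros((P, P))
    pvals = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            sub_counts = tab.counts.iloc[[i, j]]
            present = sub_counts.sum(axis=0) > 0
            sub = HaplotypeTable(counts=sub_counts.loc[:, present])
            idx = np.flatnonzero(present.values)
            sub_d = DistanceMatrix(
                labels=[tab.haplotype_ids[k] for k in idx],
                values=d.values[np.ix_(idx, idx)],
                metric_tag=d.metric_tag,
            )
            pair_seed = int(rng.integers(2**31)) if n_perm > 0 else None
            res = amova(sub, sub_d, n_perm=n_perm, seed=pair_seed)
            phi[i, j] = phi[j, i] = res.phi_st
            pvals[i, j] = pvals[j, i] = res.p_value if res.p_value is not None else np.nan
    flags = bonferroni_flags(
        pd.DataFrame(pvals, index=pops, columns=pops), alpha=alpha
    ) if n_perm > 0 else None
    return FstMatrix(labels=pops, phi_st=phi, p_values=pvals, flags=flags)


def bonferroni_flags(p_matrix: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Two-tier significance flags after Bonferroni correction.

    With m pairwise tests, ``*`` marks p < alpha/m and ``**`` marks
    p < (alpha/5)/m (i.e. the 0.01 tier when alpha is 0.05).
    """
    P = p_matrix.shape[0]
    m = P * (P - 1) // 2
    if m < 1:
        raise MitopopError("need at least one pairwise test")
    t1, t2 = alpha / m, (alpha / 5.0) / m
    flags = p_matrix.map(
        lambda p: "**" if p < t2 else ("*" if p < t1 else "")
    )
    np.fill_diagonal(flags.values, "")
    return flags
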