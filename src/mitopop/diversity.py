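"""Nei's within-population diversity indices.

Three quantities are reported per group: haplotype diversity Hd (the
unbiased probability that two sequences drawn without replacement carry
different haplotypes, with the n/(n−1) small-sample correction), the mean
number of pairwise nucleotide differences k, and the nucleotide diversity
π = k/L per analysed site.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, haplotype_distance_matrix
from .errors import MitopopError, UndefinedStatisticError
from .haplotypes import HaplotypeTable, SiteReport, segregating_sites
from .io import Alignment


@dataclass
class DiversityStats:
    """Per-group summary: n, haplotypes, S, Hd, k and π."""

    n: int
    num_haplotypes: int
    S: int | None
    Hd: float
    k_mean: float | None
    pi: float | None


def haplotype_diversity(counts) -> float:
    """Nei's unbiased haplotype (gene) diversity.

    Hd = n/(n−1) · (1 − Σ pᵢ²) with pᵢ the haplotype relative frequencies.
    Undefined for n < 2.
    """
    c = np.asarray(list(counts), dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise UndefinedStatisticError(f"haplotype diversity undefined at n={n:g}")
    p = c / n
    return float(n / (n - 1) * (1.0 - np.sum(p * p)))


def mean_pairwise_differences(counts, d: DistanceMatrix | np.ndarray) -> float:
    """Mean pairwise distance k over all C(n,2) unordered sequence pairs.

    Pairs within the same haplotype contribute distance zero but count in
    the denominator.
    """
    c = np.asarray(list(counts), dtype=float)
    dm = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    if dm.shape != (c.size, c.size):
        raise MitopopError(
            f"distance matrix {dm.shape} does not match {c.size} haplotypes"
        )
    n = c.sum()
    if n < 2:
        raise UndefinedStatisticError(f"mean pairwise differences undefined at n={n:g}")
    pairs = n * (n - 1) / 2.0
    return float(0.5 * c @ dm @ c / pairs)


def nucleotide_diversity(k_mean: float, L: int) -> float:
    """π = k/L, diversity per analysed site."""
    if L < 1:
        raise MitopopError("analysed length must be at least 1")
    return k_mean / L


def _group_stats(
    counts: pd.Series,
    d: DistanceMatrix | None,
    L: int | None,
    seqs: dict[str, str] | None,
) -> DiversityStats:
    present = counts[counts > 0]
    n = int(counts.sum())
    Hd = haplotype_diversity(counts.values)
    k = pi = S = None
    if d is not None:
        k = mean_pairwise_differences(counts.values, d)
        if L is not None:
            pi = nucleotide_diversity(k, L)
    if seqs is not None:
        sub = Alignment(
            ids=list(present.index),
            seqs=[seqs[h] for h in present.index],
            population_of={h: "x" for h in present.index},
        )
        S = segregating_sites(sub).S
    return DiversityStats(
        n=n, num_haplotypes=int((counts > 0).sum()), S=S, Hd=Hd, k_mean=k, pi=pi
    )


def diversity_summary(
    tab: HaplotypeTable,
    d: DistanceMatrix | None = None,
    L: int | None = None,
) -> pd.DataFrame:
    """Diversity statistics per population, per basin and pooled.

    ``d`` is a haplotype distance matrix in substitution counts (built from
    the table's sequences when omitted and sequences are present); ``L`` the
    analysed alignment length. S and k/π require sequences/distances and are
    left missing on counts-only tables.
    """
    if d is None and tab.sequences is not None:
        d = haplotype_distance_matrix(tab, model="diff_count")
    if d is not None and list(d.labels) != tab.haplotype_ids:
        raise MitopopError("distance matrix labels disagree with table haplotypes")
    if L is None and tab.sequences is not None:
        L = len(next(iter(tab.sequences.values())))
    rows: dict[str, DiversityStats] = {}
    for pop in tab.populations:
        rows[pop] = _group_stats(tab.counts.loc[pop], d, L, tab.sequences)
    if tab.basin_of is not None:
        bc = tab.basin_counts()
        for basin in bc.index:
            rows[f"basin:{basin}"] = _group_stats(bc.loc[basin], d, L, tab.sequences)
    rows["all"] = _group_stats(tab.pooled_counts(), d, L, tab.sequences)
    df = pd.DataFrame(
        {
            "n": {g: s.n for g, s in rows.items()},
            "num_haplotypes": {g: s.num_haplotypes for g, s in rows.items()},
            "S": {g: s.S for g, s in rows.items()},
            "Hd": {g: s.Hd for g, s in rows.items()},
            "k": {g: s.k_mean for g, s in rows.items()},
            "pi": {g: s.pi for g, s in rows.items()},
        }
    )
    df.index.name = "group"
    return df


def diversity_report(df: pd.DataFrame, path: str | Path | None = None) -> str:
    """TSV report with the conventional rounding (Hd/k to 3, π to 4 decimals)."""
    out = df.copy()
    out["Hd"] = out["Hd"].map(lambda x: f"{x:.3f}")
    for col, nd in (("k", 3), ("pi", 4)):
        out[col] = out[col].map(
            lambda x: "" if pd.isna(x) else f"{x:.{nd}f}"
        )
    text = out.to_csv(sep="\t")
    if path is not None:
        Path(path).write_text(text)
    return text
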