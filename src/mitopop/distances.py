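"""Pairwise distances among haplotypes and among populations.

Three sequence-level metrics are provided: raw substitution counts
(``diff_count``, the Hamming distance), the proportion of differing sites
(``p``) and the Kimura 2-parameter correction (``k2p``), which treats
transitions (A↔G, C↔T) and transversions separately. Population-level
distances are count-weighted means over sequence pairs: ``dxy`` (mean
between-population distance) and ``da`` (net distance, dxy minus the mean
of the within-population means).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, MitopopError, SaturationError
from .haplotypes import HaplotypeTable

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with labelled entities."""

    labels: list[str]
    values: np.ndarray
    metric_tag: str = "diff_count"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise MitopopError("distance matrix shape disagrees with labels")
        if not np.allclose(v, v.T):
            raise MitopopError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise MitopopError("distance matrix diagonal is not zero")
        if (v < 0).any():
            raise MitopopError("negative distances")
        self.values = v

    def loc(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_tsv(self, path: str | Path | None = None) -> str:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        text = df.to_csv(sep="\t")
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_phylip(self, path: str | Path | None = None) -> str:
        lines = [f"    {len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab.ljust(10) + "  ".join(f"{x:.6f}" for x in row))
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def _check_pair(seq_a: str, seq_b: str) -> None:
    if len(seq_a) != len(seq_b):
        raise AlignmentError(
            f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )


def pairwise_difference_count(seq_a: str, seq_b: str) -> int:
    """Hamming distance: number of columns at which the sequences differ."""
    _check_pair(seq_a, seq_b)
    return sum(a != b for a, b in zip(seq_a, seq_b))


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing sites."""
    _check_pair(seq_a, seq_b)
    return pairwise_difference_count(seq_a, seq_b) / len(seq_a)


def transition_transversion_counts(seq_a: str, seq_b: str) -> tuple[int, int]:
    _check_pair(seq_a, seq_b)
    ts = tv = 0
    for a, b in zip(seq_a, seq_b):
        if a == b:
            continue
        if (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES):
            ts += 1
        else:
            tv += 1
    return ts, tv


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura 2-parameter distance.

    d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q), with P and Q the transition and
    transversion proportions. Raises :class:`SaturationError` when a log
    argument is non-positive.
    """
    ts, tv = transition_transversion_counts(seq_a, seq_b)
    L = len(seq_a)
    P, Q = ts / L, tv / L
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P correction undefined at P={P:.4f}, Q={Q:.4f} (saturated)"
        )
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


_SEQ_METRICS = {
    "diff_count": pairwise_difference_count,
    "p": p_distance,
    "k2p": k2p_distance,
}


def haplotype_distance_matrix(
    tab: HaplotypeTable, model: str = "diff_count"
) -> DistanceMatrix:
    """All-pairs distances among the table's haplotype sequences."""
    if tab.sequences is None:
        raise MitopopError("haplotype sequences required for distances")
    if model not in _SEQ_METRICS:
        raise ValueError(f"unknown distance model {model!r}")
    fn = _SEQ_METRICS[model]
    hids = tab.haplotype_ids
    m = len(hids)
    d = np.zeros((m, m))
    if model == "diff_count":
        mat = np.frombuffer(
            "".join(tab.sequences[h] for h in hids).encode(), dtype="S1"
        ).reshape(m, -1)
        d = (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(float)
    else:
        for i in range(m):
            for j in range(i + 1, m):
                d[i, j] = d[j, i] = fn(
                    tab.sequences[hids[i]], tab.sequences[hids[j]]
                )
    return DistanceMatrix(labels=hids, values=d, metric_tag=model)


def within_population_mean_distance(
    counts: np.ndarray, d: np.ndarray
) -> float:
    """Mean distance over all unordered pairs within one population.

    ``counts`` are per-haplotype counts; identical-haplotype pairs contribute
    zero distance but do enter the pair total.
    """
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n < 2:
        return 0.0
    pairs = n * (n - 1) / 2.0
    return float(0.5 * c @ d @ c / pairs)


def population_distance_matrix(
    tab: HaplotypeTable, model: str = "k2p", kind: str = "dxy"
) -> DistanceMatrix:
    """Count-weighted dxy or da distances among populations.

    dxy(X,Y) averages the model distance over every between-population
    sequence pair; da subtracts the mean of the two within-population means
    and is clamped at zero (sampling noise can push it slightly negative).
    """
    if kind not in ("dxy", "da"):
        raise ValueError(f"unknown population distance kind {kind!r}")
    hd = haplotype_distance_matrix(tab, model=model)
    d = hd.values
    pops = tab.populations
    C = tab.counts.values.astype(float)
    sizes = C.sum(axis=1)
    P = len(pops)
    out = np.zeros((P, P))
    pis = np.array([
        within_population_mean_distance(C[i], d) for i in range(P)
    ])
    clamped = False
    for i in range(P):
        for j in range(i + 1, P):
            dxy = float(C[i] @ d @ C[j] / (sizes[i] * sizes[j]))
            if kind == "da":
                val = dxy - 0.5 * (pis[i] + pis[j])
                if val < 0:
                    clamped = True
                    val = 0.0
            else:
                val = dxy
            out[i, j] = out[j, i] = val
    if clamped:
        warnings.warn("negative da values clamped to 0", stacklevel=2)
    return DistanceMatrix(labels=pops, values=out, metric_tag=kind)
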