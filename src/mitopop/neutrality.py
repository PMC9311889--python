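"""Neutrality statistics: Tajima's D and Fu's Fs.

Tajima's D contrasts the π-based and S-based estimates of θ; Fu's Fs is
the logit of the Ewens-sampling-formula probability of seeing at least as
many haplotypes as observed given θ̂ = k (the π-based plug-in, the
conventional choice). Both go strongly negative after a demographic
expansion. Ewens probabilities use unsigned Stirling numbers of the first
kind, carried in log space so sample sizes of a few hundred are exact
enough.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MitopopError, UndefinedStatisticError


@dataclass
class NeutralityStats:
    n: int
    S: int
    k_mean: float
    theta_w: float
    tajima_d: float
    fu_fs: float
    K_obs: int
    d_p: float | None = None
    fs_p: float | None = None


def tajima_constants(n: int) -> dict[str, float]:
    """The a1…e2 normalising constants of Tajima's test."""
    if n < 2:
        raise MitopopError("need n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def watterson_theta(n: int, S: int) -> float:
    """θ̂_W = S/a1 (per sequence)."""
    return S / tajima_constants(n)["a1"]


def tajimas_d(n: int, S: int, k_mean: float) -> float:
    """Tajima's D = (k − S/a1) / sqrt(e1·S + e2·S·(S−1)).

    Undefined (raises) at S = 0: no segregating variation means the
    statistic has a zero denominator, which is distinct from D = 0.
    """
    if n < 4:
        raise MitopopError("Tajima's D needs n >= 4")
    if S < 1:
        raise UndefinedStatisticError("Tajima's D undefined at S = 0")
    c = tajima_constants(n)
    denom = math.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    return (k_mean - S / c["a1"]) / denom


def log_stirling_first_kind(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0…n (−inf where the number is zero).

    Built by the row recurrence |s(n+1,k)| = n·|s(n,k)| + |s(n,k−1)| in log
    space (logaddexp), which is overflow-safe for n in the hundreds.
    """
    row = np.full(n + 1, -np.inf)
    row[min(1, n)] = 0.0  # |s(1,1)| = 1 (and |s(0,0)| = 1)
    if n == 0:
        row[0] = 0.0
        return row
    for m in range(1, n):
        new = np.full(n + 1, -np.inf)
        shifted = np.concatenate(([-np.inf], row[:-1]))
        new = np.logaddexp(math.log(m) + row, shifted)
        row = new
    return row


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(K = k | θ, n) for k = 0…n under the Ewens sampling formula."""
    if theta <= 0:
        raise MitopopError("theta must be positive")
    ls = log_stirling_first_kind(n)
    k = np.arange(n + 1)
    log_denom = float(np.sum(np.log(theta + np.arange(n))))
    with np.errstate(divide="ignore"):
        logp = ls + k * math.log(theta) - log_denom
    return logp


def fus_fs(n: int, theta: float, K_obs: int) -> float:
    """Fu's Fs = ln(S′/(1−S′)) with S′ = Pr(K ≥ K_obs | θ, n).

    θ is normally the mean pairwise difference k. K_obs = 1 gives S′ = 1 and
    the statistic is −∞-free only formally: +inf is returned as the
    "cannot reject anything" signal.
    """
    if not 1 <= K_obs <= n:
        raise MitopopError(f"K_obs must lie in 1..{n}")
    if K_obs == 1:
        return math.inf
    logp = ewens_log_pmf(n, theta)
    from scipy.special import logsumexp

    log_sp = float(logsumexp(logp[K_obs:]))
    log_one_minus = float(logsumexp(logp[:K_obs]))
    return log_sp - log_one_minus


def neutrality_tests(
    n: int, S: int, k_mean: float, K_obs: int
) -> NeutralityStats:
    """Bundle D and Fs (without p-values) from summary statistics."""
    return NeutralityStats(
        n=n, S=S, k_mean=k_mean,
        theta_w=watterson_theta(n, S),
        tajima_d=tajimas_d(n, S, k_mean),
        fu_fs=fus_fs(n, k_mean, K_obs) if k_mean > 0 else math.inf,
        K_obs=K_obs,
    )


def neutrality_pvalues(
    stats: NeutralityStats,
    n_rep: int = 1000,
    seed: int | None = None,
    L_seq: int = 647,
) -> NeutralityStats:
    """Coalescent p-values: Pr(statistic_sim ≤ statistic_obs) under a
    constant-size history with θ = θ̂_W, estimated from ``n_rep`` seeded
    replicates (one-tailed toward expansion-like values)."""
    from . import simulate as sim
    from .diversity import mean_pairwise_differences
    from .distances import haplotype_distance_matrix
    from .haplotypes import collapse_haplotypes, segregating_sites

    rng = np.random.default_rng(seed)
    d_hits = fs_hits = d_tot = fs_tot = 0
    cfg = sim.SimConfig(
        scenario="constant", n_per_pop=(stats.n,),
        theta=max(stats.theta_w, 1e-3), L_seq=L_seq,
    )
    for _ in range(n_rep):
        aln = sim.simulate_dataset(cfg, seed=int(rng.integers(2**31)))[0]
        tab = collapse_haplotypes(aln)
        rep = segregating_sites(aln)
        if rep.S == 0:
            continue
        d = haplotype_distance_matrix(tab, model="diff_count")
        k = mean_pairwise_differences(tab.pooled_counts().values, d)
        d_tot += 1
        if tajimas_d(stats.n, rep.S, k) <= stats.tajima_d:
            d_hits += 1
        if k > 0:
            fs_tot += 1
            if fus_fs(stats.n, k, len(tab.haplotype_ids)) <= stats.fu_fs:
                fs_hits += 1
    stats.d_p = (d_hits + 1) / (d_tot + 1) if d_tot else None
    stats.fs_p = (fs_hits + 1) / (fs_tot + 1) if fs_tot else None
    return stats


def neutrality_report(rows: dict[str, NeutralityStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            g: {
                "n": s.n, "S": s.S, "k": s.k_mean, "theta_w": s.theta_w,
                "D": s.tajima_d, "D_p": s.d_p, "Fs": s.fu_fs, "Fs_p": s.fs_p,
            }
            for g, s in rows.items()
        }
    ).T
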