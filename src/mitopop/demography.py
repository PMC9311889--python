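"""Mismatch distributions, sudden-expansion fitting and expansion dating.

The mismatch distribution is the frequency spectrum of pairwise
difference counts. Under a sudden demographic expansion it is a smooth
unimodal wave whose position τ measures the expansion age in mutational
time units (τ = 2ut generations). Two model tiers are fitted by least
squares: a pure-expansion Poisson wave (the θ0→0, θ1→∞ limit, closed-form
testable) and the full three-parameter sudden-expansion model with
pre-/post-expansion θ0 and θ1 (the Arlequin-style default, tagged
``rh92``). τ converts to years via t = T·τ/(2·µ·k) with T the generation
time, µ the per-site per-generation mutation rate and k the fragment
length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln

from .distances import DistanceMatrix
from .errors import MitopopError
from .haplotypes import HaplotypeTable


@dataclass
class MismatchFit:
    observed: np.ndarray
    expected: np.ndarray
    tau: float
    theta0: float
    theta1: float
    ssd: float
    model_tag: str
    warning: str | None = field(default=None)


@dataclass
class ExpansionTime:
    tau: float
    mu: float          # mutation rate per nucleotide per generation
    L_seq: int         # fragment length (sites)
    T: float = 1.0     # generation time in years
    t_years: float = field(init=False)
    t_mya: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.tau, self.mu, self.L_seq, self.T) <= 0:
            raise MitopopError("all expansion-time inputs must be positive")
        self.t_years = self.T * self.tau / (2.0 * self.mu * self.L_seq)
        self.t_mya = self.t_years / 1e6


def mismatch_observed(
    tab: HaplotypeTable, d: DistanceMatrix, i_max: int | None = None
) -> np.ndarray:
    """Observed mismatch frequencies over the pooled sample.

    Count-weighted over all C(n,2) unordered sequence pairs; pairs within
    one haplotype sit at zero differences. ``d`` must be in substitution
    counts. The vector sums to 1.
    """
    if list(d.labels) != tab.haplotype_ids:
        raise MitopopError("distance labels disagree with table haplotypes")
    c = tab.pooled_counts().values.astype(float)
    n = c.sum()
    if n < 2:
        raise MitopopError("need at least two sequences")
    dm = np.rint(d.values).astype(int)
    top = int(dm.max()) if i_max is None else i_max
    freq = np.zeros(top + 1)
    freq[0] += np.sum(c * (c - 1) / 2.0)
    m = len(c)
    for i in range(m):
        for j in range(i + 1, m):
            freq[min(dm[i, j], top)] += c[i] * c[j]
    return freq / (n * (n - 1) / 2.0)


def equilibrium_mismatch(theta: float, i_max: int) -> np.ndarray:
    """Stationary mismatch law F̂_i(θ) = θ^i/(θ+1)^(i+1) (geometric)."""
    i = np.arange(i_max + 1, dtype=float)
    if theta == 0:
        out = np.zeros(i_max + 1)
        out[0] = 1.0
        return out
    # log-space to stay finite for large theta and i
    return np.exp(i * math.log(theta) - (i + 1) * math.log(theta + 1.0))


def expected_mismatch(
    model: str, tau: float, theta0: float = 0.0,
    theta1: float = float("inf"), i_max: int = 30
) -> np.ndarray:
    """Model mismatch distribution over difference counts 0…i_max.

    ``poisson``: F_i = e^(−τ)·τ^i/i!. ``rh92``: the sudden-expansion
    closed form F_i = F̂_i(θ1) + e^(−τ(θ1+1)/θ1)·Σ_j (F̂_j(θ0)−F̂_j(θ1))·
    τ^(i−j)/(i−j)!, which reduces to the equilibrium law at τ=0 and to the
    Poisson wave as θ0→0, θ1→∞.
    """
    if i_max < 1:
        raise MitopopError("i_max must be >= 1")
    if tau < 0 or theta0 < 0 or theta1 < 0:
        raise MitopopError("parameters must be non-negative")
    i = np.arange(i_max + 1)
    if model == "poisson":
        if tau == 0:
            out = np.zeros(i_max + 1)
            out[0] = 1.0
            return out
        return np.exp(-tau + i * math.log(tau) - gammaln(i + 1))
    if model != "rh92":
        raise ValueError(f"unknown mismatch model {model!r}")
    if theta1 < theta0:
        raise MitopopError("theta1 must be >= theta0")
    f1 = (equilibrium_mismatch(theta1, i_max)
          if math.isfinite(theta1) else np.zeros(i_max + 1))
    f0 = equilibrium_mismatch(theta0, i_max)
    diff = f0 - f1
    if tau == 0:
        conv = diff
        damp = 1.0
    else:
        # kernel[t] = tau^t / t!
        kernel = np.exp(i * math.log(tau) - gammaln(i + 1))
        conv = np.array([
            np.sum(diff[: m + 1] * kernel[m::-1]) for m in range(i_max + 1)
        ])
        rate = (theta1 + 1.0) / theta1 if math.isfinite(theta1) else 1.0
        damp = math.exp(-tau * rate)
    out = f1 + damp * conv
    return np.clip(out, 0.0, None)  # roundoff-level negatives


def tau_mode(observed: np.ndarray) -> int:
    """Integer mode of the observed mismatch distribution (the crude
    τ estimator some workflows quote)."""
    return int(np.argmax(observed))


def fit_expansion(
    observed: np.ndarray,
    model: str = "rh92",
    bounds: tuple[float, float] | None = None,
    seed: int | None = None,
) -> MismatchFit:
    """Least-squares sudden-expansion fit to an observed mismatch vector.

    Minimises Σ(observed − expected)² by a coarse deterministic grid plus
    local refinement; identical inputs give identical fits. A degenerate
    observed vector (all mass at zero differences) returns the τ = 0
    boundary with a warning note.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or obs.size < 2 or obs.min() < 0:
        raise MitopopError("observed must be a frequency vector of length >= 2")
    if not math.isclose(obs.sum(), 1.0, abs_tol=1e-6):
        raise MitopopError("observed frequencies must sum to 1")
    i_max = obs.size - 1
    i = np.arange(obs.size)
    mean_d = float(np.sum(i * obs))
    if mean_d == 0:
        exp0 = expected_mismatch(model, 0.0, 0.0, max(mean_d, 1.0), i_max)
        return MismatchFit(
            observed=obs, expected=exp0, tau=0.0, theta0=0.0,
            theta1=max(mean_d, 1.0), ssd=float(np.sum((obs - exp0) ** 2)),
            model_tag=model, warning="degenerate observed: all mass at zero",
        )
    hi = bounds[1] if bounds else max(4.0 * mean_d, 2.0)
    lo = bounds[0] if bounds else 0.0

    if model == "poisson":
        def loss(tau: float) -> float:
            return float(np.sum(
                (obs - expected_mismatch("poisson", tau, i_max=i_max)) ** 2
            ))
        res = minimize_scalar(loss, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-8})
        tau = float(res.x)
        exp_v = expected_mismatch("poisson", tau, i_max=i_max)
        return MismatchFit(observed=obs, expected=exp_v, tau=tau, theta0=0.0,
                           theta1=math.inf, ssd=float(res.fun),
                           model_tag="poisson")

    def loss3(x: np.ndarray) -> float:
        tau, th0, dth = x
        return float(np.sum(
            (obs - expected_mismatch("rh92", tau, th0, th0 + dth, i_max)) ** 2
        ))

    best = None
    for tau0 in np.linspace(max(lo, 0.05), hi, 4):
        for th0 in (0.0, 0.25 * mean_d):
            for dth in (mean_d, 20 * mean_d, 1000.0):
                x0 = np.array([tau0, th0, dth])
                r = minimize(
                    loss3, x0, method="L-BFGS-B",
                    bounds=[(lo, hi), (0.0, 10 * mean_d), (1e-6, 1e7)],
                )
                if best is None or r.fun < best.fun:
                    best = r
    tau, th0, dth = best.x
    exp_v = expected_mismatch("rh92", tau, th0, th0 + dth, i_max)
    return MismatchFit(
        observed=obs, expected=exp_v, tau=float(tau), theta0=float(th0),
        theta1=float(th0 + dth), ssd=float(best.fun), model_tag="rh92",
    )


def expansion_time(
    tau: float, mu: float, L_seq: int, T: float = 1.0
) -> ExpansionTime:
    """Convert τ to years: t = T·τ/(2·µ·k) with k = fragment length."""
    return ExpansionTime(tau=tau, mu=mu, L_seq=L_seq, T=T)
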