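"""Coalescent generator of aligned haploid mtDNA datasets with known truth.

Three demographic scenarios are supported, chosen to bracket the regimes a
low-diversity mtDNA survey meets in practice:

* ``constant`` — a single panmictic population of constant size (the
  Kingman coalescent; time in units of 2N generations, so a sample pair
  has expected coalescence time 1).
* ``expansion`` — sudden growth: looking back, lineages coalesce at the
  present-day rate until ``tau_true/theta`` coalescent units ago, then at
  the ancestral rate inflated by ``theta/theta0``. The truth record keeps
  the expansion age in mutational units (τ = θ1·t_change), the scale the
  mismatch-fitting module estimates.
* ``island`` — a symmetric n-deme island model; each lineage migrates at
  rate M/2 per coalescent unit and may only coalesce within its deme.

Mutations follow the infinite-sites model dropped onto a finite 647 bp
fragment: Poisson(θ/2 × branch length) mutations per branch, each at a
fresh uniformly chosen column (collisions resample), with
transition-biased base changes (4:1 by default) over a realistic mtDNA
base composition. θ is the 4Nµ-scaled mutation parameter per sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import SimulationError
from .io import Alignment, write_alignment

#: COI-like base composition (A, C, G, T) used for ancestral sequences.
DEFAULT_BASE_COMPOSITION = (0.26, 0.19, 0.33, 0.22)
_BASES = np.frombuffer(b"ACGT", dtype="S1")
#: transition partner of each base (A<->G, C<->T), indexed as A,C,G,T
_TRANSITION = {0: 2, 1: 3, 2: 0, 3: 1}


@dataclass
class SimConfig:
    """Scenario and parameters of one synthetic dataset.

    ``theta`` is the present-day per-sequence θ (θ1 under expansion);
    ``theta0``/``tau_true`` only apply to the expansion scenario and ``M``
    (the scaled migration rate) only to the island model, where ``n_per_pop``
    gives one sample size per deme.
    """

    scenario: str = "constant"
    n_per_pop: tuple[int, ...] = (20,)
    theta: float = 5.0
    theta0: float = 0.05
    tau_true: float = 2.0
    M: float = 10.0
    L_seq: int = 647
    base_composition: tuple[float, float, float, float] = DEFAULT_BASE_COMPOSITION
    transition_fraction: float = 0.8  # 4:1 transition:transversion
    pop_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.scenario not in ("constant", "expansion", "island"):
            raise SimulationError(f"unknown scenario {self.scenario!r}")
        if any(n < 1 for n in self.n_per_pop) or sum(self.n_per_pop) < 2:
            raise SimulationError("need at least two sampled sequences")
        if min(self.theta, self.M, self.L_seq) < 0 or self.theta0 < 0:
            raise SimulationError("rates and sizes must be non-negative")
        if self.scenario == "expansion" and self.theta0 <= 0:
            raise SimulationError("expansion needs theta0 > 0")
        if self.scenario != "island" and len(self.n_per_pop) > 1:
            # multi-population sampling without structure is allowed: the
            # labels partition an exchangeable sample (a null for Phi-st).
            pass

    @property
    def labels(self) -> tuple[str, ...]:
        if self.pop_labels is not None:
            return self.pop_labels
        return tuple(f"P{i+1}" for i in range(len(self.n_per_pop)))


def study_shape_config(**overrides) -> SimConfig:
    """Preset mirroring the data shape of a typical multi-basin mtDNA
    survey: 11 populations, 197 sequences in total, 647 bp, low diversity
    (pooled mean pairwise differences near 1)."""
    base = dict(
        scenario="island",
        n_per_pop=(10, 10, 10, 10, 31, 10, 9, 30, 23, 24, 30),
        theta=1.2,
        M=10.0,
        L_seq=647,
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class Genealogy:
    """A coalescent tree: per-node parent pointers and branch lengths.

    Nodes 0..n−1 are leaves; the root's parent is −1. ``leaf_sets`` caches
    the leaves below each node for fast mutation application.
    """

    n: int
    parent: np.ndarray
    blen: np.ndarray
    leaf_sets: list[np.ndarray]

    @property
    def total_length(self) -> float:
        return float(self.blen[:-1].sum())

    @property
    def tmrca(self) -> float:
        # root time equals any leaf-to-root path length
        t, node = 0.0, 0
        while self.parent[node] != -1:
            t += self.blen[node]
            node = self.parent[node]
        return t


def _finish_tree(n: int, node_time: list[float], merges: list[tuple[int, int, int]]
                 ) -> Genealogy:
    total = 2 * n - 1
    parent = np.full(total, -1, dtype=int)
    blen = np.zeros(total)
    leaf_sets: list[np.ndarray] = [np.array([i]) for i in range(n)]
    for new, a, b in merges:
        parent[a] = parent[b] = new
        blen[a] = node_time[new] - node_time[a]
        blen[b] = node_time[new] - node_time[b]
        leaf_sets.append(np.concatenate((leaf_sets[a], leaf_sets[b])))
    return Genealogy(n=n, parent=parent, blen=blen, leaf_sets=leaf_sets)


def simulate_genealogy(config: SimConfig, rng: np.random.Generator) -> Genealogy:
    """Draw one random genealogy of the configured sample."""
    n = sum(config.n_per_pop)
    if config.scenario == "island" and len(config.n_per_pop) > 1:
        return _island_genealogy(config, rng)
    # unstructured (constant or expansion): piecewise-constant rate
    t_change = (config.tau_true / config.theta
                if config.scenario == "expansion" else np.inf)
    growth = (config.theta / config.theta0
              if config.scenario == "expansion" else 1.0)
    active = list(range(n))
    node_time = [0.0] * n
    merges: list[tuple[int, int, int]] = []
    t = 0.0
    next_node = n
    while len(active) > 1:
        k = len(active)
        rate_mult = 1.0 if t < t_change else growth
        w = rng.exponential(1.0 / (k * (k - 1) / 2.0 * rate_mult))
        if t < t_change < t + w:
            t = t_change  # size change: restart the exponential clock
            continue
        t += w
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        active[j] = next_node
        active.pop(i)
        node_time.append(t)
        merges.append((next_node, a, b))
        next_node += 1
    return _finish_tree(n, node_time, merges)


def _island_genealogy(config: SimConfig, rng: np.random.Generator) -> Genealogy:
    n = sum(config.n_per_pop)
    P = len(config.n_per_pop)
    deme_of: list[int] = []
    for d, nd in enumerate(config.n_per_pop):
        deme_of.extend([d] * nd)
    active = list(range(n))
    lin_deme = list(deme_of)
    node_time = [0.0] * n
    merges: list[tuple[int, int, int]] = []
    t = 0.0
    next_node = n
    while len(active) > 1:
        per_deme: dict[int, list[int]] = {}
        for idx, node in enumerate(active):
            per_deme.setdefault(lin_deme[idx], []).append(idx)
        coal_rate = sum(
            len(v) * (len(v) - 1) / 2.0 for v in per_deme.values()
        )
        mig_rate = len(active) * config.M / 2.0
        total = coal_rate + mig_rate
        if total == 0:
            raise SimulationError("isolated lineages cannot coalesce (M=0)")
        t += rng.exponential(1.0 / total)
        if rng.random() < coal_rate / total:
            demes = [d for d, v in per_deme.items() if len(v) >= 2]
            weights = np.array([
                len(per_deme[d]) * (len(per_deme[d]) - 1) / 2.0 for d in demes
            ])
            d = demes[rng.choice(len(demes), p=weights / weights.sum())]
            i, j = sorted(rng.choice(len(per_deme[d]), size=2, replace=False))
            ii, jj = per_deme[d][i], per_deme[d][j]
            a, b = active[ii], active[jj]
            active[jj] = next_node
            lin_deme[jj] = d
            active.pop(ii)
            lin_deme.pop(ii)
            node_time.append(t)
            merges.append((next_node, a, b))
            next_node += 1
        else:
            idx = int(rng.integers(len(active)))
            others = [d for d in range(P) if d != lin_deme[idx]]
            lin_deme[idx] = others[int(rng.integers(len(others)))]
    return _finish_tree(n, node_time, merges)


def drop_mutations(
    gen: Genealogy,
    theta: float,
    L_seq: int,
    rng: np.random.Generator,
    base_composition: tuple[float, ...] = DEFAULT_BASE_COMPOSITION,
    transition_fraction: float = 0.8,
) -> np.ndarray:
    """Place infinite-sites mutations on the genealogy; return the (n, L)
    base-index matrix (0..3 coding A,C,G,T).

    Each branch receives Poisson(θ/2 × length) mutations; every mutation
    occupies a previously untouched column (uniform draw, resampled on
    collision), so no column mutates twice and S equals the mutation count.
    """
    comp = np.asarray(base_composition, dtype=float)
    comp = comp / comp.sum()
    root = rng.choice(4, size=L_seq, p=comp)
    mat = np.tile(root, (gen.n, 1))
    used: set[int] = set()
    n_nodes = len(gen.parent)
    for node in range(n_nodes - 1):  # root has no branch
        nmut = rng.poisson(theta / 2.0 * gen.blen[node])
        for _ in range(nmut):
            if len(used) >= L_seq:
                raise SimulationError(
                    f"all {L_seq} sites mutated; increase L_seq"
                )
            site = int(rng.integers(L_seq))
            while site in used:
                site = int(rng.integers(L_seq))
            used.add(site)
            old = int(root[site])
            if rng.random() < transition_fraction:
                new = _TRANSITION[old]
            else:
                choices = [b for b in range(4) if b != old and b != _TRANSITION[old]]
                new = choices[int(rng.integers(2))]
            mat[gen.leaf_sets[node], site] = new
    return mat


def simulate_dataset(
    config: SimConfig, seed: int | None = None
) -> tuple[Alignment, dict]:
    """One complete dataset: alignment plus the ground-truth record."""
    rng = np.random.default_rng(seed)
    gen = simulate_genealogy(config, rng)
    mat = drop_mutations(
        gen, config.theta, config.L_seq, rng,
        config.base_composition, config.transition_fraction,
    )
    labels = config.labels
    ids, pops = [], {}
    for lab, nd in zip(labels, config.n_per_pop):
        for i in range(nd):
            sid = f"{lab}_{i+1:03d}"
            ids.append(sid)
            pops[sid] = lab
    seqs = ["".join("ACGT"[b] for b in row) for row in mat]
    aln = Alignment(ids=ids, seqs=seqs, population_of=pops)
    truth = {
        "scenario": config.scenario,
        "n_per_pop": list(config.n_per_pop),
        "theta": config.theta,
        "L_seq": config.L_seq,
        "seed": seed,
        "tmrca": gen.tmrca,
        "total_tree_length": gen.total_length,
    }
    if config.scenario == "expansion":
        truth.update(
            theta0=config.theta0, theta1=config.theta,
            tau_true=config.tau_true,
            t_change_coalescent=config.tau_true / config.theta,
        )
    if config.scenario == "island":
        truth["M"] = config.M
    return aln, truth


def emit_dataset(
    config: SimConfig, outdir: str | Path, seed: int | None = None,
    prefix: str = "sim",
) -> dict[str, Path]:
    """Write FASTA + popmap + truth JSON; returns the file paths.

    Byte-identical output for identical config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln, truth = simulate_dataset(config, seed=seed)
    paths = {
        "fasta": outdir / f"{prefix}.fasta",
        "popmap": outdir / f"{prefix}.popmap.tsv",
        "truth": outdir / f"{prefix}.truth.json",
    }
    write_alignment(aln, paths["fasta"], paths["popmap"])
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return paths
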