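"""End-to-end orchestration: collapse → diversity → Φst/AMOVA → neutrality
→ mismatch/dating → trees → network, with a JSON report.

Inputs are either an aligned FASTA plus popmap (full analysis) or a
counts-only haplotype table (then only the statistics computable without
sequences are produced and the rest are skipped with an explicit reason —
no silent wrong numbers). One global seed drives every stochastic stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .demography import expansion_time, fit_expansion, mismatch_observed
from .distances import haplotype_distance_matrix, population_distance_matrix
from .diversity import diversity_report, diversity_summary
from .errors import MitopopError
from .haplotypes import (
    HaplotypeTable,
    collapse_haplotypes,
    haplotype_frequencies,
    read_haplotype_table,
    segregating_sites,
)
from .io import filter_sites, read_alignment
from .network import ancestral_weights, edge_list, median_joining, write_gml
from .neutrality import neutrality_pvalues, neutrality_tests
from .structure import amova, pairwise_phist
from .trees import neighbor_joining, upgma, write_newick

log = logging.getLogger("mitopop")


@dataclass
class PipelineConfig:
    fasta: str | None = None
    popmap: str | None = None
    haplotype_table: str | None = None
    mu: tuple[float, ...] = ()          # per-site per-generation rates for dating
    generation_time: float = 1.0
    permutations: int = 1000
    bootstrap: int = 1000
    seed: int = 0
    outdir: str = "mitopop_out"
    mismatch_model: str = "rh92"
    neutrality_pvalue_reps: int = 0     # 0 disables simulated p-values

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "mu" in raw and not isinstance(raw["mu"], (list, tuple)):
            raw["mu"] = [raw["mu"]]
        raw["mu"] = tuple(raw.get("mu", ()))
        return cls(**raw)


@dataclass
class PipelineReport:
    sections: dict = field(default_factory=dict)
    skipped: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "metadata": self.metadata,
            "sections": self.sections,
            "skipped": self.skipped,
        }
        text = json.dumps(payload, indent=2, sort_keys=True, default=str)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def run_pipeline(config: PipelineConfig | str | Path) -> PipelineReport:
    cfg = (
        config if isinstance(config, PipelineConfig)
        else PipelineConfig.from_yaml(config)
    )
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport()
    report.metadata = {
        "version": __version__,
        "seed": cfg.seed,
        "permutations": cfg.permutations,
        "bootstrap": cfg.bootstrap,
        "generation_time": cfg.generation_time,
        "mu": list(cfg.mu),
    }
    rng = np.random.default_rng(cfg.seed)

    aln = None
    if cfg.fasta is not None:
        if cfg.popmap is None:
            raise MitopopError("fasta input requires a popmap")
        aln = filter_sites(read_alignment(cfg.fasta, cfg.popmap))
        tab = collapse_haplotypes(aln)
        L = aln.length
    elif cfg.haplotype_table is not None:
        tab = read_haplotype_table(cfg.haplotype_table)
        L = None
    else:
        raise MitopopError("config names neither fasta+popmap nor haplotype_table")

    have_seqs = tab.sequences is not None

    def stage(name: str):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
                log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            except MitopopError as exc:
                report.skipped[name] = str(exc)
                log.warning("stage %s skipped: %s", name, exc)
        return deco

    d = haplotype_distance_matrix(tab, "diff_count") if have_seqs else None

    @stage("diversity")
    def _div():
        df = diversity_summary(tab, d=d, L=L)
        diversity_report(df, outdir / "diversity.tsv")
        report.sections["diversity"] = json.loads(df.to_json(orient="index"))
        report.sections["haplotype_frequencies_pct"] = (
            haplotype_frequencies(tab, "all").round(2).to_dict()
        )

    @stage("structure")
    def _struct():
        if not have_seqs:
            raise MitopopError("requires haplotype sequences")
        res = amova(tab, d, n_perm=cfg.permutations,
                    seed=int(rng.integers(2**31)))
        res.to_frame().to_csv(outdir / "amova.tsv", sep="\t")
        report.sections["amova"] = {
            "phi_st": res.phi_st, "p_value": res.p_value,
            "pct_among": res.pct_among, "pct_within": res.pct_within,
        }
        fst = pairwise_phist(tab, d, n_perm=cfg.permutations,
                             seed=int(rng.integers(2**31)))
        dxy = population_distance_matrix(tab, model="k2p", kind="dxy")
        (outdir / "phist_matrix.tsv").write_text(fst.report(upper=dxy))
        report.sections["pairwise_phist"] = json.loads(
            fst.to_frame().to_json(orient="index")
        )

    @stage("neutrality")
    def _neut():
        if not have_seqs:
            raise MitopopError("requires haplotype sequences")
        pooled = tab.pooled_counts()
        from .diversity import mean_pairwise_differences
        k = mean_pairwise_differences(pooled.values, d)
        S = segregating_sites_of_table(tab)
        stats = neutrality_tests(tab.total_n, S, k, len(tab.haplotype_ids))
        if cfg.neutrality_pvalue_reps > 0:
            stats = neutrality_pvalues(
                stats, n_rep=cfg.neutrality_pvalue_reps,
                seed=int(rng.integers(2**31)), L_seq=L or 647,
            )
        report.sections["neutrality"] = {
            "n": stats.n, "S": stats.S, "k": stats.k_mean,
            "theta_w": stats.theta_w, "tajima_d": stats.tajima_d,
            "fu_fs": stats.fu_fs, "D_p": stats.d_p, "Fs_p": stats.fs_p,
        }

    @stage("demography")
    def _demo():
        if not have_seqs:
            raise MitopopError("requires haplotype sequences")
        obs = mismatch_observed(tab, d)
        fit = fit_expansion(obs, model=cfg.mismatch_model,
                            seed=int(rng.integers(2**31)))
        sec = {
            "tau": fit.tau, "theta0": fit.theta0, "theta1": fit.theta1,
            "ssd": fit.ssd, "model": fit.model_tag,
            "observed": fit.observed.tolist(),
            "expected": fit.expected.tolist(),
        }
        if cfg.mu and fit.tau > 0:
            sec["expansion_time_years"] = {
                f"{mu:g}": expansion_time(fit.tau, mu, L or 647,
                                          cfg.generation_time).t_years
                for mu in cfg.mu
            }
        report.sections["mismatch"] = sec

    @stage("trees")
    def _trees():
        if not have_seqs:
            raise MitopopError("requires haplotype sequences")
        dxy = population_distance_matrix(tab, model="k2p", kind="dxy")
        if len(dxy.labels) >= 2:
            (outdir / "upgma_populations.nwk").write_text(
                write_newick(upgma(dxy)) + "\n")
        hap_d = haplotype_distance_matrix(tab, "k2p")
        if len(hap_d.labels) >= 3:
            (outdir / "nj_haplotypes.nwk").write_text(
                write_newick(neighbor_joining(hap_d)) + "\n")
        report.sections["trees"] = {
            "upgma_populations": "upgma_populations.nwk",
            "nj_haplotypes": "nj_haplotypes.nwk",
        }

    @stage("network")
    def _net():
        if not have_seqs:
            raise MitopopError("requires haplotype sequences")
        g = median_joining(tab)
        write_gml(g, outdir / "network.gml")
        edge_list(g, outdir / "network_edges.tsv")
        report.sections["network"] = {
            "file": "network.gml",
            "ancestral_weights": ancestral_weights(tab).round(4).to_dict(),
        }

    report.to_json(outdir / "report.json")
    return report


def segregating_sites_of_table(tab: HaplotypeTable) -> int:
    """S over the haplotypes present in the table (sequence-bearing)."""
    from .io import Alignment

    seqs = tab.sequences
    if seqs is None:
        raise MitopopError("requires haplotype sequences")
    aln = Alignment(
        ids=list(seqs), seqs=[seqs[h] for h in seqs],
        population_of={h: "x" for h in seqs},
    )
    return segregating_sites(aln).S
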