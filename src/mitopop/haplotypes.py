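"""Haplotype collapsing and the populations × haplotypes count table.

Identical aligned sequences share one haplotype; labels H1, H2, … are
assigned by order of first appearance in the input, which makes collapsing
deterministic and reproducible. The count table is the central exchange
object for every downstream statistic that does not need raw sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, MitopopError
from .io import Alignment, BASES


@dataclass
class HaplotypeTable:
    """Populations × haplotypes count matrix with optional sequences.

    ``counts`` has population labels as the index and haplotype ids as
    columns. ``sequences`` maps haplotype id → aligned sequence (all distinct,
    equal length) when the table was built from an alignment. ``basin_of``
    optionally groups populations into drainage basins (or any higher-level
    grouping).
    """

    counts: pd.DataFrame
    sequences: dict[str, str] | None = None
    basin_of: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        c = self.counts
        if (c.values < 0).any():
            raise MitopopError("negative haplotype counts")
        if not np.issubdtype(c.values.dtype, np.integer):
            if not np.allclose(c.values, np.round(c.values)):
                raise MitopopError("haplotype counts must be integers")
            self.counts = c.astype(int)
        if (self.counts.sum(axis=0) < 1).any():
            empty = list(self.counts.columns[self.counts.sum(axis=0) < 1])
            raise MitopopError(f"haplotype columns with zero total: {empty}")
        if self.sequences is not None:
            seqs = [self.sequences[h] for h in self.counts.columns]
            if len(set(seqs)) != len(seqs):
                raise MitopopError("haplotype sequences are not all distinct")
            if len({len(s) for s in seqs}) != 1:
                raise MitopopError("haplotype sequences differ in length")

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def populations(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def total_n(self) -> int:
        return int(self.counts.values.sum())

    def pooled_counts(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def basin_counts(self) -> pd.DataFrame:
        """Counts re-aggregated by basin; requires ``basin_of``."""
        if self.basin_of is None:
            raise MitopopError("no basin map attached to this table")
        mapped = [p for p in self.populations if p in self.basin_of]
        groups = pd.Series({p: self.basin_of[p] for p in mapped})
        return self.counts.loc[mapped].groupby(groups, sort=False).sum()

    def expand(self) -> list[tuple[str, str]]:
        """Repeat each haplotype by its count: list of (population, haplotype id).

        Inverse of collapsing up to sample identity; used by the brute-force
        oracles in the test-suite and by permutation procedures.
        """
        out = []
        for pop in self.populations:
            for h in self.haplotype_ids:
                out.extend([(pop, h)] * int(self.counts.at[pop, h]))
        return out

    def to_tsv(self, path: str | Path | None = None) -> str:
        df = self.counts.copy()
        if self.basin_of is not None:
            df.insert(0, "basin", [self.basin_of[p] for p in df.index])
        df["N"] = self.sample_sizes
        df.index.name = "population"
        text = df.to_csv(sep="\t")
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class SiteReport:
    """Segregating (polymorphic) sites of an alignment."""

    S: int
    positions: list[int]  # 1-based column indices

    def __post_init__(self) -> None:
        if self.S != len(self.positions):
            raise MitopopError("site count disagrees with position list")


def collapse_haplotypes(aln: Alignment) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes and cross-tabulate.

    Labels follow first occurrence in the input order. Population order in the
    table is the order populations first appear among the samples.
    """
    hap_of: dict[str, str] = {}
    seq_of: dict[str, str] = {}
    for s in aln.seqs:
        if s not in hap_of:
            hid = f"H{len(hap_of) + 1}"
            hap_of[s] = hid
            seq_of[hid] = s
    pops = aln.populations
    hids = list(seq_of)
    counts = pd.DataFrame(0, index=pops, columns=hids, dtype=int)
    for sid, s in zip(aln.ids, aln.seqs):
        counts.at[aln.population_of[sid], hap_of[s]] += 1
    return HaplotypeTable(counts=counts, sequences=seq_of)


def segregating_sites(aln: Alignment) -> SiteReport:
    """Columns with at least two observed states among A/C/G/T.

    Gaps and Ns do not count as states (on complete-deletion-filtered input
    none remain anyway).
    """
    m = aln.matrix()
    nstates = sum(
        ((m == b.encode()).any(axis=0)).astype(int) for b in BASES
    )
    pos = np.flatnonzero(nstates >= 2)
    return SiteReport(S=int(pos.size), positions=[int(i) + 1 for i in pos])


def haplotype_frequencies(
    tab: HaplotypeTable, scope: str = "all", name: str | None = None
) -> pd.Series:
    """Haplotype frequencies in percent within a scope.

    ``scope`` is ``"all"`` (pooled sample), ``"population"`` or ``"basin"``
    (then ``name`` selects the group). Full precision; report at 2 decimals.
    """
    if scope == "all":
        counts = tab.pooled_counts()
    elif scope == "population":
        if name not in tab.populations:
            raise MitopopError(f"unknown population {name!r}")
        counts = tab.counts.loc[name]
    elif scope == "basin":
        bc = tab.basin_counts()
        if name not in bc.index:
            raise MitopopError(f"unknown basin {name!r}")
        counts = bc.loc[name]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    n = counts.sum()
    if n == 0:
        raise MitopopError(f"empty scope {scope}/{name}")
    return 100.0 * counts / n


def write_haplotype_fasta(tab: HaplotypeTable, path: str | Path) -> None:
    if tab.sequences is None:
        raise MitopopError("table carries no haplotype sequences")
    with open(path, "w") as fh:
        for hid in tab.haplotype_ids:
            fh.write(f">{hid}\n{tab.sequences[hid]}\n")


def read_haplotype_table(path: str | Path) -> HaplotypeTable:
    """Read a count table TSV (columns: population, [basin], H…, [N])."""
    df = pd.read_csv(path, sep="\t", dtype={"population": str})
    df = df.set_index("population")
    basin_of = None
    if "basin" in df.columns:
        basins = df.pop("basin")
        basin_of = {p: b for p, b in basins.items() if b not in ("-", "", None)}
        basin_of = basin_of or None
    if "N" in df.columns:
        stated = df.pop("N")
        if not (stated == df.sum(axis=1)).all():
            bad = list(stated.index[stated != df.sum(axis=1)])
            raise MitopopError(f"stated N disagrees with row sums for: {bad}")
    return HaplotypeTable(counts=df.astype(int), basin_of=basin_of)


def load_example_counts() -> HaplotypeTable:
    """Bundled example: printed COI haplotype counts of the icefish
    *Neosalanx taihuensis* surveyed across 11 populations in six Chinese
    river basins (13 haplotypes, 197 individuals, 647 bp fragment).

    Only the 11 per-population rows are returned; the survey's own pooled
    row is available via :func:`load_example_pooled_counts` (its printed H2
    total differs by one from the column sums of the per-population rows, so
    the two are kept separate rather than silently reconciled).
    """
    with resources.files("mitopop.data").joinpath("example_counts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t").set_index("population")
    df = df.drop(index="Entire_region")
    basin_of = dict(df["basin"])
    counts = df.drop(columns=["basin", "N"]).astype(int)
    return HaplotypeTable(counts=counts, basin_of=basin_of)


def load_example_pooled_counts() -> pd.Series:
    """The example survey's printed pooled (entire-region) haplotype counts."""
    with resources.files("mitopop.data").joinpath("example_counts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t").set_index("population")
    return df.loc["Entire_region"].drop(["basin", "N"]).astype(int)
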