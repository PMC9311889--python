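"""Aligned-FASTA input, population maps, site filtering and base composition.

The central container is :class:`Alignment`: equal-length haploid mtDNA
sequences over ``{A, C, G, T, -, N}`` with a sample→population map. All
user-facing column coordinates are 1-based inclusive.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, AlphabetError, PopmapError

ALPHABET = frozenset("ACGT-N")
BASES = ("A", "C", "G", "T")


@dataclass
class Alignment:
    """An aligned set of haploid sequences with population labels.

    Invariants (enforced at construction): identical sequence lengths,
    unique sample ids, every sample mapped to a population, alphabet
    restricted to ``{A,C,G,T,-,N}`` (case-normalised to upper).
    """

    ids: list[str]
    seqs: list[str]
    population_of: dict[str, str]
    #: original 1-based column numbers retained by the last filtering step;
    #: ``None`` means the alignment is unfiltered.
    retained_columns: list[int] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and sequences differ in number")
        if not self.ids:
            raise AlignmentError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sample ids")
        self.seqs = [s.upper() for s in self.seqs]
        L = len(self.seqs[0])
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != L:
                raise AlignmentError(
                    f"record {sid!r} has length {len(s)}, expected {L}"
                )
            bad = set(s) - ALPHABET
            if bad:
                raise AlphabetError(
                    f"record {sid!r} contains characters outside A/C/G/T/-/N: "
                    f"{sorted(bad)}"
                )
        missing = [sid for sid in self.ids if sid not in self.population_of]
        if missing:
            raise PopmapError(f"samples missing from population map: {missing}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance among samples."""
        seen: dict[str, None] = {}
        for sid in self.ids:
            seen.setdefault(self.population_of[sid], None)
        return list(seen)

    def matrix(self) -> np.ndarray:
        """(n, L) byte matrix view of the sequences (dtype ``S1``)."""
        return np.frombuffer(
            "".join(self.seqs).encode(), dtype="S1"
        ).reshape(self.n, self.length)


def read_alignment(fasta_path: str | Path, popmap_path: str | Path) -> Alignment:
    """Read an aligned FASTA plus a two-column popmap TSV.

    The popmap must have header columns ``sample_id`` and ``population``.
    Every FASTA record must be mapped; unmapped samples are an error.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {fasta_path}")
    popmap = read_popmap(popmap_path)
    ids = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    return Alignment(ids=ids, seqs=seqs, population_of=popmap)


def read_popmap(popmap_path: str | Path) -> dict[str, str]:
    df = pd.read_csv(popmap_path, sep="\t", dtype=str)
    for col in ("sample_id", "population"):
        if col not in df.columns:
            raise PopmapError(f"popmap {popmap_path} lacks column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise PopmapError(f"duplicate sample ids in popmap: {dups}")
    return dict(zip(df["sample_id"], df["population"]))


def write_alignment(aln: Alignment, fasta_path: str | Path,
                    popmap_path: str | Path | None = None) -> None:
    """Write the alignment back to FASTA (and optionally its popmap TSV)."""
    recs = [
        SeqRecord(Seq(s), id=sid, description="")
        for sid, s in zip(aln.ids, aln.seqs)
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")
    if popmap_path is not None:
        pd.DataFrame(
            {"sample_id": aln.ids,
             "population": [aln.population_of[i] for i in aln.ids]}
        ).to_csv(popmap_path, sep="\t", index=False)


def filter_sites(aln: Alignment, policy: str = "complete_deletion") -> Alignment:
    """Remove alignment columns according to the gap policy.

    ``complete_deletion`` drops every column containing ``-`` or ``N`` in any
    record (the default used by all downstream statistics); ``none`` is the
    identity. The returned alignment records the retained original column
    numbers (1-based) in ``retained_columns``.
    """
    if policy == "none":
        return aln
    if policy != "complete_deletion":
        raise ValueError(f"unknown site-filter policy {policy!r}")
    m = aln.matrix()
    clean = ~((m == b"-") | (m == b"N")).any(axis=0)
    if not clean.any():
        raise AlignmentError("complete deletion removed every column")
    keep = np.flatnonzero(clean)
    sub = m[:, keep]
    return Alignment(
        ids=list(aln.ids),
        seqs=[row.tobytes().decode() for row in sub],
        population_of=dict(aln.population_of),
        retained_columns=[int(i) + 1 for i in keep],
    )


def base_composition(aln: Alignment, by_population: bool = True) -> pd.DataFrame:
    """Per-group mean base composition (percent), plus an overall mean row.

    Percentages are computed per sequence over non-gap, non-N characters and
    averaged over the sequences of each group; columns are T, C, A, G, T+A and
    C+G. Values are full precision; round to 2 decimals for reporting.
    """
    m = aln.matrix()
    counts = np.stack([(m == b.encode()).sum(axis=1) for b in BASES], axis=1)
    denom = counts.sum(axis=1).astype(float)
    if (denom == 0).any():
        bad = [aln.ids[i] for i in np.flatnonzero(denom == 0)]
        raise AlignmentError(f"records with no unambiguous bases: {bad}")
    pct = 100.0 * counts / denom[:, None]  # per-sequence A,C,G,T %
    per_seq = pd.DataFrame(pct, index=aln.ids, columns=list(BASES))

    def _row(sub: pd.DataFrame) -> dict[str, float]:
        mean = sub.mean(axis=0)
        return {
            "T": mean["T"], "C": mean["C"], "A": mean["A"], "G": mean["G"],
            "T+A": mean["T"] + mean["A"], "C+G": mean["C"] + mean["G"],
        }

    rows: dict[str, dict[str, float]] = {}
    if by_population:
        for pop in aln.populations:
            members = [sid for sid in aln.ids if aln.population_of[sid] == pop]
            rows[pop] = _row(per_seq.loc[members])
    rows["Total average"] = _row(per_seq)
    return pd.DataFrame.from_dict(rows, orient="index")


def composition_report(table: pd.DataFrame) -> str:
    """Render a composition table as TSV with 2-decimal percentages."""
    buf = _io.StringIO()
    table.round(2).to_csv(buf, sep="\t", float_format="%.2f")
    return buf.getvalue()
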