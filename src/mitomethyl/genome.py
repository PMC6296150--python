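"""Circular mitochondrial genomes and CpG site enumeration.

The mitochondrial genome is a small circular molecule; a CpG dinucleotide on
the plus strand implies a CpG on the minus strand at the adjacent position
(CG is its own reverse complement), so every CG occurrence contributes one
cytosine site per strand.  Coordinates are 1-based on the plus strand
throughout, matching the convention of per-site methylation tables
("Location of C" + strand): a minus-strand cytosine is reported at the
plus-strand position of its pairing guanine.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PLUS = "+"
MINUS = "-"


class CpGSite(NamedTuple):
    """A cytosine in CpG context.

    ``position`` is the 1-based plus-strand coordinate of the cytosine
    (for a minus-strand site, the coordinate of the plus-strand G it pairs
    with); ``strand`` is ``"+"`` or ``"-"``.
    """

    position: int
    strand: str

    @property
    def context(self) -> str:
        return "CpG"


@dataclass(frozen=True)
class CircularGenome:
    """A named DNA sequence with optional circular topology.

    Parameters
    ----------
    name:
        Sequence identifier (FASTA header word).
    sequence:
        Uppercase DNA over ``{A, C, G, T, N}``.
    circular:
        When true, position ``length`` wraps to position 1 so the junction
        dinucleotide (last base, first base) exists.
    """

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"non-DNA character(s) {sorted(bad)} in sequence {self.name!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based plus-strand position (no wrapping)."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside [1, {self.length}]")
        return self.sequence[position - 1]

    def base_wrapped(self, index0: int) -> str:
        """Base at a 0-based index taken modulo the genome length."""
        return self.sequence[index0 % self.length]


@dataclass(frozen=True)
class GenotypeCpGDiff:
    """Set difference of CpG profiles between two equal-length genotypes."""

    genome_a: str
    genome_b: str
    gained: frozenset = field(default_factory=frozenset)  # in a, not in b
    lost: frozenset = field(default_factory=frozenset)  # in b, not in a

    def __post_init__(self) -> None:
        if self.gained & self.lost:
            raise ValueError("gained and lost CpG sets must be disjoint")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def load_fasta(path, circular: bool = True) -> CircularGenome:
    """Read a single-record FASTA into a :class:`CircularGenome`.

    Raises a ``ValueError`` for an empty file, multiple records, or
    non-DNA characters (the offending character is named).
    """
    with open(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise ValueError(f"no FASTA record found in {path}")
    if len(records) > 1:
        raise ValueError(
            f"multiple records ({len(records)}) in {path}; expected exactly one"
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    m = re.search(f"[^{''.join(sorted(_ALPHABET))}]", seq)
    if m:
        raise ValueError(
            f"non-DNA character {m.group(0)!r} at sequence position "
            f"{m.start() + 1} in {path}"
        )
    return CircularGenome(name=rec.id, sequence=seq, circular=circular)


def write_fasta(genome: CircularGenome, path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    SeqIO.write([rec], str(path), "fasta")


def _cg_starts(genome: CircularGenome) -> list[int]:
    """0-based start indices of CG dinucleotides, including the circular
    junction (last base, first base) when the genome is circular."""
    s = genome.sequence
    n = len(s)
    starts = [i for i in range(n - 1) if s[i] == "C" and s[i + 1] == "G"]
    if genome.circular and n >= 2 and s[-1] == "C" and s[0] == "G":
        starts.append(n - 1)
    return starts


def enumerate_cpg_sites(genome: CircularGenome) -> list[CpGSite]:
    """All CpG-context cytosines on both strands, sorted by (position, strand).

    Each CG occurrence yields a plus-strand site at the C and a minus-strand
    site at the G (reported at its plus-strand coordinate).  On a circular
    genome the junction dinucleotide contributes sites at (L, +) and (1, -).
    """
    n = genome.length
    sites = []
    for i in _cg_starts(genome):
        sites.append(CpGSite(i + 1, PLUS))
        sites.append(CpGSite((i + 1) % n + 1, MINUS))
    sites.sort(key=lambda s: (s.position, 0 if s.strand == PLUS else 1))
    return sites


def diff_cpg_profiles(a: CircularGenome, b: CircularGenome) -> GenotypeCpGDiff:
    """CpG sites gained/lost in genotype ``a`` relative to ``b``.

    Both genomes must share a coordinate system (equal length); genotypes
    differing by indels are unsupported and must be aligned externally.
    """
    if a.length != b.length:
        raise ValueError(
            f"genome lengths differ ({a.length} vs {b.length}); "
            "indel-bearing genotypes are unsupported — compare equal-length "
            "genotypes on a shared coordinate system"
        )
    sa = set(enumerate_cpg_sites(a))
    sb = set(enumerate_cpg_sites(b))
    return GenotypeCpGDiff(
        genome_a=a.name,
        genome_b=b.name,
        gained=frozenset(sa - sb),
        lost=frozenset(sb - sa),
    )


def cytosine_table(genome: CircularGenome) -> pd.DataFrame:
    """Every cytosine on both strands with context and trinucleotide.

    Columns: ``position`` (1-based plus-strand), ``strand``, ``context``
    (``CpG`` or ``non-CpG``; non-CpG contexts are merged into one class),
    ``trinucleotide`` (the cytosine and the next two bases on its own
    strand; ``N``-padded at the ends of a linear genome).
    """
    s = genome.sequence
    n = len(s)

    def plus_base(i: int) -> str:
        if genome.circular:
            return s[i % n]
        return s[i] if 0 <= i < n else "N"

    rows = []
    comp = str.maketrans("ACGTN", "TGCAN")
    for i, b in enumerate(s):
        if b == "C":
            nxt, nxt2 = plus_base(i + 1), plus_base(i + 2)
            rows.append(
                (i + 1, PLUS, "CpG" if nxt == "G" else "non-CpG", "C" + nxt + nxt2)
            )
        if b == "G":
            # minus-strand cytosine pairs with this G; its downstream bases
            # run leftwards on the plus strand
            nxt = plus_base(i - 1).translate(comp)
            nxt2 = plus_base(i - 2).translate(comp)
            rows.append(
                (i + 1, MINUS, "CpG" if nxt == "G" else "non-CpG", "C" + nxt + nxt2)
            )
    df = pd.DataFrame(rows, columns=["position", "strand", "context", "trinucleotide"])
    df["_s"] = (df["strand"] == MINUS).astype(int)
    df = df.sort_values(["position", "_s"]).drop(columns="_s").reset_index(drop=True)
    return df


def write_cpg_sites_bed(sites: Iterable[CpGSite], genome: CircularGenome, path) -> None:
    """BED-like TSV: chrom, 0-based start, end, strand, context."""
    with open(path, "w") as fh:
        for site in sites:
            fh.write(
                f"{genome.name}\t{site.position - 1}\t{site.position}\t"
                f"{site.strand}\t{site.context}\n"
            )


def write_cpg_sites_table(sites: Iterable[CpGSite], path) -> None:
    """1-based site table mirroring the per-site report convention."""
    with open(path, "w") as fh:
        fh.write("position\tstrand\tcontext\n")
        for site in sites:
            fh.write(f"{site.position}\t{site.strand}\t{site.context}\n")
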