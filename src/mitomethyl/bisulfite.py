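"""Non-directional bisulfite alignment and per-cytosine methylation calling.

Bisulfite conversion deaminates unmethylated cytosines to uracil (read as
T), so reads are aligned in converted space: the query is C->T (or G->A)
collapsed and compared against the correspondingly collapsed genome.  A
non-directional library yields four strand classes:

* OT   — original top (plus) strand, C->T converted
* OB   — original bottom (minus) strand, C->T converted
* CTOT — complementary copy of the converted OT strand
* CTOB — complementary copy of the converted OB strand

For a mitochondrial-scale genome an exact in-memory k-mer index with
ungapped seed-and-extend verification is sufficient; only the unique best
alignment (fewest mismatches, strictly better than the runner-up) is kept,
and mates must align concordantly within the configured insert range.

Methylation states are read off in the plus-co-linear view: OT/CTOT
fragments call plus-strand cytosines (C = methylated, T = unmethylated),
OB/CTOB fragments call minus-strand cytosines at plus-strand G positions
(G = methylated, A = unmethylated).  Positions covered by both mates of a
fragment are counted once.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import MINUS, PLUS, CircularGenome, cytosine_table, reverse_complement

logger = logging.getLogger(__name__)

_C, _G, _T, _A = (ord(x) for x in "CGTA")


@dataclass
class AlignedFragment:
    """A uniquely aligned (read-pair) fragment.

    ``start`` is the 1-based leftmost plus-strand position, ``insert`` the
    fragment length on the genome, ``segments`` the plus-co-linear original
    read sequences as ``(0-based start, sequence)`` used for methylation
    calling.
    """

    read_id: str
    start: int
    insert: int
    strand_class: str
    mismatches: int
    unique: bool
    segments: tuple


class BisulfiteAligner:
    """Seed-and-extend ungapped aligner over a small circular genome.

    Builds k-mer indexes of the C->T and G->A collapsed genome (doubled to
    handle origin-spanning alignments when circular) and scores candidate
    placements by full-length mismatch count.
    """

    def __init__(
        self,
        genome: CircularGenome,
        k: int = 20,
        max_mismatches: int = 10,
        min_insert: int | None = None,
        max_insert: int = 700,
    ):
        self.genome = genome
        self.k = k
        self.max_mismatches = max_mismatches
        self.min_insert = min_insert
        self.max_insert = max_insert
        L = genome.length
        if "N" * min(L, 200) in genome.sequence:
            warnings.warn("long N-run in genome: region will be unmappable")
        ct = genome.sequence.replace("C", "T")
        ga = genome.sequence.replace("G", "A")
        reps = 2 if genome.circular else 1
        self._refs = {
            "CT": np.frombuffer((ct * reps).encode(), dtype=np.uint8),
            "GA": np.frombuffer((ga * reps).encode(), dtype=np.uint8),
        }
        self._index = {name: self._build_index(ref) for name, ref in self._refs.items()}

    def _build_index(self, ref: np.ndarray) -> dict:
        L, k = self.genome.length, self.k
        buf = ref.tobytes()
        index: dict[bytes, list[int]] = {}
        last = L if self.genome.circular else L - k + 1
        for i in range(last):
            index.setdefault(buf[i: i + k], []).append(i)
        return index

    # -- candidate generation ------------------------------------------------

    def _hits(self, q: np.ndarray, ref_name: str) -> list[tuple[int, int]]:
        """Verified placements of a collapsed query: (0-based pos, mismatches)."""
        L, k = self.genome.length, self.k
        n = q.size
        if n < k:
            return []
        ref = self._refs[ref_name]
        index = self._index[ref_name]
        qb = q.tobytes()
        offsets = {0, (n - k) // 2, n - k}
        cand: set[int] = set()
        for off in offsets:
            for pos in index.get(qb[off: off + k], ()):
                cand.add((pos - off) % L)
        out = []
        for pos in cand:
            if not self.genome.circular and pos + n > L:
                continue
            mm = int(np.count_nonzero(ref[pos: pos + n] != q))
            if mm <= self.max_mismatches:
                out.append((pos, mm))
        return out

    # -- public API ----------------------------------------------------------

    def align_pair(self, read_id: str, r1: str, r2: str) -> AlignedFragment | None:
        """Align a mate pair; returns None for unmapped or ambiguous pairs."""
        L = self.genome.length
        rl1, rl2 = len(r1), len(r2)
        min_ins = self.min_insert if self.min_insert is not None else max(rl1, rl2)

        a1 = np.frombuffer(r1.encode(), dtype=np.uint8)
        a2 = np.frombuffer(r2.encode(), dtype=np.uint8)
        rc1 = np.frombuffer(reverse_complement(r1).encode(), dtype=np.uint8)
        rc2 = np.frombuffer(reverse_complement(r2).encode(), dtype=np.uint8)

        def ct(a):
            b = a.copy()
            b[b == _C] = _T
            return b

        def ga(a):
            b = a.copy()
            b[b == _G] = _A
            return b

        # per class: (ref, left query, right query, left/right original
        # plus-co-linear sequences)
        layouts = {
            "OT": ("CT", ct(a1), ct(rc2), r1, reverse_complement(r2)),
            "CTOT": ("CT", ct(a2), ct(rc1), r2, reverse_complement(r1)),
            "CTOB": ("GA", ga(a1), ga(rc2), r1, reverse_complement(r2)),
            "OB": ("GA", ga(a2), ga(rc1), r2, reverse_complement(r1)),
        }

        best = None  # (mm, cls, pL, ins, segL, segR)
        second_mm = None
        for cls, (ref, qL, qR, segL, segR) in layouts.items():
            hitsL = self._hits(qL, ref)
            if not hitsL:
                continue
            hitsR = self._hits(qR, ref)
            for pL, mmL in hitsL:
                for pR, mmR in hitsR:
                    ins = (pR - pL) % L + len(qR)
                    if not min_ins <= ins <= self.max_insert:
                        continue
                    if not self.genome.circular and pL + ins > L:
                        continue
                    mm = mmL + mmR
                    key = (mm, cls, pL, ins, segL, segR, pR)
                    if best is None or mm < best[0]:
                        second_mm = best[0] if best is not None else None
                        best = key
                    elif (cls, pL, ins) != (best[1], best[2], best[3]):
                        if second_mm is None or mm < second_mm:
                            second_mm = mm
        if best is None:
            return None
        if second_mm is not None and second_mm <= best[0]:
            return None  # ambiguous placement: conservative rejection
        mm, cls, pL, ins, segL, segR, pR = best
        return AlignedFragment(
            read_id=read_id,
            start=pL + 1,
            insert=ins,
            strand_class=cls,
            mismatches=mm,
            unique=True,
            segments=((pL, segL), (pR, segR)),
        )

    def align_read(self, read_id: str, r: str) -> AlignedFragment | None:
        """Align a single-end read (fragment length = read length)."""
        a = np.frombuffer(r.encode(), dtype=np.uint8)
        rc = np.frombuffer(reverse_complement(r).encode(), dtype=np.uint8)

        def ct(x):
            b = x.copy()
            b[b == _C] = _T
            return b

        def ga(x):
            b = x.copy()
            b[b == _G] = _A
            return b

        layouts = {
            "OT": ("CT", ct(a), r),
            "CTOT": ("CT", ct(rc), reverse_complement(r)),
            "CTOB": ("GA", ga(a), r),
            "OB": ("GA", ga(rc), reverse_complement(r)),
        }
        best = None
        second_mm = None
        for cls, (ref, q, seg) in layouts.items():
            for pos, mm in self._hits(q, ref):
                if best is None or mm < best[0]:
                    second_mm = best[0] if best is not None else None
                    best = (mm, cls, pos, seg)
                elif (cls, pos) != (best[1], best[2]):
                    if second_mm is None or mm < second_mm:
                        second_mm = mm
        if best is None or (second_mm is not None and second_mm <= best[0]):
            return None
        mm, cls, pos, seg = best
        return AlignedFragment(
            read_id=read_id,
            start=pos + 1,
            insert=len(r),
            strand_class=cls,
            mismatches=mm,
            unique=True,
            segments=((pos, seg),),
        )


def align_bisulfite(
    read_pairs: Iterable[tuple[str, str, str | None]],
    genome: CircularGenome,
    max_mismatches: int = 10,
    circular: bool = True,
    max_insert: int = 700,
) -> list[AlignedFragment]:
    """Align an iterable of ``(read_id, r1, r2_or_None)`` to the genome.

    The ambiguity/unmapped rate is logged; only unique best alignments are
    returned.
    """
    g = genome if genome.circular == circular else CircularGenome(
        genome.name, genome.sequence, circular
    )
    aligner = BisulfiteAligner(g, max_mismatches=max_mismatches, max_insert=max_insert)
    out = []
    total = 0
    for rid, r1, r2 in read_pairs:
        total += 1
        frag = (
            aligner.align_pair(rid, r1, r2)
            if r2 is not None
            else aligner.align_read(rid, r1)
        )
        if frag is not None:
            out.append(frag)
    if total:
        logger.info(
            "aligned %d/%d fragments uniquely (%.2f%% unmapped/ambiguous)",
            len(out),
            total,
            100.0 * (total - len(out)) / total,
        )
    return out


def deduplicate(fragments: Sequence[AlignedFragment]) -> list[AlignedFragment]:
    """Remove PCR duplicates: one fragment kept per
    (leftmost position, fragment length, strand class), first encountered."""
    seen = set()
    kept = []
    for frag in fragments:
        key = (frag.start, frag.insert, frag.strand_class)
        if key in seen:
            continue
        seen.add(key)
        kept.append(frag)
    return kept


def extract_methylation(
    fragments: Sequence[AlignedFragment], genome: CircularGenome
) -> pd.DataFrame:
    """Per-cytosine methylation calls from deduplicated fragments.

    Returns the cytosine call table: one row per cytosine on either strand
    of the genome with ``count_methylated``, ``count_unmethylated``,
    ``context`` (CpG vs the merged non-CpG class) and ``trinucleotide``.
    Read bases other than C/T (plus-strand calls) or G/A (minus-strand
    calls) at a cytosine position are ignored; each fragment contributes at
    most one call per site even where its mates overlap.
    """
    L = genome.length
    garr = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    meth = {PLUS: np.zeros(L, dtype=np.int64), MINUS: np.zeros(L, dtype=np.int64)}
    unmeth = {PLUS: np.zeros(L, dtype=np.int64), MINUS: np.zeros(L, dtype=np.int64)}

    for frag in fragments:
        plus_calls = frag.strand_class in ("OT", "CTOT")
        gbase, methbase, unmethbase = (
            (_C, _C, _T) if plus_calls else (_G, _G, _A)
        )
        strand = PLUS if plus_calls else MINUS
        seen_pos: set[int] | None = None
        for seg_start, seg_seq in frag.segments:
            sarr = np.frombuffer(seg_seq.encode(), dtype=np.uint8)
            idx = (seg_start + np.arange(sarr.size)) % L
            if not genome.circular:
                keep = idx < L
                idx, sarr = idx[keep], sarr[keep]
            mask = garr[idx] == gbase
            pos = idx[mask]
            rb = sarr[mask]
            if seen_pos is not None and pos.size:
                new = np.array([p not in seen_pos for p in pos])
                pos, rb = pos[new], rb[new]
            if len(frag.segments) > 1:
                if seen_pos is None:
                    seen_pos = set(pos.tolist())
                else:
                    seen_pos.update(pos.tolist())
            np.add.at(meth[strand], pos[rb == methbase], 1)
            np.add.at(unmeth[strand], pos[rb == unmethbase], 1)

    table = cytosine_table(genome).copy()
    pos0 = table["position"].to_numpy() - 1
    cm = np.empty(len(table), dtype=np.int64)
    cu = np.empty(len(table), dtype=np.int64)
    for strand in (PLUS, MINUS):
        m = (table["strand"] == strand).to_numpy()
        cm[m] = meth[strand][pos0[m]]
        cu[m] = unmeth[strand][pos0[m]]
    table["count_methylated"] = cm
    table["count_unmethylated"] = cu
    return table[
        ["position", "strand", "count_methylated", "count_unmethylated",
         "context", "trinucleotide"]
    ]


def coverage_filter(table: pd.DataFrame, min_reads: int = 10) -> pd.DataFrame:
    """Keep rows covered by at least ``min_reads`` calls (inclusive)."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    cov = table["count_methylated"] + table["count_unmethylated"]
    return table[cov >= min_reads].reset_index(drop=True)


def methylation_pct(table: pd.DataFrame) -> pd.Series:
    """Percent methylation per row; NaN where coverage is zero."""
    cov = table["count_methylated"] + table["count_unmethylated"]
    with np.errstate(invalid="ignore", divide="ignore"):
        return 100.0 * table["count_methylated"] / cov.replace(0, np.nan)
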