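"""Synthetic genomes, methylomes, bisulfite read sets and qPCR tables.

Everything downstream of wet-lab sequencing is exercised against data from
this module: genotype genomes with known CpG differences, per-site true
methylomes, non-directional bisulfite-converted paired-end reads (with PCR
duplicates and a truth sidecar the aligner cannot see), long-PCR control
read sets (unmethylated negative, enzyme-methylated positive), and qPCR Ct
tables with log-linear amplification.

Defaults emulate the study regime this package targets: a 16,569 bp
circular genome, ~10% mean CpG methylation, >500-fold coverage from 150 bp
paired-end non-directional libraries, bisulfite conversion ~99.5%, ~5% PCR
duplicates, and two overlapping ~8.5 kb control amplicons spanning the
whole circle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import (
    MINUS,
    PLUS,
    CircularGenome,
    cytosine_table,
    enumerate_cpg_sites,
    reverse_complement,
)

# human mtDNA-like base composition (heavy strand is G-poor)
_BASE_FREQS = {"A": 0.309, "C": 0.313, "G": 0.131, "T": 0.247}

STRAND_CLASSES = ("OT", "OB", "CTOT", "CTOB")


# ---------------------------------------------------------------------------
# genotype genomes
# ---------------------------------------------------------------------------

def synthetic_reference_genome(
    length: int = 16569,
    n_cpg_dinucleotides: int = 435,
    seed: int = 2018,
    name: str = "synthMT",
) -> CircularGenome:
    """A synthetic stand-in for the human mitochondrial reference genome.

    This is *not* the real rCRS sequence: it is a random circular sequence
    with human-mtDNA-like base composition, calibrated to the published CpG
    census of the reference mitochondrial genome — 16,569 bp carrying
    exactly 435 CG dinucleotides, i.e. 870 CpG-context cytosines counting
    both strands.  Positions 9053-9054 and 11911-11912 are reserved as
    non-CpG ("CA") so that genotype variants can gain CpG sites there (see
    :func:`synthetic_genotypes`).

    Construction is deterministic for a given seed.
    """
    if length < 100:
        raise ValueError("synthetic reference must be at least 100 bp")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    probs = np.array([_BASE_FREQS[b] for b in "ACGT"])
    seq = list(rng.choice(bases, size=length, p=probs))

    # remove every CG occurrence (single pass cannot create new ones)
    for i in range(length):
        if seq[i] == "C" and seq[(i + 1) % length] == "G":
            seq[(i + 1) % length] = "A"

    # reserve the genotype-difference positions as CA (CpG-free, one
    # substitution away from CG); guard their flanks from planting below
    reserved_windows = []
    for pos in (9053, 11911):
        if pos + 1 <= length:
            seq[pos - 1] = "C"
            seq[pos] = "A"
            reserved_windows.append(range(pos - 4, pos + 3))  # 0-based starts

    blocked = set()
    for w in reserved_windows:
        blocked.update(w)
    blocked.add(length - 1)  # keep the junction CpG-free: toy tests own wrap

    # plant CG dinucleotides at well-separated starts; each plant adds
    # exactly one CG because no CG exists and plants are >=3 apart
    candidates = rng.permutation(length - 2)
    starts: list[int] = []
    taken = np.zeros(length, dtype=bool)
    for i in candidates:
        i = int(i)
        if i in blocked or taken[max(i - 2, 0): i + 3].any():
            continue
        starts.append(i)
        taken[i: i + 3] = True
        if len(starts) == n_cpg_dinucleotides:
            break
    if len(starts) < n_cpg_dinucleotides:
        raise ValueError("genome too short to place requested CpG count")
    for i in starts:
        seq[i], seq[i + 1] = "C", "G"

    genome = CircularGenome(name=name, sequence="".join(seq), circular=True)
    n_sites = len(enumerate_cpg_sites(genome))
    if n_sites != 2 * n_cpg_dinucleotides:
        raise AssertionError(
            f"synthetic reference has {n_sites} CpG sites, "
            f"expected {2 * n_cpg_dinucleotides}"
        )
    return genome


def simulate_genotype(
    base: CircularGenome,
    substitutions: Sequence[tuple[int, str]],
    name: str,
) -> CircularGenome:
    """Apply point substitutions (1-based position, new base) to a genome.

    The new base must differ from the current one; length is unchanged.
    """
    seq = list(base.sequence)
    for pos, new in substitutions:
        if not 1 <= pos <= base.length:
            raise IndexError(f"substitution position {pos} outside [1, {base.length}]")
        new = new.upper()
        if new not in "ACGTN":
            raise ValueError(f"invalid substitution base {new!r}")
        if seq[pos - 1] == new:
            raise ValueError(f"substitution at {pos} does not change the base")
        seq[pos - 1] = new
    return CircularGenome(name=name, sequence="".join(seq), circular=base.circular)


def synthetic_genotypes(seed: int = 2018) -> dict[str, CircularGenome]:
    """Three synthetic mtDNA genotype stand-ins sharing one coordinate system.

    ``hNSC`` equals the synthetic reference (870 CpG sites, matching the
    published census for the reference genome and the neural-stem-cell
    genotype); ``143B`` and ``GBM`` additionally carry CpG-creating
    substitutions at nt 9054 and nt 11912, so each gains the CpG pairs at
    nt 9053-9054 and nt 11911-11912 relative to ``hNSC``.  ``GBM`` carries
    one further CpG-neutral private substitution so the two tumor genotypes
    are distinguishable.
    """
    ref = synthetic_reference_genome(seed=seed)
    hnsc = CircularGenome(name="hNSC", sequence=ref.sequence, circular=True)
    tumor_subs = [(9054, "G"), (11912, "G")]
    b143 = simulate_genotype(hnsc, tumor_subs, name="143B")
    # a CpG-neutral marker: flip an A<->T away from any C or G neighborhood
    marker = _cpg_neutral_position(hnsc.sequence)
    gbm = simulate_genotype(
        b143,
        [(marker, "T" if b143.sequence[marker - 1] == "A" else "A")],
        name="GBM",
    )
    return {"hNSC": hnsc, "143B": b143, "GBM": gbm}


def _cpg_neutral_position(seq: str) -> int:
    """1-based position of an A or T flanked by A/T on both sides."""
    for i in range(1, len(seq) - 1):
        if all(b in "AT" for b in seq[i - 1: i + 2]):
            return i + 1
    raise ValueError("no CpG-neutral position found")


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupEffect:
    """Additive shift in true methylation probability at selected sites."""

    sites: frozenset  # of (position, strand)
    shift: float


@dataclass
class MethylomeSpec:
    """True per-site methylation model.

    CpG-context cytosines draw from a Beta distribution with mean
    ``cpg_mean`` and concentration ``cpg_concentration`` (a = mean*conc,
    b = (1-mean)*conc); non-CpG cytosines sit at the near-zero constant
    ``non_cpg_level``.  ``group_effects`` adds labelled per-site shifts
    (applied then clamped to [0, 1]) for constructing contrast groups.
    """

    cpg_mean: float = 0.10
    cpg_concentration: float = 20.0
    non_cpg_level: float = 0.002
    group_effects: Mapping[str, GroupEffect] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cpg_mean <= 1.0:
            raise ValueError("cpg_mean must be in [0, 1]")
        if not 0.0 <= self.non_cpg_level <= 1.0:
            raise ValueError("non_cpg_level must be in [0, 1]")
        if self.cpg_concentration < 0:
            raise ValueError("cpg_concentration must be >= 0")


def draw_methylome(
    genome: CircularGenome,
    spec: MethylomeSpec,
    effects: Iterable[str] = (),
) -> pd.DataFrame:
    """Draw a true methylome: one probability per cytosine on both strands.

    Returns a DataFrame with columns ``position``, ``strand``, ``context``,
    ``true_p``.  The Beta draw is reproducible under ``spec.seed`` and is
    shared across groups: applying a group effect shifts the same base
    methylome, so contrasts differ only where an effect was injected.
    """
    table = cytosine_table(genome).copy()
    rng = np.random.default_rng(spec.seed)
    is_cpg = (table["context"] == "CpG").to_numpy()
    p = np.full(len(table), spec.non_cpg_level, dtype=float)
    m, c = spec.cpg_mean, spec.cpg_concentration
    if m in (0.0, 1.0) or c == 0.0:
        p[is_cpg] = m  # degenerate Beta treated as a point mass at the mean
        rng.beta(1.0, 1.0, size=int(is_cpg.sum()))  # keep stream alignment
    else:
        p[is_cpg] = rng.beta(m * c, (1.0 - m) * c, size=int(is_cpg.sum()))
    table["true_p"] = p

    for label in effects:
        if label not in spec.group_effects:
            raise KeyError(f"unknown group effect {label!r}")
        eff = spec.group_effects[label]
        mask = [
            (pos, strand) in eff.sites
            for pos, strand in zip(table["position"], table["strand"])
        ]
        table.loc[mask, "true_p"] += eff.shift
    table["true_p"] = table["true_p"].clip(0.0, 1.0)
    return table


# ---------------------------------------------------------------------------
# bisulfite read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSimConfig:
    """Bisulfite sequencing regime.

    ``conversion_efficiency`` is the probability an unmethylated cytosine
    reads as T; ``methylation_protection`` the probability a methylated
    cytosine survives as C.  ``non_directional`` draws fragments uniformly
    from the four strand classes OT/OB/CTOT/CTOB (the complementary classes
    arise from amplification of the converted strands); otherwise OT/OB
    only.  ``duplicate_fraction`` of fragments is emitted twice to emulate
    PCR duplicates.
    """

    read_length: int = 150
    paired: bool = True
    insert_mean: float = 300.0
    insert_sd: float = 50.0
    mean_coverage: float = 500.0
    conversion_efficiency: float = 0.995
    methylation_protection: float = 0.995
    seq_error: float = 0.001
    duplicate_fraction: float = 0.05
    non_directional: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "conversion_efficiency",
            "methylation_protection",
            "seq_error",
            "duplicate_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be > 0")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")


@dataclass
class SimulatedReads:
    """Simulator output: FASTQ paths, the truth table, and bookkeeping.

    ``truth`` counts drawn methylation states per unique molecule (PCR
    duplicates excluded) at every *read-observed* cytosine — positions in
    the middle of an insert longer than two read lengths are invisible to
    sequencing and are not counted; ``sidecar`` records one
    row per emitted fragment (read id, 1-based leftmost plus-strand start,
    fragment length, strand class, duplicate flag) so tests can check the
    aligner against the simulated origins without the aligner seeing them.
    """

    fastq_r1: Path
    fastq_r2: Path | None
    sidecar: Path
    truth: pd.DataFrame
    n_fragments: int
    achieved_coverage: float


_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_DEC = np.array(list("ACGTN"))


def _seq_to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _arr_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def simulate_bisulfite_reads(
    genome: CircularGenome,
    methylome: pd.DataFrame,
    config: ReadSimConfig,
    out_prefix,
    intervals: Sequence[tuple[int, int]] | None = None,
    n_fragments: int | None = None,
) -> SimulatedReads:
    """Simulate a bisulfite-converted read set with truth sidecar.

    Fragments are sampled uniformly on the circle (or, when ``intervals``
    is given, uniformly within linear amplicon intervals that fragments
    never span the ends of — long-PCR products are linear molecules).
    Methylation states are drawn once per molecule, so overlapping mates
    agree at shared sites; conversion chemistry, strand-class complements,
    sequencing errors and PCR duplication are applied in that order.

    ``intervals`` are 1-based half-open ``(start, end)`` with ``end`` allowed
    to exceed the genome length to denote wrapping around the origin.
    """
    rng = np.random.default_rng(config.seed)
    L = genome.length
    rl = config.read_length
    garr = _seq_to_arr(genome.sequence)

    # per-position true methylation probability, by strand
    p_plus = np.zeros(L)
    p_minus = np.zeros(L)
    plus_rows = methylome[methylome["strand"] == PLUS]
    minus_rows = methylome[methylome["strand"] == MINUS]
    p_plus[plus_rows["position"].to_numpy() - 1] = plus_rows["true_p"].to_numpy()
    p_minus[minus_rows["position"].to_numpy() - 1] = minus_rows["true_p"].to_numpy()

    bases_per_frag = 2 * rl if config.paired else rl
    if n_fragments is None:
        n_fragments = int(round(config.mean_coverage * L / bases_per_frag))
    if n_fragments <= 0:
        raise ValueError("no fragments to simulate")

    if rl > L or (config.paired and config.insert_mean > L):
        raise ValueError(
            f"insert regime (read {rl} bp, insert mean {config.insert_mean:g}) "
            f"exceeds the {L} bp genome"
        )
    inserts = rng.normal(config.insert_mean, config.insert_sd, size=n_fragments)
    inserts = np.clip(np.rint(inserts), rl, min(2 * rl + 400, L)).astype(int)

    if intervals is None:
        starts = rng.integers(0, L, size=n_fragments)  # 0-based, may wrap
    else:
        starts = np.empty(n_fragments, dtype=int)
        norm = [_normalize_interval(iv, L) for iv in intervals]
        which = rng.integers(0, len(norm), size=n_fragments)
        for j, (s0, e0) in enumerate(norm):
            sel = which == j
            span = (e0 - s0) - inserts[sel]
            if (span < 0).any():
                # amplicon shorter than some inserts: shrink those inserts
                inserts[sel] = np.minimum(inserts[sel], e0 - s0)
                span = (e0 - s0) - inserts[sel]
            starts[sel] = s0 + (rng.random(sel.sum()) * (span + 1)).astype(int)
        starts %= L

    if config.non_directional:
        classes = rng.integers(0, 4, size=n_fragments)
    else:
        classes = rng.integers(0, 2, size=n_fragments)  # OT/OB only

    n_dup = int(math.floor(config.duplicate_fraction * n_fragments))
    dup_idx = set(
        rng.choice(n_fragments, size=n_dup, replace=False).tolist() if n_dup else []
    )

    meth_counts = {PLUS: np.zeros(L, dtype=np.int64), MINUS: np.zeros(L, dtype=np.int64)}
    unmeth_counts = {
        PLUS: np.zeros(L, dtype=np.int64),
        MINUS: np.zeros(L, dtype=np.int64),
    }

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    r1_path = Path(str(out_prefix) + "_R1.fastq")
    r2_path = Path(str(out_prefix) + "_R2.fastq") if config.paired else None
    sidecar_path = Path(str(out_prefix) + "_origins.tsv")

    C, G, T, A = (ord(x) for x in "CGTA")
    total_read_bases = 0

    f1 = open(r1_path, "w")
    f2 = open(r2_path, "w") if config.paired else None
    sc = open(sidecar_path, "w")
    sc.write("read_id\tstart\tinsert\tstrand_class\tduplicate\n")
    try:
        for fi in range(n_fragments):
            i0, ins = int(starts[fi]), int(inserts[fi])
            cls = STRAND_CLASSES[int(classes[fi])]
            idx = (i0 + np.arange(ins)) % L
            frag = garr[idx].copy()
            # positions a read actually reports: both mates for paired data,
            # the first read length otherwise
            observed = np.zeros(ins, dtype=bool)
            observed[:rl] = True
            if config.paired:
                observed[max(ins - rl, 0):] = True

            # draw per-molecule methylation on the originating strand and
            # apply conversion chemistry in the plus-co-linear view
            if cls in ("OT", "CTOT"):
                cmask = frag == C
                probs = p_plus[idx[cmask]]
                meth = rng.random(cmask.sum()) < probs
                stays_c = np.where(
                    meth,
                    rng.random(meth.size) < config.methylation_protection,
                    rng.random(meth.size) >= config.conversion_efficiency,
                )
                conv = frag.copy()
                cpos = np.flatnonzero(cmask)
                conv[cpos[~stays_c]] = T
                strand = PLUS
                sites = idx[cmask]
            else:  # OB / CTOB: originating strand is the minus strand
                gmask = frag == G
                probs = p_minus[idx[gmask]]
                meth = rng.random(gmask.sum()) < probs
                stays_c = np.where(
                    meth,
                    rng.random(meth.size) < config.methylation_protection,
                    rng.random(meth.size) >= config.conversion_efficiency,
                )
                conv = frag.copy()
                gpos = np.flatnonzero(gmask)
                conv[gpos[~stays_c]] = A  # converted minus C shows as plus A
                strand = MINUS
                sites = idx[gmask]

            obs = observed[np.flatnonzero(cmask if cls in ("OT", "CTOT") else gmask)]
            np.add.at(meth_counts[strand], sites[meth & obs], 1)
            np.add.at(unmeth_counts[strand], sites[~meth & obs], 1)

            conv_seq = _arr_to_seq(conv)
            if cls in ("OT", "CTOB"):
                read1 = conv_seq[:rl]
                read2 = reverse_complement(conv_seq[-rl:])
            else:  # CTOT / OB: the sequenced molecule is the reverse complement
                read1 = reverse_complement(conv_seq[-rl:])
                read2 = conv_seq[:rl]

            copies = 2 if fi in dup_idx else 1
            for ci in range(copies):
                rid = f"frag{fi:07d}" + ("d" if ci else "")
                s1 = _apply_errors(read1, config.seq_error, rng)
                _write_fastq_record(f1, rid + "/1", s1)
                total_read_bases += rl
                if config.paired:
                    s2 = _apply_errors(read2, config.seq_error, rng)
                    _write_fastq_record(f2, rid + "/2", s2)
                    total_read_bases += rl
                sc.write(f"{rid}\t{i0 + 1}\t{ins}\t{cls}\t{ci}\n")
    finally:
        f1.close()
        if f2:
            f2.close()
        sc.close()

    truth = _truth_frame(methylome, meth_counts, unmeth_counts)
    return SimulatedReads(
        fastq_r1=r1_path,
        fastq_r2=r2_path,
        sidecar=sidecar_path,
        truth=truth,
        n_fragments=n_fragments,
        achieved_coverage=total_read_bases / L,
    )


def _normalize_interval(iv: tuple[int, int], L: int) -> tuple[int, int]:
    """1-based half-open (start, end), end may exceed L to wrap -> 0-based."""
    s, e = iv
    if not (1 <= s <= L) or e <= s:
        raise ValueError(f"bad interval {iv}")
    if e - s > L:
        raise ValueError(f"interval {iv} longer than the genome")
    return s - 1, e - 1


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = _seq_to_arr(seq).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    if hits.size == 0:
        return seq
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for h in hits:
        choices = alphabet[alphabet != arr[h]]
        arr[h] = rng.choice(choices)
    return _arr_to_seq(arr)


def _write_fastq_record(fh, rid: str, seq: str) -> None:
    fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def _truth_frame(methylome, meth_counts, unmeth_counts) -> pd.DataFrame:
    truth = methylome[["position", "strand", "context", "true_p"]].copy()
    pos0 = truth["position"].to_numpy() - 1
    n_meth = np.empty(len(truth), dtype=np.int64)
    n_unmeth = np.empty(len(truth), dtype=np.int64)
    for strand in (PLUS, MINUS):
        m = (truth["strand"] == strand).to_numpy()
        n_meth[m] = meth_counts[strand][pos0[m]]
        n_unmeth[m] = unmeth_counts[strand][pos0[m]]
    truth["n_meth"] = n_meth
    truth["n_unmeth"] = n_unmeth
    return truth


# ---------------------------------------------------------------------------
# long-PCR controls
# ---------------------------------------------------------------------------

@dataclass
class ControlSpec:
    """Long-PCR control design.

    Two overlapping plus-strand amplicon intervals (1-based half-open; an
    ``end`` beyond the genome length wraps past the origin) must jointly
    cover every position.  The negative control is entirely unmethylated
    (PCR products carry no methylation); the positive control is the same
    material treated with a CpG methyltransferase whose per-site efficiency
    is Beta-distributed with mean ``positive_enzyme_mean``.
    """

    amplicons: tuple[tuple[int, int], tuple[int, int]] = ((1, 8501), (8301, 16870))
    positive_enzyme_mean: float = 0.90
    positive_enzyme_concentration: float = 50.0
    seed: int = 0

    def covers(self, L: int) -> bool:
        covered = np.zeros(L, dtype=bool)
        for s, e in self.amplicons:
            s0, e0 = _normalize_interval((s, e), L)
            idx = np.arange(s0, e0) % L
            covered[idx] = True
        return bool(covered.all())


@dataclass
class SimulatedControls:
    negative: SimulatedReads
    positive: SimulatedReads
    enzyme_efficiency: pd.DataFrame  # per-CpG realized enzyme methylation prob


def default_control_spec(L: int, seed: int = 0) -> ControlSpec:
    """Two overlapping ~half-genome amplicons covering the whole circle."""
    half = L // 2
    ovl = max(L // 80, 2)
    return ControlSpec(
        amplicons=((1, half + ovl + 1), (half + 1, L + ovl + 1)), seed=seed
    )


def simulate_controls(
    genotype: CircularGenome,
    spec: ControlSpec,
    config: ReadSimConfig,
    out_prefix,
) -> SimulatedControls:
    """Simulate negative (unmethylated) and positive (enzyme-methylated)
    long-PCR control read sets for one genotype.

    Fragments are confined to the amplicon intervals (linear molecules never
    span an amplicon end).  Raises if the amplicons leave a coverage gap.
    """
    L = genotype.length
    if not spec.covers(L):
        raise ValueError("control amplicons leave a coverage gap on the genome")
    for s, e in spec.amplicons:
        if e - s >= L:
            raise ValueError("each amplicon must be shorter than the genome")

    table = cytosine_table(genotype)
    zero = table.copy()
    zero["true_p"] = 0.0

    rng = np.random.default_rng(spec.seed)
    m, c = spec.positive_enzyme_mean, spec.positive_enzyme_concentration
    is_cpg = (table["context"] == "CpG").to_numpy()
    eff = np.zeros(len(table))
    if m in (0.0, 1.0) or c == 0.0:
        eff[is_cpg] = m
    else:
        eff[is_cpg] = rng.beta(m * c, (1.0 - m) * c, size=int(is_cpg.sum()))
    positive = table.copy()
    positive["true_p"] = eff

    cfg_neg = ReadSimConfig(**{**config.__dict__, "seed": config.seed * 2 + 1})
    cfg_pos = ReadSimConfig(**{**config.__dict__, "seed": config.seed * 2 + 2})
    out_prefix = Path(out_prefix)
    neg = simulate_bisulfite_reads(
        genotype, zero, cfg_neg, str(out_prefix) + "_neg", intervals=spec.amplicons
    )
    pos = simulate_bisulfite_reads(
        genotype, positive, cfg_pos, str(out_prefix) + "_pos", intervals=spec.amplicons
    )
    enzyme = positive[["position", "strand", "context", "true_p"]].rename(
        columns={"true_p": "enzyme_efficiency"}
    )
    return SimulatedControls(negative=neg, positive=pos, enzyme_efficiency=enzyme)


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

@dataclass
class QpcrSimConfig:
    """Log-linear qPCR model: Ct = intercept - log(quantity)/log(efficiency)
    plus Gaussian noise, per replicate."""

    intercept_ct: float = 25.0
    efficiency: float = 2.0
    noise_sd: float = 0.15
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("efficiency must be in (1, 2]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def simulate_qpcr_ct(
    true_quantities: Mapping[str, float], config: QpcrSimConfig
) -> pd.DataFrame:
    """Ct table (sample, replicate, ct) for given relative template amounts."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for sample, q in true_quantities.items():
        if q <= 0:
            raise ValueError(f"non-positive quantity for sample {sample!r}")
        base = config.intercept_ct - math.log(q) / math.log(config.efficiency)
        noise = rng.normal(0.0, config.noise_sd, size=config.replicates)
        for rep in range(config.replicates):
            rows.append((sample, rep + 1, base + float(noise[rep])))
    return pd.DataFrame(rows, columns=["sample", "replicate", "ct"])
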