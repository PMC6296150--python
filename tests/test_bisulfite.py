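"""Alignment, deduplication and methylation extraction."""

import numpy as np
import pytest

from mitomethyl import (
    AlignedFragment,
    BisulfiteAligner,
    CircularGenome,
    coverage_filter,
    deduplicate,
    extract_methylation,
)
from mitomethyl.genome import reverse_complement


def bisulfite_ot_read(genome: CircularGenome, start0: int, length: int) -> str:
    """Fully converted plus-strand read (all C -> T)."""
    s = genome.sequence * 2
    return s[start0: start0 + length].replace("C", "T")


# -- alignment ---------------------------------------------------------------

def test_exact_converted_substring_maps_ot(ref_small):
    aligner = BisulfiteAligner(ref_small)
    read = bisulfite_ot_read(ref_small, 100, 80)
    frag = aligner.align_read("r", read)
    assert frag is not None
    assert (frag.start, frag.strand_class, frag.mismatches) == (101, "OT", 0)


def test_minus_strand_read_maps_ob(ref_small):
    sub = ref_small.sequence[200:280]
    # converted bottom-strand molecule: C -> T on the reverse complement
    read = reverse_complement(sub).replace("C", "T")
    frag = BisulfiteAligner(ref_small).align_read("r", read)
    assert frag is not None
    assert (frag.start, frag.strand_class) == (201, "OB")


def test_repeated_locus_is_ambiguous():
    unit = "ATTGGACCTAGGATCAGGACTTAAGGCACTATTAACCGG"
    g = CircularGenome("rep", unit * 2 + "TTTTAAAATTTTAAAA", circular=True)
    read = unit[:30].replace("C", "T")
    assert BisulfiteAligner(g).align_read("r", read) is None


def test_origin_recovery_against_sidecar(small_run):
    """Error-free fragments must map back to their simulated origin."""
    sc = small_run["sidecar"]
    truth = {r.read_id: (r.start, r.insert, r.strand_class)
             for r in sc.itertuples()}
    aligned = small_run["aligned"]
    n_total = len(small_run["pairs"])
    correct = sum(
        1 for f in aligned
        if truth[f.read_id] == (f.start, f.insert, f.strand_class)
    )
    assert correct / n_total >= 0.999


def test_pair_alignment_spans_origin(ref_small):
    """A fragment crossing the circular junction aligns at its true start."""
    aligner = BisulfiteAligner(ref_small)
    L = ref_small.length
    start0 = L - 60  # 200 bp fragment wrapping the origin
    r1 = bisulfite_ot_read(ref_small, start0, 100)
    r2_src = (ref_small.sequence * 2)[start0 + 100: start0 + 200]
    r2 = reverse_complement(r2_src.replace("C", "T"))
    frag = aligner.align_pair("w", r1, r2)
    assert frag is not None
    assert (frag.start, frag.insert, frag.strand_class) == (start0 + 1, 200, "OT")


def test_rotation_equivariant_alignment(ref_small):
    """Aligning to a rotated genome shifts positions by the rotation."""
    r = 137
    rot = CircularGenome(
        "rot", ref_small.sequence[r:] + ref_small.sequence[:r], circular=True
    )
    a0 = BisulfiteAligner(ref_small)
    a1 = BisulfiteAligner(rot)
    L = ref_small.length
    for start0 in (0, 500, 1500, 2900):
        read = bisulfite_ot_read(ref_small, start0, 90)
        f0 = a0.align_read("r", read)
        f1 = a1.align_read("r", read)
        assert f0 is not None and f1 is not None
        assert (f1.start - 1) % L == (f0.start - 1 - r) % L


def test_n_run_warning():
    g = CircularGenome("n", "ACGT" * 100 + "N" * 300 + "ACGT" * 100)
    with pytest.warns(UserWarning, match="N-run"):
        BisulfiteAligner(g)


# -- deduplication -----------------------------------------------------------

def _frag(start, insert, cls, rid="r"):
    return AlignedFragment(rid, start, insert, cls, 0, True, ((start - 1, "A"),))


def test_dedup_keeps_one_per_key():
    frags = [_frag(10, 200, "OT", "a"), _frag(10, 200, "OT", "b"),
             _frag(10, 200, "OB", "c"), _frag(11, 200, "OT", "d")]
    kept = deduplicate(frags)
    assert [f.read_id for f in kept] == ["a", "c", "d"]  # first encountered wins


def test_dedup_matches_sidecar_exactly(small_run):
    """Retained fragments equal the distinct (start, insert, class) keys
    among simulated fragments — duplicates removed, nothing else."""
    sc = small_run["sidecar"]
    expected = sc.drop_duplicates(["start", "insert", "strand_class"]).shape[0]
    assert len(deduplicate(small_run["aligned"])) == expected


# -- extraction --------------------------------------------------------------

def test_single_ot_read_calls_plus_strand():
    g = CircularGenome("g", "AACGTTAA", circular=False)
    # read shows C at the CpG cytosine (pos 3) -> methylated call
    frag = AlignedFragment("r", 1, 8, "OT", 0, True, ((0, "AACGTTAA"),))
    tab = extract_methylation([frag], g)
    row = tab[(tab.position == 3) & (tab.strand == "+")].iloc[0]
    assert (row.count_methylated, row.count_unmethylated) == (1, 0)
    # and a T at the same site is an unmethylated call
    frag2 = AlignedFragment("r", 1, 8, "OT", 0, True, ((0, "AATGTTAA"),))
    row2 = extract_methylation([frag2], g).set_index(["position", "strand"]).loc[(3, "+")]
    assert (row2.count_methylated, row2.count_unmethylated) == (0, 1)


def test_ob_read_calls_minus_strand():
    g = CircularGenome("g", "AACGTTAA", circular=False)
    # OB segment is stored plus-co-linear: G at position 4 = methylated minus C
    frag = AlignedFragment("r", 1, 8, "OB", 0, True, ((0, "AACGTTAA"),))
    tab = extract_methylation([frag], g).set_index(["position", "strand"])
    assert tab.loc[(4, "-"), "count_methylated"] == 1
    assert tab.loc[(3, "+"), "count_methylated"] == 0  # OB never calls plus


def test_overlapping_mates_counted_once():
    g = CircularGenome("g", "AACGTTAA", circular=False)
    frag = AlignedFragment(
        "r", 1, 8, "OT", 0, True, ((0, "AACGTT"), (2, "CGTTAA")),
    )
    tab = extract_methylation([frag], g).set_index(["position", "strand"])
    assert tab.loc[(3, "+"), "count_methylated"] == 1  # not 2


def test_extraction_matches_truth_exactly(small_run):
    """With perfect chemistry and no errors, extracted counts equal the
    simulator's truth table at every cytosine (both strands)."""
    tab = extract_methylation(small_run["dedup"], small_run["genome"])
    truth = small_run["sim"].truth
    merged = tab.merge(truth, on=["position", "strand", "context"])
    assert len(merged) == len(tab)
    assert (merged.count_methylated == merged.n_meth).all()
    assert (merged.count_unmethylated == merged.n_unmeth).all()


def test_call_conservation(small_run):
    """Total calls at a site never exceed fragment coverage there."""
    g = small_run["genome"]
    L = g.length
    cov = {"+": np.zeros(L, dtype=int), "-": np.zeros(L, dtype=int)}
    for f in small_run["dedup"]:
        strand = "+" if f.strand_class in ("OT", "CTOT") else "-"
        for seg_start, seg in f.segments:
            idx = (seg_start + np.arange(len(seg))) % L
            cov[strand][idx] += 1
    tab = extract_methylation(small_run["dedup"], g)
    for r in tab.itertuples():
        assert r.count_methylated + r.count_unmethylated <= cov[r.strand][r.position - 1]


def test_coverage_filter_boundary():
    g = CircularGenome("g", "AACGTTAA", circular=False)
    frags = [
        AlignedFragment(f"r{i}", 1, 8, "OT", 0, True, ((0, "AACGTTAA"),))
        for i in range(9)
    ]
    tab = extract_methylation(frags, g)
    assert len(coverage_filter(tab, 10)) == 0  # 9 < 10 removed
    assert (coverage_filter(tab, 9)["position"] == 3).any()  # 9 >= 9 retained
    assert len(coverage_filter(tab, 1)) == len(tab[
        tab.count_methylated + tab.count_unmethylated > 0
    ])
    with pytest.raises(ValueError):
        coverage_filter(tab, 0)
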