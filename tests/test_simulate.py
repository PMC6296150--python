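"""The synthetic-data generator: methylomes, reads, controls, qPCR."""

import numpy as np
import pytest

from mitomethyl import (
    CircularGenome,
    ControlSpec,
    GroupEffect,
    MethylomeSpec,
    QpcrSimConfig,
    ReadSimConfig,
    draw_methylome,
    simulate_bisulfite_reads,
    simulate_controls,
    simulate_genotype,
    simulate_qpcr_ct,
    synthetic_reference_genome,
)
from mitomethyl.genome import diff_cpg_profiles, enumerate_cpg_sites


# -- genotype simulation -----------------------------------------------------

def test_simulate_genotype_identity_and_bounds():
    base = CircularGenome("b", "ACGTACGT")
    assert simulate_genotype(base, [], "c").sequence == base.sequence
    with pytest.raises(IndexError):
        simulate_genotype(base, [(0, "A")], "c")
    with pytest.raises(IndexError):
        simulate_genotype(base, [(9, "A")], "c")
    with pytest.raises(ValueError):
        simulate_genotype(base, [(1, "A")], "c")  # no-op substitution


def test_substitution_creates_cpg_pair():
    base = CircularGenome("b", "A" * 99 + "CA" + "A" * 99)
    mut = simulate_genotype(base, [(101, "G")], "m")  # CA -> CG at 100-101
    d = diff_cpg_profiles(mut, base)
    assert {(s.position, s.strand) for s in d.gained} == {(100, "+"), (101, "-")}


def test_synthetic_reference_census():
    ref = synthetic_reference_genome(length=2000, n_cpg_dinucleotides=50, seed=4)
    assert ref.length == 2000
    assert len(enumerate_cpg_sites(ref)) == 100


# -- methylomes --------------------------------------------------------------

def test_methylome_degenerate_all_zero():
    g = synthetic_reference_genome(length=500, n_cpg_dinucleotides=10, seed=1)
    m = draw_methylome(g, MethylomeSpec(cpg_mean=0.0, non_cpg_level=0.0, seed=0))
    assert (m["true_p"] == 0.0).all()


def test_methylome_beta_mean_converges():
    """Law of large numbers at the configured concentration: the sample
    mean over ten thousand CpG draws sits within a point of the mean."""
    g = CircularGenome("dense", "CGA" * 5000)  # 10,000 CpG sites
    m = draw_methylome(g, MethylomeSpec(cpg_mean=0.10, seed=5))
    cpg = m[m["context"] == "CpG"]
    assert len(cpg) == 10_000
    assert abs(cpg["true_p"].mean() - 0.10) < 0.01


def test_methylome_group_effect_additive_shift():
    g = synthetic_reference_genome(length=500, n_cpg_dinucleotides=10, seed=1)
    site = next(
        (r.position, r.strand)
        for r in draw_methylome(g, MethylomeSpec(seed=2)).itertuples()
        if r.context == "CpG"
    )
    spec = MethylomeSpec(
        seed=2,
        group_effects={"up": GroupEffect(sites=frozenset([site]), shift=0.15)},
    )
    base = draw_methylome(g, spec)
    shifted = draw_methylome(g, spec, effects=("up",))
    merged = base.merge(shifted, on=["position", "strand"], suffixes=("_a", "_b"))
    at = merged[(merged.position == site[0]) & (merged.strand == site[1])]
    assert np.isclose(at["true_p_b"], np.clip(at["true_p_a"] + 0.15, 0, 1)).all()
    rest = merged[~((merged.position == site[0]) & (merged.strand == site[1]))]
    assert (rest["true_p_a"] == rest["true_p_b"]).all()


# -- bisulfite read simulation ----------------------------------------------

def test_fragment_count_matches_coverage_identity(tmp_path):
    """Paired 150 bp reads at C-fold coverage need ~C*L/300 fragments."""
    g = synthetic_reference_genome(length=3000, n_cpg_dinucleotides=60, seed=2)
    m = draw_methylome(g, MethylomeSpec(seed=0))
    sim = simulate_bisulfite_reads(
        g, m, ReadSimConfig(mean_coverage=500, seed=0), tmp_path / "cov"
    )
    expected = 500 * 3000 / 300
    assert abs(sim.n_fragments - expected) / expected < 0.01
    assert abs(sim.achieved_coverage - 500) / 500 < 0.11  # duplicates add reads


def test_perfect_conversion_leaves_no_methylated_calls(tmp_path, ref_small):
    """All-unmethylated molecules under complete conversion: every
    cytosine in the truth table is recorded unmethylated."""
    m = draw_methylome(
        ref_small, MethylomeSpec(cpg_mean=0.0, non_cpg_level=0.0, seed=0)
    )
    sim = simulate_bisulfite_reads(
        ref_small,
        m,
        ReadSimConfig(mean_coverage=20, conversion_efficiency=1.0, seq_error=0.0,
                      seed=1),
        tmp_path / "conv",
    )
    assert (sim.truth["n_meth"] == 0).all()
    assert sim.truth["n_unmeth"].sum() > 0


def test_perfect_protection_leaves_no_unmethylated_calls(tmp_path, ref_small):
    m = draw_methylome(
        ref_small, MethylomeSpec(cpg_mean=1.0, non_cpg_level=1.0, seed=0)
    )
    sim = simulate_bisulfite_reads(
        ref_small,
        m,
        ReadSimConfig(mean_coverage=20, methylation_protection=1.0, seq_error=0.0,
                      seed=1),
        tmp_path / "prot",
    )
    assert (sim.truth["n_unmeth"] == 0).all()
    assert sim.truth["n_meth"].sum() > 0


def test_same_seed_byte_identical_fastq(tmp_path, ref_small):
    m = draw_methylome(ref_small, MethylomeSpec(seed=3))
    cfg = ReadSimConfig(mean_coverage=10, seed=42)
    a = simulate_bisulfite_reads(ref_small, m, cfg, tmp_path / "a")
    b = simulate_bisulfite_reads(ref_small, m, cfg, tmp_path / "b")
    assert a.fastq_r1.read_bytes() == b.fastq_r1.read_bytes()
    assert a.fastq_r2.read_bytes() == b.fastq_r2.read_bytes()
    assert a.sidecar.read_text() == b.sidecar.read_text()


def test_insert_longer_than_genome_rejected(tmp_path):
    g = CircularGenome("tiny", "ACGT" * 30)  # 120 bp
    m = draw_methylome(g, MethylomeSpec(seed=0))
    cfg = ReadSimConfig(mean_coverage=5, read_length=100, insert_mean=400,
                        insert_sd=1, seed=0)
    with pytest.raises(ValueError, match="insert"):
        simulate_bisulfite_reads(g, m, cfg, tmp_path / "x")


# -- controls ----------------------------------------------------------------

def test_control_amplicons_must_cover_genome(tmp_path, ref_small):
    cfg = ReadSimConfig(mean_coverage=5, seed=0)
    bad = ControlSpec(amplicons=((1, 1000), (1500, 2500)), seed=0)
    with pytest.raises(ValueError, match="coverage gap"):
        simulate_controls(ref_small, bad, cfg, tmp_path / "bad")
    ok = ControlSpec(amplicons=((1, 1700), (1600, 3100)), seed=0)
    assert ok.covers(ref_small.length)


def test_negative_control_fully_unmethylated(tmp_path, ref_small):
    spec = ControlSpec(amplicons=((1, 1700), (1600, 3100)), seed=1)
    cfg = ReadSimConfig(mean_coverage=30, conversion_efficiency=1.0,
                        seq_error=0.0, seed=2)
    ctl = simulate_controls(ref_small, spec, cfg, tmp_path / "neg")
    assert (ctl.negative.truth["n_meth"] == 0).all()


def test_positive_control_saturates_at_full_enzyme_efficiency(tmp_path, ref_small):
    spec = ControlSpec(
        amplicons=((1, 1700), (1600, 3100)),
        positive_enzyme_mean=1.0, positive_enzyme_concentration=0.0, seed=1,
    )
    cfg = ReadSimConfig(mean_coverage=30, methylation_protection=1.0,
                        seq_error=0.0, seed=2)
    ctl = simulate_controls(ref_small, spec, cfg, tmp_path / "pos")
    cpg = ctl.positive.truth[ctl.positive.truth["context"] == "CpG"]
    assert (cpg["n_unmeth"] == 0).all()
    noncpg = ctl.positive.truth[ctl.positive.truth["context"] != "CpG"]
    assert (noncpg["n_meth"] == 0).all()  # the enzyme is CpG-specific


# -- qPCR --------------------------------------------------------------------

def test_qpcr_ct_noise_free_values():
    cfg = QpcrSimConfig(intercept_ct=25.0, noise_sd=0.0, replicates=2, seed=0)
    table = simulate_qpcr_ct({"unit": 1.0, "double": 2.0}, cfg)
    by = table.groupby("sample")["ct"].mean()
    assert by["unit"] == pytest.approx(25.0)
    assert by["double"] == pytest.approx(24.0)  # one cycle per doubling


def test_qpcr_noise_sd_recovered():
    cfg = QpcrSimConfig(noise_sd=0.15, replicates=1000, seed=9)
    table = simulate_qpcr_ct({"s": 1.0}, cfg)
    assert abs(table["ct"].std() - 0.15) < 0.02


def test_qpcr_rejects_bad_inputs():
    with pytest.raises(ValueError):
        simulate_qpcr_ct({"s": 0.0}, QpcrSimConfig())
    with pytest.raises(ValueError):
        QpcrSimConfig(efficiency=2.5)
    with pytest.raises(ValueError):
        QpcrSimConfig(noise_sd=-1)
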