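import pytest
from hypothesis import settings

from mitomethyl import (
    MethylomeSpec,
    ReadSimConfig,
    align_bisulfite,
    deduplicate,
    draw_methylome,
    simulate_bisulfite_reads,
    synthetic_reference_genome,
)
from mitomethyl.io import read_fastq_pairs, read_sidecar

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref_small():
    """A 3 kb circular genome with 80 CpG dinucleotides."""
    return synthetic_reference_genome(length=3000, n_cpg_dinucleotides=80, seed=7)


@pytest.fixture(scope="session")
def small_run(ref_small, tmp_path_factory):
    """An error-free, fully converted simulated run with its alignment.

    Perfect chemistry (conversion 1.0, protection 1.0, no sequencing
    errors) makes the extracted calls exactly recoverable from the truth
    sidecar, so several oracle-equivalence tests share this run.
    """
    out = tmp_path_factory.mktemp("smallrun")
    meth = draw_methylome(ref_small, MethylomeSpec(seed=1))
    cfg = ReadSimConfig(
        mean_coverage=60,
        seq_error=0.0,
        conversion_efficiency=1.0,
        methylation_protection=1.0,
        duplicate_fraction=0.05,
        seed=3,
    )
    sim = simulate_bisulfite_reads(ref_small, meth, cfg, out / "run")
    pairs = list(read_fastq_pairs(sim.fastq_r1, sim.fastq_r2))
    aligned = align_bisulfite(pairs, ref_small)
    return {
        "genome": ref_small,
        "methylome": meth,
        "sim": sim,
        "pairs": pairs,
        "aligned": aligned,
        "dedup": deduplicate(aligned),
        "sidecar": read_sidecar(sim.sidecar),
    }
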