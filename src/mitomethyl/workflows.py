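"""End-to-end synthetic experiments used for validation and reporting.

Each function runs a complete study-condition experiment from scratch —
generate genomes and methylomes, simulate reads, align, deduplicate,
extract, normalize, test — and returns the headline metrics as a dict.
All randomness derives from a single integer seed through named per-stage
substreams.
"""

from __future__ import annotations

from pathlib import Path
from tempfile import TemporaryDirectory

import numpy as np
import pandas as pd

from .bisulfite import (
    align_bisulfite,
    coverage_filter,
    deduplicate,
    extract_methylation,
    methylation_pct,
)
from .genome import diff_cpg_profiles, enumerate_cpg_sites
from .io import read_fastq_pairs, read_sidecar
from .normalize import compute_full_potential, normalize_profile, validate_sites
from .qpcr import MedipMeasurement, ddct_fold_change, medip_ratio
from .simulate import (
    GroupEffect,
    MethylomeSpec,
    QpcrSimConfig,
    ReadSimConfig,
    default_control_spec,
    draw_methylome,
    simulate_bisulfite_reads,
    simulate_controls,
    simulate_qpcr_ct,
    synthetic_genotypes,
    synthetic_reference_genome,
)
from .stats import GroupDesign, anova_per_site, pairwise_contrasts


def stage_seed(seed: int, stage: str) -> int:
    """Stable named substream below 2**31 derived from the master seed."""
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % 1_000_003
    return (seed * 1_000_003 + h) % (2**31 - 1)


def _run_sample(sim, genome):
    pairs = read_fastq_pairs(sim.fastq_r1, sim.fastq_r2)
    frags = deduplicate(align_bisulfite(pairs, genome))
    return extract_methylation(frags, genome)


def cpg_census(seed: int) -> dict:
    """CpG census and genotype diff on the synthetic genotype stand-ins."""
    genomes = synthetic_genotypes(seed=stage_seed(seed, "genotypes"))
    ref = genomes["hNSC"]
    sites = enumerate_cpg_sites(ref)
    diff = diff_cpg_profiles(genomes["143B"], ref)
    return {
        "genome_length_bp": ref.length,
        "cpg_sites_both_strands": len(sites),
        "tumor_genotype_gained_sites": len(diff.gained),
        "tumor_genotype_lost_sites": len(diff.lost),
    }


def methylation_recovery(
    seed: int,
    length: int = 16569,
    coverage: float = 500.0,
    min_reads: int = 10,
) -> dict:
    """Study-condition recovery: one tumor-like sample plus its long-PCR
    controls at the given coverage, through the whole pipeline.

    Returns the genome-wide mean normalized CpG methylation (true mean
    10%), the per-site absolute errors of the raw estimate and of the
    normalized value against the true methylome, the validated-site count,
    and the control self-normalization anchors.
    """
    genome = synthetic_reference_genome(
        length=length,
        n_cpg_dinucleotides=max(round(length * 435 / 16569), 10),
        seed=stage_seed(seed, "genome"),
    )
    meth = draw_methylome(
        genome, MethylomeSpec(seed=stage_seed(seed, "methylome"))
    )
    with TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        sim = simulate_bisulfite_reads(
            genome, meth,
            ReadSimConfig(mean_coverage=coverage, seed=stage_seed(seed, "reads")),
            tmp / "sample",
        )
        ctl = simulate_controls(
            genome,
            default_control_spec(genome.length, seed=stage_seed(seed, "enzyme")),
            ReadSimConfig(mean_coverage=coverage, seed=stage_seed(seed, "ctrl")),
            tmp / "ctrl",
        )
        neg = _run_sample(ctl.negative, genome)
        pos = _run_sample(ctl.positive, genome)
        samp = _run_sample(sim, genome)

    valid = validate_sites([neg, pos], min_reads=min_reads)
    pot = compute_full_potential(neg, pos, valid)
    prof = normalize_profile(coverage_filter(samp, min_reads), pot)

    truth = meth[meth["context"] == "CpG"]
    raw = coverage_filter(samp, min_reads)
    raw = raw[raw["context"] == "CpG"].copy()
    raw["raw_pct"] = methylation_pct(raw)
    raw_err = raw.merge(truth, on=["position", "strand"])
    norm_err = prof.merge(truth, on=["position", "strand"])

    pos_anchor = normalize_profile(coverage_filter(pos, min_reads), pot)
    neg_anchor = normalize_profile(coverage_filter(neg, min_reads), pot)
    return {
        "validated_cpg_sites": len(valid),
        "total_cpg_sites": len(truth),
        "mean_normalized_pct": float(prof["normalized_pct"].mean()),
        "raw_mae_points": float(
            (raw_err["raw_pct"] - 100.0 * raw_err["true_p"]).abs().mean()
        ),
        "normalized_mae_points": float(
            (norm_err["normalized_pct"] - 100.0 * norm_err["true_p"]).abs().mean()
        ),
        "positive_anchor_min": float(pos_anchor["normalized_pct"].min()),
        "positive_anchor_max": float(pos_anchor["normalized_pct"].max()),
        "negative_anchor_min": float(neg_anchor["normalized_pct"].min()),
        "negative_anchor_max": float(neg_anchor["normalized_pct"].max()),
        "n_normalized_sites": len(prof),
    }


def aligner_oracle(
    seed: int, length: int = 16569, n_fragments: int = 8000
) -> dict:
    """Origin recovery of error-free fragments against the truth sidecar,
    and exactness of duplicate removal."""
    genome = synthetic_reference_genome(seed=stage_seed(seed, "genome"))
    if length != genome.length:
        genome = synthetic_reference_genome(
            length=length, n_cpg_dinucleotides=max(length // 38, 10),
            seed=stage_seed(seed, "genome"),
        )
    meth = draw_methylome(genome, MethylomeSpec(seed=stage_seed(seed, "meth")))
    cfg = ReadSimConfig(
        seq_error=0.0, conversion_efficiency=1.0, methylation_protection=1.0,
        duplicate_fraction=0.05, seed=stage_seed(seed, "reads"),
    )
    with TemporaryDirectory() as tmp:
        sim = simulate_bisulfite_reads(
            genome, meth, cfg, Path(tmp) / "oracle", n_fragments=n_fragments
        )
        pairs = list(read_fastq_pairs(sim.fastq_r1, sim.fastq_r2))
        aligned = align_bisulfite(pairs, genome)
        sidecar = read_sidecar(sim.sidecar)
    truth = {
        r.read_id: (r.start, r.insert, r.strand_class)
        for r in sidecar.itertuples()
    }
    correct = sum(
        1 for f in aligned
        if truth[f.read_id] == (f.start, f.insert, f.strand_class)
    )
    n_total = len(pairs)
    expected_unique = sidecar.drop_duplicates(
        ["start", "insert", "strand_class"]
    ).shape[0]
    return {
        "origin_recovery_pct": 100.0 * correct / n_total,
        "n_fragments": n_total,
        "dedup_retained": len(deduplicate(aligned)),
        "dedup_expected": expected_unique,
    }


def anova_type_one_error(
    seed: int, n_sims: int = 2000, alpha: float = 0.05
) -> dict:
    """Null rejection rate: 3 groups x 3 replicates of equal-mean Gaussian
    noise, one ANOVA per simulated site."""
    rng = np.random.default_rng(stage_seed(seed, "null-anova"))
    data = rng.normal(10.0, 2.0, size=(n_sims, 9))
    positions = np.arange(1, n_sims + 1)
    profiles = {
        f"s{j}": pd.DataFrame(
            {"position": positions, "strand": "+", "normalized_pct": data[:, j]}
        )
        for j in range(9)
    }
    design = GroupDesign(
        {f"s{j}": (f"g{j // 3}", "") for j in range(9)}
    )
    res = anova_per_site(profiles, design, group_by="genotype")
    return {
        "type_one_error_rate": float((res["p_value"] < alpha).mean()),
        "n_simulations": n_sims,
    }


def differential_recovery(
    seed: int,
    length: int = 4000,
    coverage: float = 500.0,
    n_effect_sites: int = 10,
    shift: float = 0.15,
    min_reads: int = 10,
) -> dict:
    """Injected-effect recovery under the joint significance rule.

    Three groups of three replicates share a base methylome; one group
    carries a +15-point shift at ten CpG sites.  Each replicate is an
    independent sequencing run through align -> dedup -> extract ->
    normalize; the affected-vs-control contrast is then tested with the
    joint rule (p < 0.05 and |difference| > 5 points).
    """
    genome = synthetic_reference_genome(
        length=length, n_cpg_dinucleotides=max(length // 40, n_effect_sites * 2),
        seed=stage_seed(seed, "genome"),
    )
    sites = enumerate_cpg_sites(genome)
    rng = np.random.default_rng(stage_seed(seed, "effect-sites"))
    chosen = rng.choice(len(sites), size=n_effect_sites, replace=False)
    effect_sites = frozenset(
        (sites[i].position, sites[i].strand) for i in chosen
    )
    spec_base = dict(
        cpg_mean=0.10, cpg_concentration=20.0,
        group_effects={"hyper": GroupEffect(sites=effect_sites, shift=shift)},
        seed=stage_seed(seed, "methylome"),
    )

    with TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        ctl = simulate_controls(
            genome,
            default_control_spec(genome.length, seed=stage_seed(seed, "enzyme")),
            ReadSimConfig(mean_coverage=coverage, seed=stage_seed(seed, "ctrl")),
            tmp / "ctrl",
        )
        neg = _run_sample(ctl.negative, genome)
        pos = _run_sample(ctl.positive, genome)
        valid = validate_sites([neg, pos], min_reads=min_reads)
        pot = compute_full_potential(neg, pos, valid)

        profiles = {}
        assignment = {}
        for label in ("ctrlgrp", "hyper", "null"):
            meth = draw_methylome(
                genome, MethylomeSpec(**spec_base),
                effects=("hyper",) if label == "hyper" else (),
            )
            for rep in range(3):
                sample = f"{label}{rep}"
                sim = simulate_bisulfite_reads(
                    genome, meth,
                    ReadSimConfig(
                        mean_coverage=coverage,
                        seed=stage_seed(seed, f"reads-{sample}"),
                    ),
                    tmp / sample,
                )
                table = coverage_filter(_run_sample(sim, genome), min_reads)
                profiles[sample] = normalize_profile(table, pot)
                assignment[sample] = (label, "")

    design = GroupDesign(assignment)
    res = pairwise_contrasts(
        profiles, design, [("hyper", "ctrlgrp")],
        alpha=0.05, min_difference=5.0, group_by="genotype",
    )
    is_effect = [
        (int(p), s) in effect_sites
        for p, s in zip(res["position"], res["strand"])
    ]
    is_effect = np.array(is_effect)
    recovered = int(res.loc[is_effect, "passes"].sum())
    null_mask = ~is_effect
    fp_rate = float(res.loc[null_mask, "passes"].mean()) if null_mask.any() else 0.0
    return {
        "injected_sites": n_effect_sites,
        "recovered_sites": recovered,
        "false_positive_pct": 100.0 * fp_rate,
        "n_null_sites": int(null_mask.sum()),
    }


def qpcr_roundtrips(seed: int) -> dict:
    """Noise-free inversion of the qPCR simulator by the quantification
    formulas: a 3:1 MeDIP quantity ratio and a 2-fold expression change."""
    cfg = QpcrSimConfig(noise_sd=0.0, replicates=3, seed=stage_seed(seed, "q1"))
    cts = simulate_qpcr_ct({"m5": 3.0, "m5h": 1.0}, cfg)
    by = cts.groupby("sample")["ct"]
    ratio = medip_ratio(
        MedipMeasurement("s", "O_H", "5mC", tuple(by.get_group("m5"))),
        MedipMeasurement("s", "O_H", "5hmC", tuple(by.get_group("m5h"))),
    )

    rows = []
    for sample, group, q in [("c1", "ctrl", 1.0), ("c2", "ctrl", 1.0),
                             ("t1", "treat", 2.0), ("t2", "treat", 2.0)]:
        cts = simulate_qpcr_ct(
            {"18SrRNA": 50.0, "OAZ1": 2.0, "HPRT1": 0.5, "ND5": q},
            QpcrSimConfig(noise_sd=0.0, replicates=1,
                          seed=stage_seed(seed, f"q-{sample}")),
        )
        rows += [(sample, group, r.sample, r.ct) for r in cts.itertuples()]
    folds = ddct_fold_change(
        pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"]), "ctrl"
    )
    fold = float(folds.loc[folds["group"] == "treat", "fold"].iloc[0])
    return {"medip_ratio_recovered": float(ratio), "ddct_fold_recovered": fold}
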