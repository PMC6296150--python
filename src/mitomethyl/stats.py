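"""Per-site group comparisons of normalized methylation profiles.

The analysis convention reproduced here: normalized per-site methylation
percentages are compared across groups (genotypes, tumor stages) with
one-way ANOVA as an omnibus test and pairwise Welch t-tests for the
tabulated contrasts; a contrast is called significant under the joint rule
p < alpha (default 0.05) *and* |mean difference| > ``min_difference``
percentage points (default 5), with the difference rule switchable per
contrast family (stage contrasts are conventionally reported without it).
Stars encode p < 0.05 / 0.01 / 0.001; no multiple-testing correction is
applied by default (Benjamini-Hochberg available and prominently logged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class GroupDesign:
    """Sample sheet: sample id -> (genotype label, stage label).

    ``group_by`` selects which label (or their combination) defines the
    comparison groups; every group needs at least two samples for variance
    estimation.
    """

    samples: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def groups(self, group_by: str = "combined") -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sample, (genotype, stage) in self.samples.items():
            if group_by == "genotype":
                label = genotype
            elif group_by == "stage":
                label = stage
            elif group_by == "combined":
                label = f"{genotype}:{stage}" if stage else genotype
            else:
                raise ValueError(f"unknown group_by {group_by!r}")
            out.setdefault(label, []).append(sample)
        return out

    def check_replication(self, group_by: str = "combined") -> None:
        for label, members in self.groups(group_by).items():
            if len(members) < 2:
                raise ValueError(
                    f"group {label!r} has {len(members)} sample(s); "
                    "need >= 2 for variance estimation"
                )


def _site_matrix(
    profiles: Mapping[str, pd.DataFrame], value: str = "normalized_pct"
) -> pd.DataFrame:
    """Sites x samples matrix of normalized percentages (inner join:
    sites absent from any sample are skipped and logged)."""
    cols = {}
    for sample, prof in profiles.items():
        cols[sample] = prof.set_index(["position", "strand"])[value]
    mat = pd.DataFrame(cols)
    n_before = len(mat)
    mat = mat.dropna()
    dropped = n_before - len(mat)
    if dropped:
        logger.info("%d site(s) absent from some sample; skipped", dropped)
    return mat


def anova_per_site(
    profiles: Mapping[str, pd.DataFrame],
    design: GroupDesign,
    group_by: str = "combined",
) -> pd.DataFrame:
    """Classical one-way ANOVA per CpG site across >= 2 groups.

    Returns ``position, strand, F, p_value, degenerate``; sites with zero
    total variance take p = 1 by convention and are flagged degenerate.
    """
    design.check_replication(group_by)
    groups = design.groups(group_by)
    if len(groups) < 2:
        raise ValueError("need at least two groups for ANOVA")
    mat = _site_matrix(profiles)
    arrays = [mat[members].to_numpy() for members in groups.values()]
    grand = np.concatenate(arrays, axis=1)
    degenerate = grand.var(axis=1) == 0.0
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance sites are handled by the degenerate convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        F, p = sps.f_oneway(*arrays, axis=1)
    F = np.where(degenerate, 0.0, F)
    p = np.where(degenerate, 1.0, p)
    out = mat.index.to_frame(index=False)
    out["F"] = F
    out["p_value"] = p
    out["degenerate"] = degenerate
    return out


def star_annotation(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05 (strict)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pairwise_contrasts(
    profiles: Mapping[str, pd.DataFrame],
    design: GroupDesign,
    contrasts: Sequence[tuple[str, str]],
    alpha: float = 0.05,
    min_difference: float = 5.0,
    difference_rule: bool | Mapping[tuple[str, str], bool] = True,
    group_by: str = "combined",
    equal_var: bool = False,
    fdr: bool = False,
    annotation: Sequence[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Per-site pairwise contrasts with the joint significance rule.

    For each contrast ``(A, B)`` and site: mean difference (A - B) in
    percentage points and a two-sample t-test p value (Welch by default).
    ``passes`` is True when p < alpha and, where the difference rule is
    enabled for that contrast, |difference| > min_difference.  Optional
    Benjamini-Hochberg correction across sites (per contrast) replaces the
    p values used for the rule and stars.
    """
    design.check_replication(group_by)
    groups = design.groups(group_by)
    mat = _site_matrix(profiles)
    sites = mat.index.to_frame(index=False)
    genome_len = int(sites["position"].max()) if len(sites) else 0
    labels = (
        annotate_sites(list(mat.index), annotation, genome_len)
        if annotation is not None
        else None
    )

    frames = []
    for a, b in contrasts:
        if a not in groups or b not in groups:
            raise KeyError(f"unknown group label in contrast ({a!r}, {b!r})")
        xa = mat[groups[a]].to_numpy()
        xb = mat[groups[b]].to_numpy()
        diff = xa.mean(axis=1) - xb.mean(axis=1)
        degenerate = np.concatenate([xa, xb], axis=1).var(axis=1) == 0.0
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, p = sps.ttest_ind(xa, xb, axis=1, equal_var=equal_var)
        p = np.where(degenerate, 1.0, p)
        p = np.where(np.isnan(p), 1.0, p)
        if fdr:
            logger.warning(
                "Benjamini-Hochberg FDR applied across %d sites for contrast "
                "%s vs %s", len(p), a, b
            )
            p = sps.false_discovery_control(p, method="bh")
        use_rule = (
            difference_rule.get((a, b), True)
            if isinstance(difference_rule, Mapping)
            else difference_rule
        )
        passes = (p < alpha) & (
            (np.abs(diff) > min_difference) if use_rule else True
        )
        frame = sites.copy()
        frame["contrast"] = f"{a} vs {b}"
        frame["mean_a"] = xa.mean(axis=1)
        frame["mean_b"] = xb.mean(axis=1)
        frame["mean_difference"] = diff
        frame["p_value"] = p
        frame["stars"] = [star_annotation(float(v)) for v in p]
        frame["passes"] = passes
        if labels is not None:
            frame.insert(2, "annotation", labels)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def annotate_sites(
    sites: Sequence[tuple[int, str]],
    annotation_map: Sequence[tuple[str, int, int]],
    genome_length: int,
) -> list[str]:
    """Label sites by the containing feature interval, else "Non-coding".

    ``annotation_map`` rows are ``(label, start, end)`` in 1-based inclusive
    plus-strand coordinates; an interval with start > end wraps the origin.
    The first matching interval wins; a site covered by several features is
    labelled by the first and a warning is logged once.
    """
    def contains(start: int, end: int, pos: int) -> bool:
        if start <= end:
            return start <= pos <= end
        return pos >= start or pos <= end  # wraps the origin

    labels = []
    warned = False
    for pos, _strand in sites:
        if genome_length and not 1 <= pos <= genome_length:
            raise ValueError(f"site position {pos} outside [1, {genome_length}]")
        hits = [lab for lab, s, e in annotation_map if contains(s, e, pos)]
        if len(hits) > 1 and not warned:
            logger.warning(
                "site %d covered by multiple features (%s); first match wins",
                pos, ", ".join(hits),
            )
            warned = True
        labels.append(hits[0] if hits else "Non-coding")
    return labels
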