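"""qPCR quantification: MeDIP 5mC/5hmC ratios, delta-delta-Ct expression,
and methylation-expression correlation.

Ct (threshold cycle) is log-linear in template amount: one cycle fewer
means ``efficiency``-fold more template (efficiency 2 = perfect doubling).
The 5mC/5hmC ratio for a region is the fold difference between the two
antibody pull-downs; relative gene expression uses the delta-delta-Ct
scheme with the arithmetic mean of three reference-gene Cts (18SrRNA,
OAZ1, HPRT1) as the internal control and a designated control group as the
unit baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_GENES = ("18SrRNA", "OAZ1", "HPRT1")


@dataclass(frozen=True)
class MedipMeasurement:
    """Replicate Ct values for one (sample, region, antibody) pull-down."""

    sample: str
    region: str
    antibody: str  # "5mC" or "5hmC"
    cts: tuple

    def __post_init__(self) -> None:
        if not self.cts:
            raise ValueError("need at least one Ct replicate")
        if any(ct <= 0 for ct in self.cts):
            raise ValueError("Ct values must be positive")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.cts))


def medip_ratio(
    m5: MedipMeasurement,
    m5h: MedipMeasurement,
    efficiency: float = 2.0,
) -> float:
    """5mC/5hmC relative quantity for one sample and region.

    Replicate Cts are averaged first; the ratio is
    ``efficiency ** (mean Ct_5hmC - mean Ct_5mC)`` — a lower 5mC Ct than
    5hmC Ct means more methylated than hydroxymethylated template.
    """
    if (m5.sample, m5.region) != (m5h.sample, m5h.region):
        raise ValueError(
            "5mC and 5hmC measurements must share sample and region "
            f"({m5.sample}/{m5.region} vs {m5h.sample}/{m5h.region})"
        )
    return efficiency ** (m5h.mean_ct - m5.mean_ct)


def medip_ratio_table(
    measurements: Sequence[MedipMeasurement], efficiency: float = 2.0
) -> pd.DataFrame:
    """All 5mC/5hmC ratios found by pairing antibodies per (sample, region)."""
    by_key: dict[tuple[str, str], dict[str, MedipMeasurement]] = {}
    for m in measurements:
        by_key.setdefault((m.sample, m.region), {})[m.antibody] = m
    rows = []
    for (sample, region), d in sorted(by_key.items()):
        if "5mC" in d and "5hmC" in d:
            rows.append(
                (sample, region, medip_ratio(d["5mC"], d["5hmC"], efficiency))
            )
    return pd.DataFrame(rows, columns=["sample", "region", "ratio_5mC_5hmC"])


def ddct_fold_change(
    table: pd.DataFrame,
    control_group: str,
    reference_genes: Sequence[str] = DEFAULT_REFERENCE_GENES,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Relative expression by the delta-delta-Ct method.

    ``table`` columns: ``sample, group, gene, ct`` (one row per measured
    gene per sample; replicate wells should be averaged upstream).  Per
    sample, dCt = Ct_gene - mean(reference-gene Cts); per gene,
    ddCt = dCt - mean dCt over control-group samples; fold =
    efficiency**(-ddCt).  Samples missing any reference gene are excluded
    with a warning.

    Returns per-sample folds with columns ``gene, group, sample, fold``
    plus group-level ``fold_mean``/``fold_sem`` merged per (gene, group).
    """
    if control_group not in set(table["group"]):
        raise ValueError(f"control group {control_group!r} not present")
    piv = table.pivot_table(index="sample", columns="gene", values="ct")
    sample_group = table.drop_duplicates("sample").set_index("sample")["group"]

    missing = [g for g in reference_genes if g not in piv.columns]
    if missing:
        raise ValueError(f"reference gene(s) {missing} absent from the table")
    ok = piv[list(reference_genes)].notna().all(axis=1)
    for bad in piv.index[~ok]:
        logger.warning("sample %s missing a reference gene Ct; excluded", bad)
    piv = piv[ok]

    ref_mean = piv[list(reference_genes)].mean(axis=1)
    target_genes = [g for g in piv.columns if g not in reference_genes]
    dct = piv[target_genes].sub(ref_mean, axis=0)

    control_samples = [s for s in piv.index if sample_group[s] == control_group]
    if not control_samples:
        raise ValueError("no usable control-group samples")
    ddct = dct.sub(dct.loc[control_samples].mean(axis=0), axis=1)
    fold = efficiency ** (-ddct)

    long = fold.reset_index().melt(
        id_vars="sample", var_name="gene", value_name="fold"
    ).dropna(subset=["fold"])
    long["group"] = long["sample"].map(sample_group)
    summary = (
        long.groupby(["gene", "group"])["fold"]
        .agg(fold_mean="mean", fold_sem="sem")
        .reset_index()
    )
    return long.merge(summary, on=["gene", "group"])[
        ["gene", "group", "sample", "fold", "fold_mean", "fold_sem"]
    ]


@dataclass(frozen=True)
class CorrelationResult:
    r_squared: float
    p_value: float
    slope_sign: int  # +1, -1 or 0
    n: int
    undefined: bool = False


def correlate_methylation_expression(
    site_group_means: Mapping[str, float],
    expression: Mapping[str, Sequence[float]],
) -> CorrelationResult:
    """Pearson correlation between site methylation and gene expression.

    Each expression replicate of a group is paired with that group's mean
    methylation percentage; requires >= 3 paired points.  Returns R², the
    two-sided p value of the correlation, and the slope sign (to report
    e.g. a significant *negative* correlation).  Zero variance in either
    variable makes the correlation undefined and is flagged rather than
    raised.
    """
    xs, ys = [], []
    for group, folds in expression.items():
        if group not in site_group_means:
            raise KeyError(f"no methylation value for group {group!r}")
        for f in folds:
            xs.append(site_group_means[group])
            ys.append(float(f))
    if len(xs) < 3:
        raise ValueError("need at least 3 paired points for a correlation")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if x.std() == 0.0 or y.std() == 0.0:
        return CorrelationResult(math.nan, math.nan, 0, len(xs), undefined=True)
    r, p = sps.pearsonr(x, y)
    sign = 0 if r == 0 else (1 if r > 0 else -1)
    return CorrelationResult(float(r * r), float(p), sign, len(xs))
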