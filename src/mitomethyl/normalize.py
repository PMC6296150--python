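"""Control-anchored "full potential" normalization of CpG methylation.

Long-PCR products carry no methylation, so an untreated (negative) control
measures the bisulfite conversion-failure background at each site, while
the same material treated with a CpG methyltransferase (positive control)
measures the achievable ceiling.  The difference between the two percent
methylation values is the site's *full potential*, taken as 100%; sample
methylation is expressed relative to that range.

Only CpG sites covered by at least ``min_reads`` reads in every control
sample are considered validated; sites whose potential falls below
``min_potential`` percentage points are excluded from normalization to
avoid dividing by an unreliable range at enzyme-resistant sites.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bisulfite import methylation_pct

logger = logging.getLogger(__name__)

NORMALIZATION_MODES = ("baseline", "ratio")


def validate_sites(
    control_tables: Sequence[pd.DataFrame], min_reads: int = 10
) -> set[tuple[int, str]]:
    """CpG sites covered by >= ``min_reads`` in *all* control tables.

    Takes cytosine call tables (one per control sample; at least one
    negative and one positive) and returns the validated ``(position,
    strand)`` set.  An empty intersection is returned with a warning rather
    than raised.
    """
    if len(control_tables) < 2:
        raise ValueError("need at least two control tables (negative and positive)")
    valid: set[tuple[int, str]] | None = None
    for table in control_tables:
        cpg = table[table["context"] == "CpG"]
        cov = cpg["count_methylated"] + cpg["count_unmethylated"]
        ok = {
            (int(p), s)
            for p, s in zip(cpg.loc[cov >= min_reads, "position"],
                            cpg.loc[cov >= min_reads, "strand"])
        }
        valid = ok if valid is None else (valid & ok)
    assert valid is not None
    if not valid:
        logger.warning("no CpG site passed coverage validation in all controls")
    return valid


def compute_full_potential(
    negative: pd.DataFrame,
    positive: pd.DataFrame,
    valid_sites: Iterable[tuple[int, str]],
    min_potential: float = 10.0,
) -> pd.DataFrame:
    """Per-site methylation range spanned by the controls.

    Returns rows ``position, strand, negative_pct, positive_pct,
    potential_points, valid`` where ``potential_points = positive_pct -
    negative_pct`` and ``valid`` additionally requires ``potential_points
    >= min_potential``.  Sites missing from either control table are marked
    invalid and logged.
    """
    def pct_map(table: pd.DataFrame) -> dict:
        pct = methylation_pct(table)
        return {
            (int(p), s): float(v)
            for p, s, v in zip(table["position"], table["strand"], pct)
        }

    neg = pct_map(negative)
    pos = pct_map(positive)
    rows = []
    for site in sorted(valid_sites, key=lambda s: (s[0], s[1])):
        npct, ppct = neg.get(site), pos.get(site)
        if npct is None or ppct is None or np.isnan(npct) or np.isnan(ppct):
            logger.warning("site %s missing from a control table; marked invalid", site)
            rows.append((site[0], site[1], np.nan, np.nan, np.nan, False))
            continue
        potential = ppct - npct
        rows.append(
            (site[0], site[1], npct, ppct, potential, bool(potential >= min_potential))
        )
    return pd.DataFrame(
        rows,
        columns=["position", "strand", "negative_pct", "positive_pct",
                 "potential_points", "valid"],
    )


def normalize_profile(
    sample: pd.DataFrame,
    potentials: pd.DataFrame,
    mode: str = "baseline",
) -> pd.DataFrame:
    """Normalize a coverage-filtered sample call table by the full potentials.

    ``baseline`` (default): normalized = (raw - negative) / potential * 100,
    i.e. the negative control is the zero anchor and the positive control
    the 100 anchor.  ``ratio``: normalized = raw / potential * 100 without
    baseline subtraction.  Both are clamped to [0, 100]; only valid sites
    present in the sample are returned.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    pct = methylation_pct(sample)
    raw = {
        (int(p), s): float(v)
        for p, s, v in zip(sample["position"], sample["strand"], pct)
    }
    rows = []
    for _, r in potentials[potentials["valid"]].iterrows():
        site = (int(r["position"]), r["strand"])
        if site not in raw or np.isnan(raw[site]):
            continue
        if r["potential_points"] <= 0:
            logger.warning("non-positive potential at %s; site skipped", site)
            continue
        x = raw[site]
        if mode == "baseline":
            norm = (x - r["negative_pct"]) / r["potential_points"] * 100.0
        else:
            norm = x / r["potential_points"] * 100.0
        rows.append((site[0], site[1], x, float(np.clip(norm, 0.0, 100.0))))
    return pd.DataFrame(
        rows, columns=["position", "strand", "raw_pct", "normalized_pct"]
    )
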