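"""Readers and writers for the pipeline's tabular artifacts.

The cytosine report follows the common bisulfite cytosine-report field
order — sequence name, 1-based position, strand, count methylated, count
unmethylated, context, trinucleotide — so third-party reports can be
ingested; a minimal 5-column dialect (without context/trinucleotide, or
without name) is tolerated on read.
"""

from __future__ import annotations

import gzip
import json
import platform
from pathlib import Path
from typing import Iterator

import pandas as pd
import yaml

from . import __version__

_REPORT_COLUMNS = [
    "position", "strand", "count_methylated", "count_unmethylated",
    "context", "trinucleotide",
]


def write_cytosine_report(table: pd.DataFrame, path, name: str = "MT") -> None:
    """Write a cytosine call table as a 7-column cytosine report TSV."""
    out = table[_REPORT_COLUMNS].copy()
    out.insert(0, "name", name)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a cytosine report, tolerating the 7-column dialect and a
    minimal 5-column variant (position, strand, meth, unmeth, context)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    ncol = df.shape[1]
    if ncol == 7:
        df = df.iloc[:, 1:]
        df.columns = _REPORT_COLUMNS
    elif ncol == 6:
        df.columns = _REPORT_COLUMNS
    elif ncol == 5:
        df.columns = _REPORT_COLUMNS[:5]
        df["trinucleotide"] = "NNN"
    else:
        raise ValueError(f"unrecognized cytosine report with {ncol} columns: {path}")
    df["position"] = df["position"].astype(int)
    for c in ("count_methylated", "count_unmethylated"):
        df[c] = df[c].astype(int)
    return df.reset_index(drop=True)


def read_fastq_pairs(r1_path, r2_path=None) -> Iterator[tuple[str, str, str | None]]:
    """Yield (read id, read1, read2 or None) from FASTQ file(s).

    Mate files must be position-matched; a trailing ``/1``/``/2`` on the id
    is stripped.  Gzipped input is detected by suffix.
    """
    def records(path):
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            while True:
                header = fh.readline()
                if not header:
                    return
                seq = fh.readline().strip()
                fh.readline()
                fh.readline()
                yield header[1:].split()[0], seq

    it1 = records(r1_path)
    if r2_path is None:
        for rid, seq in it1:
            yield rid.rsplit("/", 1)[0], seq, None
        return
    it2 = records(r2_path)
    for (rid1, s1), (rid2, s2) in zip(it1, it2):
        base1 = rid1.rsplit("/", 1)[0]
        base2 = rid2.rsplit("/", 1)[0]
        if base1 != base2:
            raise ValueError(f"mate id mismatch: {rid1} vs {rid2}")
        yield base1, s1, s2


def read_sidecar(path) -> pd.DataFrame:
    """Read a simulator origin sidecar TSV."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def write_manifest(path, stage: str, inputs: dict, parameters: dict,
                   seed: int | None, outputs: dict) -> None:
    """One JSON manifest per run: provenance for every written artifact."""
    manifest = {
        "stage": stage,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": parameters,
        "seed": seed,
        "outputs": outputs,
        "versions": {
            "mitomethyl": __version__,
            "python": platform.python_version(),
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
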