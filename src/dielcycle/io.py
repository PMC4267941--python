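"""Readers/writers for the pipeline's tabular and sequence formats.

Expression matrices travel as TSV with a ``gene_id`` column and one column
per sample, headers encoding clock time and day as ``ZT<h>_day<d>``.
Promoters are FASTA; pair tables, fits, clusters and enrichment results
are plain TSV; configuration is YAML and the run manifest JSON.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import ExpressionMatrix
from .layout import SamplingLayout

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_fasta",
    "write_fasta",
    "read_pairs_tsv",
    "load_config",
    "write_manifest",
]

log = logging.getLogger("dielcycle")

_HEADER_RE = re.compile(r"^ZT(?P<zt>[0-9.]+)_day(?P<day>\d+)$")


def _layout_from_headers(columns) -> SamplingLayout:
    parsed = []
    for c in columns:
        m = _HEADER_RE.match(c)
        if not m:
            raise ValueError(f"malformed sample header {c!r} (want ZT<h>_day<d>)")
        parsed.append((float(m.group("zt")), int(m.group("day"))))
    zts = sorted({z for z, _ in parsed})
    days = sorted({d for _, d in parsed})
    if len(zts) < 2:
        raise ValueError("need at least two ZT points")
    interval = zts[1] - zts[0]
    day_length = interval * len(zts)
    return SamplingLayout(
        interval_hours=interval, day_length_hours=day_length, n_days=len(days)
    )


def read_expression_tsv(path) -> ExpressionMatrix:
    """Load an expression TSV; the layout is inferred from the headers.

    Genes with any missing sample are dropped (with a logged count) and
    values are coerced nonnegative by clipping at zero.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids")
    layout = _layout_from_headers(df.columns)
    # order columns by (day, ZT) regardless of file order
    key = [(int(_HEADER_RE.match(c)["day"]), float(_HEADER_RE.match(c)["zt"]))
           for c in df.columns]
    df = df.iloc[:, sorted(range(len(key)), key=key.__getitem__)]
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        log.warning("dropping %d genes with missing values", n_missing)
        df = df.dropna()
    df = df.clip(lower=0)
    return ExpressionMatrix(df, layout)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=g, description="") for g, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_pairs_tsv(path) -> pd.DataFrame:
    """Duplicate- or ortholog-pair table (TSV with a header row)."""
    return pd.read_csv(path, sep="\t")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def write_manifest(path, **entries) -> None:
    """JSON run manifest recording versions, seeds and thresholds."""
    import dielcycle

    manifest = {"dielcycle_version": dielcycle.__version__, **entries}

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=default)
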