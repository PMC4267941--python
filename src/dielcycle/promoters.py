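"""Promoter extraction from a genome FASTA and GFF3 gene models.

The promoter of a gene is the region immediately upstream of its
transcription start site (default 1 kb), truncated wherever it would
overlap another annotated gene body, and reverse-complemented for
minus-strand genes so every returned sequence reads 5'->3' toward the TSS.
Coordinates are handled 0-based half-open internally (GFF3's 1-based
closed intervals are converted on input).
"""

from __future__ import annotations

import warnings

import numpy as np
from pyfaidx import Fasta

from .motifs import reverse_complement

__all__ = ["extract_promoters", "read_gene_models"]


def read_gene_models(gff_path) -> list[dict]:
    """Gene features from a GFF3 file as 0-based half-open intervals."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for feat in db.features_of_type("gene"):
        genes.append(
            {
                "gene_id": feat.id,
                "seqid": feat.seqid,
                "start": feat.start - 1,  # to 0-based half-open
                "end": feat.end,
                "strand": feat.strand,
            }
        )
    return genes


def extract_promoters(
    gff_path,
    genome_fasta,
    length: int = 1000,
    min_length: int = 50,
) -> dict[str, str]:
    """Extract per-gene promoter sequences.

    For a plus-strand gene with TSS at position t the promoter interval is
    ``[t - length, t)``; for a minus-strand gene with TSS at t (its end
    coordinate) it is ``[t, t + length)`` reverse-complemented.  Bases
    overlapping any other gene body are trimmed by truncating the interval
    at the nearest overlap; promoters shorter than ``min_length`` after
    trimming (or clipping at a contig edge) are dropped with a warning.
    """
    genes = read_gene_models(gff_path)
    fasta = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    by_contig: dict[str, list[dict]] = {}
    for g in genes:
        by_contig.setdefault(g["seqid"], []).append(g)

    promoters: dict[str, str] = {}
    dropped = []
    for g in genes:
        contig = g["seqid"]
        if contig not in fasta:
            raise KeyError(f"contig {contig!r} missing from FASTA")
        contig_len = len(fasta[contig])
        others = [o for o in by_contig[contig] if o["gene_id"] != g["gene_id"]]
        if g["strand"] == "-":
            tss = g["end"]
            start, end = tss, min(tss + length, contig_len)
            # truncate at the nearest downstream-overlapping gene body
            for o in others:
                if o["start"] < end and o["end"] > start:
                    end = min(end, o["start"]) if o["start"] >= start else start
            seq = reverse_complement(str(fasta[contig][start:end]))
        else:
            tss = g["start"]
            start, end = max(tss - length, 0), tss
            for o in others:
                if o["start"] < end and o["end"] > start:
                    start = max(start, o["end"]) if o["end"] <= end else end
            seq = str(fasta[contig][start:end])
        if len(seq) < min_length:
            dropped.append(g["gene_id"])
            continue
        promoters[g["gene_id"]] = seq
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} promoters shorter than {min_length} bp"
        )
    return promoters
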