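"""Shared I/O: FASTA, TSV tables, anchor files and SAM/BAM ingestion.

All tabular output is tab-delimited UTF-8 with a header row and ``.`` for
missing values. FASTA parsing follows the standard conventions (``>``
headers, first whitespace-delimited token is the id, wrapped lines,
case-insensitive sequence).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .records import AnchorRecord, CdsRecord, FootprintRead, ProteinRecord

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_fasta(path: PathLike, kind: str = "protein"):
    """Read a protein or CDS FASTA into validated records.

    Duplicate gene ids raise; ``kind`` selects the record type
    (``"protein"`` strips a trailing stop marker, ``"cds"`` validates the
    nucleotide alphabet).
    """
    if kind not in ("protein", "cds"):
        raise ValueError(f"unknown FASTA kind {kind!r}")
    cls = ProteinRecord if kind == "protein" else CdsRecord
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate gene id {rec.id!r}")
        seen.add(rec.id)
        records.append(cls(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Sequence, path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_tsv(df: pd.DataFrame, path: PathLike, index: bool = True) -> None:
    df.to_csv(path, sep="\t", na_rep=".", index=index)


def read_tsv(path: PathLike, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."], index_col=index_col)


def read_reads_tsv(path: PathLike) -> List[FootprintRead]:
    """Footprint table: columns gene_id, five_prime, length."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "five_prime", "length"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return [
        FootprintRead(str(r.gene_id), int(r.five_prime), int(r.length))
        for r in df.itertuples(index=False)
    ]


def write_reads_tsv(reads: Sequence[FootprintRead], path: PathLike) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in reads],
            "five_prime": [r.five_prime for r in reads],
            "length": [r.length for r in reads],
        }
    ).to_csv(path, sep="\t", index=False)


def read_anchors(path: PathLike) -> List[AnchorRecord]:
    """Anchor table: columns gene_id, anchor (1-based nt), optional kind."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "anchor"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns gene_id, anchor")
    has_kind = "kind" in df.columns
    return [
        AnchorRecord(
            str(r.gene_id), int(r.anchor), str(r.kind) if has_kind else ""
        )
        for r in df.itertuples(index=False)
    ]


def ingest_alignments(path: PathLike) -> List[FootprintRead]:
    """Reduce a SAM/BAM of CDS-mapped footprints to (gene, 5', length).

    Only primary, uniquely-mapped records are kept: unmapped, secondary and
    supplementary alignments are skipped, as are reads whose ``NH`` tag
    reports multiple hits. The reference name is taken as the gene id and
    the 1-based leftmost position as the footprint 5' end.
    """
    import pysam

    reads: List[FootprintRead] = []
    skipped = 0
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                skipped += 1
                continue
            if aln.has_tag("NH") and aln.get_tag("NH") > 1:
                skipped += 1
                continue
            length = aln.query_length or aln.infer_query_length()
            if not length:
                skipped += 1
                continue
            reads.append(
                FootprintRead(aln.reference_name, aln.reference_start + 1, length)
            )
    if skipped:
        logger.info("skipped %d non-primary/multi-mapped alignment(s)", skipped)
    return reads


def hits_table(hits: Sequence) -> pd.DataFrame:
    """Hits as a tidy table (gene_id, kind, start, end, value)."""
    return pd.DataFrame(
        {
            "gene_id": [h.gene_id for h in hits],
            "kind": [h.kind for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "value": [h.value for h in hits],
        }
    )


def venn_table(venn: Dict) -> pd.DataFrame:
    rows = [
        {"region": "+".join(sorted(region)), "count": count}
        for region, count in sorted(venn.items(), key=lambda kv: sorted(kv[0]))
    ]
    return pd.DataFrame(rows)
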