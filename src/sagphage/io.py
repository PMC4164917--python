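"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA goes through Biopython. GFF3 is read and written directly (nine
tab-separated columns; gene metadata travels in the attributes column) so
that the characterization flag and hallmark category survive a round trip.
Precomputed similarity searches are accepted as 12-column tab-separated
hit tables (the classic blast outfmt-6 layout), which lets real search
output stand in for the in-repo aligner at any stage.
"""

from __future__ import annotations

import logging
import urllib.parse
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    Contig,
    ContigRole,
    Gene,
    HallmarkCategory,
    SimilarityHit,
    check_unique_ids,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(
    path: str | Path,
    *,
    source_id: str = "",
    role: ContigRole = ContigRole.SAG_ASSEMBLY,
) -> list[Contig]:
    """Read nucleotide FASTA into contigs.

    Raises on duplicate record ids and on non-nucleotide characters
    (position reported). An empty file yields an empty list with a warning.
    """
    contigs: list[Contig] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        contigs.append(
            Contig(id=rec.id, source_id=source_id, sequence=str(rec.seq), role=role)
        )
    check_unique_ids(contigs, "contig")
    if not contigs:
        logger.warning("FASTA file %s contains no records", path)
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, *, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_protein_fasta(proteins: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in proteins.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLUMNS = 9


def _fmt_attrs(gene: Gene) -> str:
    parts = [
        f"ID={urllib.parse.quote(gene.id)}",
        f"product={urllib.parse.quote(gene.annotation_text)}",
        f"characterized={'true' if gene.characterized else 'false'}",
        f"hallmark_category={gene.hallmark_category.value}",
    ]
    if gene.protein:
        parts.append(f"translation={gene.protein}")
    return ";".join(parts)


def _parse_attrs(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = urllib.parse.unquote(value.strip())
    return out


def write_gff3(genes: Iterable[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig_id, g.start)):
            row = [
                g.contig_id,
                "sagphage",
                "CDS",
                str(g.start),
                str(g.end),
                ".",
                g.strand,
                "0",
                _fmt_attrs(g),
            ]
            fh.write("\t".join(row) + "\n")


def read_gff3(path: str | Path, contigs: Sequence[Contig]) -> list[Gene]:
    """Read CDS features into genes, validating against the contig set.

    Coordinates are 1-based inclusive. Unknown seqids and coordinates
    outside the parent contig are rejected.
    """
    lengths = {c.id: c.length for c in contigs}
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_GFF_COLUMNS} columns, got {len(cols)}"
                )
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype not in ("CDS", "gene"):
                continue
            if seqid not in lengths:
                raise ValueError(f"{path}:{lineno}: unknown seqid {seqid!r}")
            start_i, end_i = int(start), int(end)
            if not (1 <= start_i <= end_i <= lengths[seqid]):
                raise ValueError(
                    f"{path}:{lineno}: interval {start_i}..{end_i} outside "
                    f"contig {seqid!r} (length {lengths[seqid]})"
                )
            a = _parse_attrs(attrs)
            genes.append(
                Gene(
                    id=a.get("ID", f"{seqid}:{start_i}-{end_i}"),
                    contig_id=seqid,
                    start=start_i,
                    end=end_i,
                    strand=strand,
                    protein=a.get("translation", ""),
                    characterized=a.get("characterized", "false") == "true",
                    annotation_text=a.get("product", ""),
                    hallmark_category=HallmarkCategory(
                        a.get("hallmark_category", "none")
                    ),
                )
            )
    check_unique_ids(genes, "gene")
    return genes


# ---------------------------------------------------------------------------
# Tabular hits (12-column, blast outfmt-6 layout)


def read_hits_tabular(path: str | Path, kind: str) -> list[SimilarityHit]:
    """Read a 12-column tab-separated hit table.

    Columns: query, subject, identity, aln_length, mismatches, gaps,
    qstart, qend, sstart, send, evalue, bitscore. Malformed rows raise
    with the offending line number.
    """
    if kind not in ("protein", "nucleotide"):
        raise ValueError(f"kind must be 'protein' or 'nucleotide', got {kind!r}")
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            try:
                hit = SimilarityHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    kind=kind,
                    identity=float(cols[2]),
                    aln_length=int(cols[3]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    s_start=int(cols[8]),
                    s_end=int(cols[9]),
                    evalue=float(cols[10]),
                    bit_score=float(cols[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_hits_tabular(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.identity:.2f}",
                        h.aln_length,
                        0,
                        0,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        f"{h.evalue:.3g}",
                        f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )
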