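"""Core domain types shared by every pipeline stage.

The pipeline operates on assembled contigs (from single-cell amplified
genomes, metagenomes, or viral references), oriented genes on those contigs,
and pairwise similarity evidence (protein- or nucleotide-level hits, and
protein-domain hits used to decide whether a gene is functionally
characterized).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

NUCLEOTIDES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ContigRole(str, enum.Enum):
    SAG_ASSEMBLY = "sag_assembly"
    METAGENOME = "metagenome"
    VIRAL_REFERENCE = "viral_reference"


class HallmarkCategory(str, enum.Enum):
    """Virion-associated gene classes diagnostic of a viral contig."""

    VIRION_STRUCTURE = "virion_structure"
    CAPSID = "capsid"
    PORTAL = "portal"
    TAIL = "tail"
    TERMINASE = "terminase"
    NONE = "none"


@dataclass
class Contig:
    """A nucleotide sequence with provenance and (optional) topology.

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    source_id : str
        The SAG, metagenome or reference collection the contig belongs to.
    sequence : str
        Upper-case nucleotide sequence over ``{A, C, G, T, N}``.
    role : ContigRole
        Where the contig comes from.
    circular : bool
        Whether the molecule is circular (e.g. complete ssDNA phage genomes).
    """

    id: str
    source_id: str
    sequence: str
    role: ContigRole = ContigRole.SAG_ASSEMBLY
    circular: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - NUCLEOTIDES
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise ValueError(
                f"contig {self.id!r}: non-nucleotide character "
                f"{self.sequence[pos]!r} at position {pos + 1}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Gene:
    """An oriented coding interval on a contig (1-based, inclusive).

    The interval spans the start codon through the last sense codon; the
    stop codon lies just outside the interval, so the protein length equals
    ``(end - start + 1) / 3``.
    """

    id: str
    contig_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    protein: str = ""
    characterized: bool = False
    annotation_text: str = ""
    hallmark_category: HallmarkCategory = HallmarkCategory.NONE

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id!r}: strand must be '+' or '-'")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.id!r}: invalid interval {self.start}..{self.end}"
            )
        if self.hallmark_category is not HallmarkCategory.NONE and not self.annotation_text:
            raise ValueError(
                f"gene {self.id!r}: hallmark category requires annotation text"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def nucleotide_sequence(self, contig: Contig) -> str:
        """Coding-strand nucleotide sequence of the gene."""
        if self.end > contig.length:
            raise ValueError(
                f"gene {self.id!r}: end {self.end} beyond contig "
                f"{contig.id!r} length {contig.length}"
            )
        seq = contig.sequence[self.start - 1 : self.end]
        return reverse_complement(seq) if self.strand == "-" else seq


@dataclass
class SimilarityHit:
    """One pairwise match (protein- or nucleotide-level)."""

    query_id: str
    subject_id: str
    kind: str  # "protein" or "nucleotide"
    identity: float  # percent, 0..100
    aln_length: int
    bit_score: float
    evalue: float
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: identity "
                f"{self.identity} outside [0, 100]"
            )
        if self.aln_length < 1:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: alignment length "
                f"{self.aln_length} < 1"
            )
        if self.evalue < 0:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: negative e-value"
            )


@dataclass
class DomainHit:
    """A protein-domain match used to decide gene characterization."""

    gene_id: str
    domain_id: str
    score: float
    evalue: float


#: Domain-hit thresholds deciding whether a gene counts as characterized.
DOMAIN_MAX_EVALUE = 1e-3
DOMAIN_MIN_SCORE = 30.0


def apply_domain_hits(
    genes: Iterable[Gene],
    domain_hits: Iterable[DomainHit],
    *,
    max_evalue: float = DOMAIN_MAX_EVALUE,
    min_score: float = DOMAIN_MIN_SCORE,
) -> list[Gene]:
    """Set ``characterized`` from domain evidence.

    A gene is characterized iff it has at least one domain hit with
    e-value <= `max_evalue` and score >= `min_score`.
    Returns new Gene objects; the inputs are not mutated.
    """
    qualified: set[str] = {
        h.gene_id
        for h in domain_hits
        if h.evalue <= max_evalue and h.score >= min_score
    }
    return [replace(g, characterized=g.id in qualified) for g in genes]


def genes_by_contig(genes: Iterable[Gene]) -> dict[str, list[Gene]]:
    """Group genes per contig, ordered by start coordinate."""
    out: dict[str, list[Gene]] = {}
    for g in genes:
        out.setdefault(g.contig_id, []).append(g)
    for lst in out.values():
        lst.sort(key=lambda g: (g.start, g.end))
    return out


def check_unique_ids(items: Iterable, what: str) -> None:
    seen: set[str] = set()
    for it in items:
        if it.id in seen:
            raise ValueError(f"duplicate {what} id {it.id!r}")
        seen.add(it.id)


def contig_index(contigs: Iterable[Contig]) -> Mapping[str, Contig]:
    idx = {c.id: c for c in contigs}
    return idx
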