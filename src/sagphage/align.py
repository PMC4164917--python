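"""Pairwise similarity search.

Protein comparisons use Smith-Waterman local alignment (Biopython's
PairwiseAligner) under BLOSUM62 with affine gaps (11/1), with bit scores
and expectation values from Karlin-Altschul statistics using the published
gapped parameters for that scoring system. Any stage of the pipeline also
accepts precomputed tabular hits, so desk-scale in-repo search and real
BLAST output are interchangeable.

Nucleotide identities are computed with edlib (banded edit-distance
alignment); identity is matching columns over alignment columns.

``search_proteins`` is a seeded many-vs-many wrapper: exact amino-acid
k-mer sharing nominates candidate pairs, which are then aligned. This
trades a little sensitivity at very low identity for tractable run times;
pairs below ~40 % identity would not pass the pipeline's score thresholds
anyway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import edlib
from Bio.Align import PairwiseAligner, substitution_matrices

from .models import SimilarityHit, reverse_complement

# Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1,
# as published for BLAST. Evalue = search_space * 2^-bits.
KA_LAMBDA = 0.267
KA_K = 0.041

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -(gap_open)
    aligner.extend_gap_score = -(gap_extend)
    return aligner


_DEFAULT_ALIGNER = _make_aligner(11.0, 1.0)


def bit_score(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def evalue_from_bits(bits: float, search_space: float) -> float:
    return search_space * 2.0 ** (-bits)


def align_proteins(
    query: str,
    subject: str,
    *,
    query_id: str = "query",
    subject_id: str = "subject",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    search_space: float | None = None,
) -> SimilarityHit | None:
    """Local protein alignment returning the highest-scoring segment pair.

    Identity is matching columns over alignment columns (gaps included);
    ``X`` never counts as a match. `search_space` defaults to the product
    of the two sequence lengths; callers modelling a database search
    should pass the effective database size instead.

    Returns None when no alignment with positive score exists.
    """
    if not query or not subject:
        raise ValueError("empty protein sequence")
    if (gap_open, gap_extend) == (11.0, 1.0):
        aligner = _DEFAULT_ALIGNER
    else:
        aligner = _make_aligner(gap_open, gap_extend)
    score = aligner.score(query, subject)
    if score <= 0:
        return None
    aln = next(iter(aligner.align(query, subject)))
    q_text, s_text = str(aln[0]), str(aln[1])
    columns = len(q_text)
    matches = sum(
        1 for a, b in zip(q_text, s_text) if a == b and a not in ("-", "X")
    )
    q_start = int(aln.aligned[0][0][0]) + 1
    q_end = int(aln.aligned[0][-1][1])
    s_start = int(aln.aligned[1][0][0]) + 1
    s_end = int(aln.aligned[1][-1][1])
    bits = bit_score(score)
    space = search_space if search_space is not None else len(query) * len(subject)
    return SimilarityHit(
        query_id=query_id,
        subject_id=subject_id,
        kind="protein",
        identity=100.0 * matches / columns,
        aln_length=columns,
        bit_score=bits,
        evalue=evalue_from_bits(bits, space),
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
    )


@dataclass(frozen=True)
class HitThresholds:
    """Qualifying-hit thresholds used throughout the pipeline."""

    max_evalue: float = 1e-3
    min_bit_score: float = 50.0

    def passes(self, hit: SimilarityHit) -> bool:
        return hit.evalue <= self.max_evalue and hit.bit_score >= self.min_bit_score


DEFAULT_THRESHOLDS = HitThresholds()


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def search_proteins(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    *,
    thresholds: HitThresholds | None = DEFAULT_THRESHOLDS,
    seed_k: int = 4,
    search_space: float | None = None,
    exclude_self: bool = True,
) -> list[SimilarityHit]:
    """Seeded all-vs-all protein search.

    Pairs sharing at least one exact amino-acid `seed_k`-mer are aligned
    with :func:`align_proteins`; hits failing `thresholds` (if given) are
    dropped. `search_space` defaults, per query, to query length times
    total subject residues (database-search convention).
    """
    index: dict[str, set[str]] = {}
    for sid, sseq in subjects.items():
        for kmer in _kmer_set(sseq, seed_k):
            index.setdefault(kmer, set()).add(sid)
    total_subject = sum(len(s) for s in subjects.values())
    hits: list[SimilarityHit] = []
    for qid, qseq in queries.items():
        candidates: set[str] = set()
        for kmer in _kmer_set(qseq, seed_k):
            candidates |= index.get(kmer, set())
        for sid in sorted(candidates):
            if exclude_self and sid == qid:
                continue
            space = (
                search_space
                if search_space is not None
                else len(qseq) * max(total_subject, 1)
            )
            hit = align_proteins(
                qseq,
                subjects[sid],
                query_id=qid,
                subject_id=sid,
                search_space=space,
            )
            if hit is None:
                continue
            if thresholds is None or thresholds.passes(hit):
                hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# Nucleotide comparisons (edlib-backed)


def _cigar_columns(cigar: str) -> int:
    total = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            total += int(num)
            num = ""
    return total


def nucleotide_identity(a: str, b: str, *, mode: str = "NW") -> float:
    """Percent identity of a global ("NW") or infix ("HW") alignment.

    In HW mode `a` is aligned as a whole inside `b`; identity is matching
    columns over alignment columns.
    """
    if not a or not b:
        raise ValueError("empty nucleotide sequence")
    res = edlib.align(a, b, mode=mode, task="path")
    cols = _cigar_columns(res["cigar"])
    return 100.0 * (cols - res["editDistance"]) / cols


def best_infix_match(
    needle: str, haystack: str, *, max_distance: int
) -> tuple[int, int, float] | None:
    """Best end-to-end placement of `needle` inside `haystack`.

    Returns (start0, end0 exclusive, percent identity) or None when no
    placement has edit distance <= `max_distance`. Both strands of the
    needle are tried; coordinates always refer to the haystack.
    """
    best: tuple[int, int, float] | None = None
    for seq in (needle, reverse_complement(needle)):
        res = edlib.align(seq, haystack, mode="HW", task="path", k=max_distance)
        if res["editDistance"] < 0:
            continue
        cols = _cigar_columns(res["cigar"])
        ident = 100.0 * (cols - res["editDistance"]) / cols
        start, end = res["locations"][0]
        if best is None or ident > best[2]:
            best = (start, end + 1, ident)
    return best
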